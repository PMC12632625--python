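"""Computed-vs-experimental correlation and pipeline reporting.

Joins Boltzmann-combined computed binding free energies with experimental
(calorimetric) ones, fits the ordinary least-squares line relating them,
and emits a plain-text/markdown report carrying every consistency flag the
pipeline produces (Gibbs-relation violations, virial-identity violations,
disagreements between experimental-value sources).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .thermo import ConformerEnsemble, ThermoRecord

__all__ = ["RegressionResult", "ols_fit", "assemble_comparison", "report"]


@dataclass
class RegressionResult:
    """Closed-form simple linear regression y = slope·x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residuals: np.ndarray

    def summary(self) -> str:
        return (
            f"y = {self.slope:.4f}x + {self.intercept:.4f}, "
            f"R^2 = {self.r_squared:.2f} (n = {self.n_points})"
        )


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with R² = 1 − SS_res/SS_tot."""
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError(f"length mismatch: {xs.shape} vs {ys.shape}")
    if xs.size < 2:
        raise ValueError("need at least two points")
    dx = xs - xs.mean()
    sxx = float(np.dot(dx, dx))
    if sxx == 0.0:
        raise ValueError("x is constant; slope undefined")
    slope = float(np.dot(dx, ys - ys.mean()) / sxx)
    intercept = float(ys.mean() - slope * xs.mean())
    residuals = ys - (slope * xs + intercept)
    ss_res = float(np.dot(residuals, residuals))
    ss_tot = float(np.dot(ys - ys.mean(), ys - ys.mean()))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=int(xs.size),
        residuals=residuals,
    )


def assemble_comparison(
    ensembles: Sequence[ConformerEnsemble],
    thermo: Sequence[ThermoRecord],
    source_policy: str = "attached",
) -> pd.DataFrame:
    """One row per complex joining combined computed ΔG with experimental ΔG.

    ``source_policy`` selects where the experimental value comes from:
    ``'attached'`` uses the ΔG_exp carried on each ensemble (the value
    printed alongside the computed table), ``'itc'`` the independent
    calorimetric records. Both are always reported side by side and rows
    where the two disagree beyond 0.5 kJ/mol are flagged. Unmatched ids on
    either side are kept with NaNs; duplicated ids within a source are an
    error. Output is sorted by complex_id, so input order never matters.
    """
    if source_policy not in ("attached", "itc"):
        raise ValueError("source_policy must be 'attached' or 'itc'")
    ens_ids = [e.complex_id for e in ensembles]
    if len(set(ens_ids)) != len(ens_ids):
        raise ValueError("duplicate complex_id among ensembles")
    th_ids = [t.complex_id for t in thermo]
    if len(set(th_ids)) != len(th_ids):
        raise ValueError("duplicate complex_id among thermodynamic records")

    left = pd.DataFrame(
        {
            "complex_id": ens_ids,
            "n_conformers": [e.n_conformers for e in ensembles],
            "combined_dg": [e.combined_dg() for e in ensembles],
            "dg_exp_attached": [e.dg_exp for e in ensembles],
        }
    )
    right = pd.DataFrame(
        {"complex_id": th_ids, "dg_exp_itc": [t.dg for t in thermo]}
    )
    joined = left.merge(right, on="complex_id", how="outer").sort_values(
        "complex_id", ignore_index=True
    )
    chosen = "dg_exp_attached" if source_policy == "attached" else "dg_exp_itc"
    joined["dg_exp"] = joined[chosen]
    both = joined["dg_exp_attached"].notna() & joined["dg_exp_itc"].notna()
    joined["exp_source_mismatch"] = both & (
        (joined["dg_exp_attached"] - joined["dg_exp_itc"]).abs() > 0.5
    )
    joined["unmatched"] = joined["combined_dg"].isna() | joined["dg_exp"].isna()
    return joined


def report(
    comparison: Optional[pd.DataFrame] = None,
    regression: Optional[RegressionResult] = None,
    thermo: Optional[Sequence[ThermoRecord]] = None,
    bcp_annotated: Optional[pd.DataFrame] = None,
    pose_tables: Optional[pd.DataFrame] = None,
    gibbs_tolerance: float = 0.15,
) -> str:
    """Human-readable markdown summary of whatever the pipeline produced.

    Requires at least one artifact. Sections mirror the standard table
    layouts (experimental thermodynamics; computed-vs-experimental free
    energies; regression; interaction inventory; pose descriptors) and end
    with every consistency flag raised along the way.
    """
    if all(v is None for v in (comparison, regression, thermo, bcp_annotated, pose_tables)):
        raise ValueError("nothing to report: supply at least one artifact")
    lines: list[str] = ["# Host-guest binding analysis report", ""]
    flags: list[str] = []

    if thermo is not None:
        lines += ["## Experimental thermodynamics", ""]
        lines.append(
            "| complex | n | K_D (M) | dG (kJ/mol) | dH (kJ/mol) | -TdS (kJ/mol) |"
        )
        lines.append("|---|---|---|---|---|---|")
        for t in thermo:
            lines.append(
                f"| {t.complex_id} | {_fmt(t.n)} | {t.kd:.3g} | {t.dg:.2f} "
                f"| {_fmt(t.dh)} | {_fmt(t.minus_t_ds)} |"
            )
            r = t.consistency_residual()
            if r is not None and abs(r) > gibbs_tolerance:
                flags.append(
                    f"Gibbs relation violated for {t.complex_id}: "
                    f"dG - (dH - TdS) = {r:+.2f} kJ/mol (tolerance {gibbs_tolerance})"
                )
        lines.append("")

    if comparison is not None:
        lines += ["## Computed vs experimental binding free energies", ""]
        lines.append(comparison.to_string(index=False))
        lines.append("")
        for _, row in comparison.iterrows():
            if row.get("exp_source_mismatch"):
                flags.append(
                    f"experimental dG sources disagree for {row['complex_id']}: "
                    f"attached {row['dg_exp_attached']:+.1f} vs calorimetric "
                    f"{row['dg_exp_itc']:+.1f} kJ/mol"
                )
            if row.get("unmatched"):
                flags.append(f"complex {row['complex_id']} missing on one side of the join")

    if regression is not None:
        lines += ["## Correlation", "", regression.summary(), ""]

    if bcp_annotated is not None:
        lines += ["## Bond-critical-point interaction inventory", ""]
        from .qtaim import interaction_inventory

        try:
            lines.append(interaction_inventory(bcp_annotated).to_string(index=False))
        except ValueError:
            lines.append(bcp_annotated.to_string(index=False))
        lines.append("")
        if "virial_flag" in bcp_annotated.columns:
            bad = bcp_annotated.index[bcp_annotated["virial_flag"]].tolist()
            for i in bad:
                flags.append(f"BCP row {i} violates the local virial identity")

    if pose_tables is not None:
        lines += ["## Binding-pose descriptors", "", pose_tables.to_string(index=False), ""]

    lines += ["## Consistency flags", ""]
    lines += [f"- {f}" for f in flags] if flags else ["- none"]
    return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    return "-" if v is None else f"{v:.2f}"
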