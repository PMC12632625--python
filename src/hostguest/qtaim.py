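"""Bond-critical-point (BCP) energetics and interaction classification.

Given tabulated electron-density properties at bond critical points —
ρ(r_c), its Laplacian ∇²ρ(r_c) and the local potential energy density
V(r_c), all in atomic units — this module derives:

* the local kinetic energy density G(r_c) from the local virial theorem,
  which in atomic units reads ¼∇²ρ = 2G + V, hence G = (¼∇²ρ − V)/2;
* the Cremer–Kraka local energy density H(r_c) = V(r_c) + G(r_c);
* an empirical interaction energy from the affine Afonin relation
  E = −172.5·V(BCP) + 0.33 (kcal/mol for V in au), reported in kJ/mol;
* the Hayashi closed-shell classification from the signs of ∇²ρ and H
  (pCS: purely closed-shell; rCS: regular closed-shell with incipient
  covalency; SS: shared shell);
* Jeffrey's strong/moderate/weak hydrogen-bond bands, both geometric
  (H⋯acceptor distance) and energetic (interaction energy);
* a rule-based interaction typing (ionic/neutral hydrogen bonds, dihydrogen
  bonds, fluorine contacts, n→π* donation).

``annotate_table`` applies the whole pipeline to a pandas table whose
density columns are in the tabulation-friendly unit au × 10³.
"""

from __future__ import annotations

import math
import re
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .units import KCAL_TO_KJ

__all__ = [
    "virial_g",
    "local_h",
    "afonin_energy",
    "hayashi_class",
    "jeffrey_geometric",
    "jeffrey_energetic",
    "type_interaction",
    "annotate_table",
    "parse_bond_label",
    "interaction_inventory",
]

#: Jeffrey H⋯A distance bands (Å): strong < 1.5 ≤ moderate < 2.2 ≤ weak ≤ 3.2.
JEFFREY_D_STRONG = 1.5
JEFFREY_D_MODERATE = 2.2
JEFFREY_D_WEAK_MAX = 3.2

#: Jeffrey energy bands, kJ/mol (4 and 15 kcal/mol).
JEFFREY_E_MODERATE = 16.7
JEFFREY_E_STRONG = 62.8

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Br", "I", "Se", "Fe", "Zn",
}


def virial_g(lap: float, v: float) -> float:
    """Local kinetic energy density G(r_c) from the local virial theorem.

    In atomic units ¼∇²ρ = 2G + V, so G = (¼∇²ρ − V)/2. G is positive
    definite; a negative result indicates inconsistent inputs and raises a
    warning.
    """
    if not (math.isfinite(lap) and math.isfinite(v)):
        raise ValueError("lap and V must be finite")
    g = (0.25 * lap - v) / 2.0
    if g < 0:
        warnings.warn(
            f"derived G(r_c) = {g:.4g} au is negative; check input units",
            stacklevel=2,
        )
    return g


def local_h(v: float, g: float) -> float:
    """Cremer–Kraka local energy density H(r_c) = V(r_c) + G(r_c) (au)."""
    if not (math.isfinite(v) and math.isfinite(g)):
        raise ValueError("V and G must be finite")
    return v + g


def afonin_energy(v: float) -> float:
    """Empirical interaction energy from V(r_c), in kJ/mol.

    E = −172.5·V + 0.33 with V in atomic units yields kcal/mol; the result
    is converted with 1 kcal = 4.184 kJ. Affine and strictly decreasing in
    V. Calibrated for hydrogen bonds (V < 0 at attractive BCPs); a positive
    V raises a warning, as does applying it outside its calibration domain.
    """
    if not math.isfinite(v):
        raise ValueError("V must be finite")
    if v > 0:
        warnings.warn(
            f"V(r_c) = {v:.4g} au is positive; the energy relation expects "
            "attractive (V < 0) critical points",
            stacklevel=2,
        )
    return (-172.5 * v + 0.33) * KCAL_TO_KJ


def hayashi_class(lap: float, h: float) -> str:
    """Closed-shell/shared-shell class from the signs of ∇²ρ and H(r_c).

    ∇²ρ > 0 with H > 0 → 'pCS' (pure closed shell, electrostatic);
    ∇²ρ > 0 with H ≤ 0 → 'rCS' (regular closed shell, partial covalency);
    ∇²ρ ≤ 0 → 'SS' (shared shell, covalent).
    """
    if not (math.isfinite(lap) and math.isfinite(h)):
        raise ValueError("lap and H must be finite")
    if lap > 0:
        return "pCS" if h > 0 else "rCS"
    return "SS"


def jeffrey_geometric(d_ha: float, angle: float) -> str:
    """Jeffrey's geometric hydrogen-bond class from the H⋯A distance (Å).

    Strong < 1.5 Å ≤ Moderate < 2.2 Å ≤ Weak ≤ 3.2 Å; contacts beyond
    3.2 Å are labelled ``'Weak (d > 3.2 Å)'``. The donor-H-acceptor angle is
    validated to [0, 180] but does not move the band.
    """
    if d_ha <= 0:
        raise ValueError(f"distance must be > 0, got {d_ha}")
    if not (0.0 <= angle <= 180.0):
        raise ValueError(f"angle must be in [0, 180] degrees, got {angle}")
    if d_ha < JEFFREY_D_STRONG:
        return "Strong"
    if d_ha < JEFFREY_D_MODERATE:
        return "Moderate"
    if d_ha <= JEFFREY_D_WEAK_MAX:
        return "Weak"
    return "Weak (d > 3.2 Å)"


def jeffrey_energetic(e: float) -> str:
    """Jeffrey's energetic class from the interaction energy (kJ/mol).

    Weak < 16.7 ≤ Moderate < 62.8 ≤ Strong (4 and 15 kcal/mol boundaries;
    boundary values fall in the higher class).
    """
    if not math.isfinite(e):
        raise ValueError("E must be finite")
    if e < JEFFREY_E_MODERATE:
        return "Weak"
    if e < JEFFREY_E_STRONG:
        return "Moderate"
    return "Strong"


def type_interaction(
    donor_element: str,
    h_involved: bool,
    acceptor_element: str,
    context_labels: tuple = (),
) -> str:
    """Rule-based typing of an intermolecular contact.

    * X–H⋯O/N → ``'hbond'``, upgraded to ``'ionic_hbond'`` when a context
      label marks the donor as a protonated (piperazinium-type) nitrogen;
    * any contact involving fluorine → ``'fluorine_contact'``;
    * H⋯H → ``'dihydrogen'``;
    * O⋯C with no hydrogen mediating → ``'n_pi_star'`` (lone pair into a
      carbonyl/aromatic π* system);
    * anything else → ``'other'``.
    """
    d = donor_element.capitalize()
    a = acceptor_element.capitalize()
    for el in (d, a):
        if el not in _ELEMENTS:
            raise ValueError(f"unknown element symbol {el!r}")
    context = {c.lower() for c in context_labels}
    if "F" in (d, a):
        return "fluorine_contact"
    if d == "H" and a == "H":
        return "dihydrogen"
    if h_involved and a in ("O", "N"):
        if d == "N" and ("piperazine_n" in context or "protonated" in context):
            return "ionic_hbond"
        return "hbond"
    if not h_involved and {d, a} == {"O", "C"}:
        return "n_pi_star"
    return "other"


def parse_bond_label(label: str):
    """Split a contact label like ``'[O1]1⋯HN4'`` into its partners.

    Labels are written ``acceptor⋯donor-side``: ``'[O1]1⋯HN4'`` is a portal
    carbonyl oxygen accepting from an H on N4, ``'[O1]3⋯FC2′'`` an
    oxygen–fluorine contact, ``'C2′F⋯HeC2'`` an aryl fluorine contacting an
    (equatorial) C–H. Returns ``(acceptor_element, h_involved,
    donor_element)``; unparseable labels return ``None``.
    """
    parts = label.replace("⋯", "...").split("...")
    if len(parts) != 2:
        return None
    left = re.findall(r"[A-Z][a-z]?", parts[0])
    right = re.findall(r"[A-Z][a-z]?", parts[1])
    if not left or not right:
        return None
    acceptor = left[-1]  # contact atom of the left partner is written last
    if right[0] == "H" and len(right) > 1:
        return acceptor, True, right[1]
    if right[0] == "He" and len(right) > 1:
        # 'He' in these tables is an equatorial C-H, not helium
        return acceptor, True, right[1]
    return acceptor, False, right[0]


REQUIRED_BCP_COLUMNS = ("rho", "lap", "V")


def annotate_table(
    records: pd.DataFrame,
    virial_tolerance: float = 5e-5,
) -> pd.DataFrame:
    """Fill derived and classification columns of a BCP table.

    The input needs ``rho``, ``lap`` and ``V`` in au × 10³; optional columns
    ``d`` (H⋯A distance, Å), ``angle`` (degrees) and ``G`` (au × 10³, checked
    against the virial identity when supplied). Derived columns: ``G``,
    ``H`` (au × 10³), ``E`` (kJ/mol), ``GC``/``EC`` (Jeffrey geometric and
    energetic classes), ``HC`` (Hayashi class), ``itype`` (when a parseable
    ``bond`` label or explicit element columns are present) and
    ``virial_flag``. Idempotent and row-order equivariant.
    """
    for col in REQUIRED_BCP_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"BCP table is missing mandatory column {col!r}")
    out = records.copy()
    if (np.asarray(out["rho"], dtype=float) < 0).any():
        raise ValueError("rho must be non-negative")

    lap_au = np.asarray(out["lap"], dtype=float) * 1e-3
    v_au = np.asarray(out["V"], dtype=float) * 1e-3

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g_au = np.array([virial_g(l, v) for l, v in zip(lap_au, v_au)])
        e_kj = np.array([afonin_energy(v) for v in v_au])
    h_au = v_au + g_au

    if "G" in records.columns and records["G"].notna().any():
        supplied = np.asarray(records["G"], dtype=float) * 1e-3
        out["virial_flag"] = np.abs(0.25 * lap_au - (2 * supplied + v_au)) > virial_tolerance
    else:
        out["virial_flag"] = False

    out["G"] = g_au * 1e3
    out["H"] = h_au * 1e3
    out["E"] = e_kj
    out["HC"] = [hayashi_class(l, h) for l, h in zip(lap_au, h_au)]
    out["EC"] = [jeffrey_energetic(e) for e in e_kj]
    if "d" in out.columns:
        ang = out["angle"] if "angle" in out.columns else pd.Series(90.0, index=out.index)
        out["GC"] = [
            jeffrey_geometric(float(dd), float(aa))
            for dd, aa in zip(out["d"], ang.fillna(90.0))
        ]

    out["itype"] = [_row_itype(row) for _, row in out.iterrows()]
    return out


def _row_itype(row: pd.Series) -> Optional[str]:
    if "donor_element" in row.index and isinstance(row.get("donor_element"), str):
        return type_interaction(
            row["donor_element"],
            bool(row.get("h_involved", False)),
            row["acceptor_element"],
            tuple(str(row.get("context", "")).split(";")) if row.get("context") else (),
        )
    bond = row.get("bond")
    if isinstance(bond, str):
        parsed = parse_bond_label(bond)
        if parsed is not None:
            acceptor_el, h_involved, donor_el = parsed
            # an N-H donating into a portal oxygen is the piperazinium contact
            context = ("piperazine_n",) if (h_involved and donor_el == "N") else ()
            try:
                return type_interaction(donor_el, h_involved, acceptor_el, context)
            except ValueError:
                return None
    return None


def interaction_inventory(annotated: pd.DataFrame) -> pd.DataFrame:
    """Count interactions per complex/conformer and type."""
    keys = [k for k in ("complex_id", "conformer", "itype") if k in annotated.columns]
    if "itype" not in keys:
        raise ValueError("annotate the table first (itype column missing)")
    return (
        annotated.groupby(keys, dropna=False).size().rename("count").reset_index()
    )
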