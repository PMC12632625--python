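"""Thermodynamic bookkeeping for host-guest binding.

This module holds the relations used to turn calorimetric observables into
free energies and to assemble a computed binding free energy from additive
components:

* ``dg_from_kd`` / ``kd_from_dg`` — the standard-state relation
  ΔG = RT ln(K_D / c°) with c° = 1 M, and its exact inverse.
* ``entropy_term`` — the Gibbs relation −TΔS = ΔG − ΔH.
* ``hostas_assemble`` — the six-term additive estimate of the binding free
  energy: interaction energy, two-body (SAPT) dispersion, implicit-solvent
  solvation free energy, the entropic term −TΔS, and the deformation
  energies of host and guest.
* ``boltzmann_combine`` — population-weighted combination of per-conformer
  free energies, ΔG_total = −RT ln Σᵢ exp(−ΔGᵢ/RT), for ligands that bind in
  several crystallographically resolved poses.
* ``interaction_energy`` / ``deformation_energy`` — supermolecular energy
  differences over supplied electronic energies (this package never computes
  quantum-chemical energies itself).
* ``sapt0_total`` — the seven-component SAPT0 interaction-energy sum.

All energies are kJ/mol unless noted; temperatures are kelvin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .units import R_GAS, T_STANDARD

__all__ = [
    "ThermoRecord",
    "EnergyTerms",
    "ConformerEnsemble",
    "SAPTComponents",
    "dg_from_kd",
    "kd_from_dg",
    "entropy_term",
    "hostas_assemble",
    "boltzmann_combine",
    "interaction_energy",
    "deformation_energy",
    "sapt0_total",
]

#: Six additive components of the assembled binding free energy.
ENERGY_TERM_FIELDS = (
    "e_int",
    "e_disp",
    "g_solv",
    "minus_t_ds",
    "e_def_host",
    "e_def_guest",
)


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if v is None or not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def dg_from_kd(kd: float, temperature: float = T_STANDARD) -> float:
    """Binding free energy (kJ/mol) from a dissociation constant (molar).

    ΔG = RT ln(K_D / c°) with standard state c° = 1 M; negative for
    sub-molar K_D. Inverse of :func:`kd_from_dg`.
    """
    if kd <= 0:
        raise ValueError(f"K_D must be positive, got {kd}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_GAS * temperature * math.log(kd) / 1000.0


def kd_from_dg(dg: float, temperature: float = T_STANDARD) -> float:
    """Dissociation constant (molar) from a binding free energy (kJ/mol)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    _require_finite(dg=dg)
    return math.exp(dg * 1000.0 / (R_GAS * temperature))


def entropy_term(dg: float, dh: float) -> float:
    """Entropic contribution −TΔS = ΔG − ΔH (kJ/mol).

    Stored with the printed sign convention: negative values are
    entropically favourable.
    """
    _require_finite(dg=dg, dh=dh)
    return dg - dh


@dataclass(frozen=True)
class ThermoRecord:
    """Experimental binding thermodynamics of one host-guest complex."""

    complex_id: str
    kd: float                      # molar
    dg: float                      # kJ/mol
    n: Optional[float] = None      # sites
    n_se: Optional[float] = None
    kd_se: Optional[float] = None
    dh: Optional[float] = None     # kJ/mol
    dh_se: Optional[float] = None
    minus_t_ds: Optional[float] = None  # kJ/mol, as printed (negative = favourable)
    temperature: float = T_STANDARD

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError(f"K_D must be positive, got {self.kd}")
        for name in ("n_se", "kd_se", "dh_se"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def consistency_residual(self) -> Optional[float]:
        """ΔG − (ΔH + (−TΔS)); None when ΔH or −TΔS is unavailable."""
        if self.dh is None or self.minus_t_ds is None:
            return None
        return self.dg - (self.dh + self.minus_t_ds)

    def is_consistent(self, tol: float = 0.15) -> bool:
        """True when ΔG = ΔH − TΔS holds within the rounding tolerance."""
        r = self.consistency_residual()
        return True if r is None else abs(r) <= tol


@dataclass(frozen=True)
class EnergyTerms:
    """The six additive free-energy components for one binding conformer.

    ``inherited`` names the terms that were tabulated once per complex
    (typically the solvation free energy) and copied onto this conformer.
    """

    e_int: float          # interaction energy
    e_disp: float         # two-body (SAPT) dispersion
    g_solv: float         # implicit-solvent solvation free energy
    minus_t_ds: float     # entropic term, −TΔS
    e_def_host: float     # host deformation
    e_def_guest: float    # guest deformation
    inherited: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for name in ENERGY_TERM_FIELDS:
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"energy term {name} must be finite, got {v!r}")
        unknown = set(self.inherited) - set(ENERGY_TERM_FIELDS)
        if unknown:
            raise ValueError(f"unknown inherited term(s): {sorted(unknown)}")


def hostas_assemble(terms: EnergyTerms) -> float:
    """Assembled binding free energy: the exact sum of the six components.

    ΔG_calcd = ΔE_int + ΔE_disp + ΔG_solv + (−TΔS) + ΔE_def(host)
    + ΔE_def(guest), all in kJ/mol. Linear in every argument.
    """
    return (
        terms.e_int
        + terms.e_disp
        + terms.g_solv
        + terms.minus_t_ds
        + terms.e_def_host
        + terms.e_def_guest
    )


def boltzmann_combine(
    dg_list: Sequence[float], temperature: float = T_STANDARD
) -> float:
    """Combine per-conformer free energies into a single binding ΔG.

    ΔG_total = −RT ln Σᵢ exp(−ΔGᵢ/RT). The result never exceeds the minimum
    of the inputs, equals it in the T→0 limit, and equals g − RT ln N for N
    identical entries g.
    """
    dgs = np.asarray(dg_list, dtype=float)
    if dgs.size == 0:
        raise ValueError("need at least one conformer free energy")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if not np.all(np.isfinite(dgs)):
        raise ValueError("conformer free energies must be finite")
    rt = R_GAS * temperature / 1000.0  # kJ/mol
    return float(-rt * logsumexp(-dgs / rt))


@dataclass
class ConformerEnsemble:
    """Per-conformer energy terms of one complex, plus the combined ΔG.

    ``dg_exp`` optionally carries the experimental binding free energy
    reported alongside the computed table, which may differ from an
    independently stored calorimetric record (the report surfaces such
    discrepancies).
    """

    complex_id: str
    conformers: list  # of (label, EnergyTerms)
    temperature: float = T_STANDARD
    dg_exp: Optional[float] = None

    def __post_init__(self):
        if len(self.conformers) < 1:
            raise ValueError("ensemble needs at least one conformer")

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    def assembled(self) -> list[float]:
        """Per-conformer assembled ΔG_calcd, in input order."""
        return [hostas_assemble(t) for _, t in self.conformers]

    def combined_dg(self) -> float:
        """Boltzmann-combined binding free energy of the ensemble."""
        return boltzmann_combine(self.assembled(), self.temperature)


def interaction_energy(
    e_complex: float, e_host_in_complex: float, e_guest_in_complex: float
) -> float:
    """Supermolecular interaction energy.

    ΔE_int = E(complex) − [E(host at complex geometry) + E(guest at complex
    geometry)]; all inputs in a common unit.
    """
    _require_finite(
        e_complex=e_complex,
        e_host_in_complex=e_host_in_complex,
        e_guest_in_complex=e_guest_in_complex,
    )
    return e_complex - (e_host_in_complex + e_guest_in_complex)


def deformation_energy(e_in_complex_geometry: float, e_unbound_optimized: float) -> float:
    """Deformation (strain) energy of one partner upon binding.

    ΔE_def = E(geometry in the complex) − E(relaxed unbound geometry).
    The unbound geometry is a minimum, so a negative result is suspicious
    and raises a warning rather than an error.
    """
    _require_finite(
        e_in_complex_geometry=e_in_complex_geometry,
        e_unbound_optimized=e_unbound_optimized,
    )
    de = e_in_complex_geometry - e_unbound_optimized
    if de < 0:
        warnings.warn(
            f"negative deformation energy ({de:.4g}): the unbound reference "
            "should be a minimum",
            stacklevel=2,
        )
    return de


@dataclass(frozen=True)
class SAPTComponents:
    """Seven-component SAPT0 decomposition of an interaction energy (kJ/mol)."""

    elst: float
    exch: float
    ind_resp: float
    exch_ind_resp: float
    disp: float
    exch_disp: float
    delta_hf: float

    def __post_init__(self):
        for name in (
            "elst", "exch", "ind_resp", "exch_ind_resp",
            "disp", "exch_disp", "delta_hf",
        ):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"SAPT component {name} must be finite, got {v!r}")


def sapt0_total(c: SAPTComponents) -> float:
    """Total SAPT0 interaction energy: the exact seven-component sum."""
    return (
        c.elst + c.exch + c.ind_resp + c.exch_ind_resp
        + c.disp + c.exch_disp + c.delta_hf
    )
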