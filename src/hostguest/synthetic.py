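"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this pipeline come from instruments and quantum-chemistry
codes: integrated per-injection ITC heats, per-conformer energy-term
tables, bond-critical-point property tables and refined crystal
coordinates. The generators here emulate each of those artifacts and embed
the ground truth they were built from, so every consumer (isotherm fitter,
free-energy assembler, BCP classifier, pose-descriptor code) can be tested
by round trip without any external data.

What is emulated — and what is not:

* ``gen_titration`` — one-site titration heats from the same forward model
  the fitter uses, plus i.i.d. Gaussian noise on each integrated heat
  (default scale: 1% of the first-injection heat). Raw power-compensation
  thermograms and baseline integration are not emulated.
* ``gen_energy_table`` — per-conformer additive energy components drawn
  uniformly from stated ranges, with the complex-level solvation term
  tabulated once and inherited, exactly as such tables are printed.
* ``gen_bcp_table`` — rows built directly from (∇²ρ, V) pairs so the local
  virial identity holds to machine precision, with Hayashi/Jeffrey class
  labels planted by construction margins away from every decision boundary.
* ``gen_toy_complex`` — an idealized barrel host (7-fold rings of portal
  oxygens and equatorial carbons, sized to cucurbit[7]uril) plus a
  pseudo-guest placed to realise requested pose descriptors exactly.
  No thermal motion, no symmetry mates, no solvent.

Seeding: each generator derives its stream from
``SeedSequence(seed, spawn_key=(KIND,))`` with a fixed per-generator KIND,
so adding a generator never perturbs the streams of the others and a fixed
seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    AtomSite,
    PoseDescriptors,
    PoseSelections,
    StructureModel,
    write_structure,
)
from .itc import TitrationProtocol, predict_injection_heats
from .thermo import ENERGY_TERM_FIELDS, EnergyTerms, boltzmann_combine, hostas_assemble
from .units import KCAL_TO_KJ, T_STANDARD

__all__ = [
    "gen_titration",
    "gen_energy_table",
    "gen_bcp_table",
    "gen_toy_complex",
    "SyntheticTitration",
    "SyntheticEnergyTable",
    "SyntheticBCPTable",
    "ToyComplex",
]

# fixed stream-split keys, one per artifact kind (never renumber)
_KIND_TITRATION = 1
_KIND_ENERGY_TABLE = 2
_KIND_BCP_TABLE = 3
_KIND_TOY_COMPLEX = 4


def _rng(seed: int, kind: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(kind,)))


# ---------------------------------------------------------------------------
# titrations

@dataclass
class SyntheticTitration:
    """Per-injection heats (J) plus the parameters that generated them."""

    heats: np.ndarray
    truth: dict          # n, kd (M), dh (kJ/mol)
    protocol: TitrationProtocol
    noise_sd: float      # J

    def write(self, basepath) -> None:
        """``<base>.csv`` with the heats and ``<base>.truth.json`` sidecar."""
        from .itc import write_heats_csv, write_protocol

        base = Path(basepath)
        write_heats_csv(base.with_suffix(".csv"), self.heats)
        write_protocol(base.with_suffix(".protocol.yaml"), self.protocol)
        base.with_suffix(".truth.json").write_text(
            json.dumps({**self.truth, "noise_sd_J": self.noise_sd}, indent=1)
        )


def gen_titration(
    truth: dict,
    protocol: TitrationProtocol,
    noise_sd: Optional[float] = None,
    seed: int = 0,
) -> SyntheticTitration:
    """Simulate a one-site titration with known (n, K_D, ΔH).

    ``truth`` supplies ``n`` (sites), ``kd`` (molar) and ``dh`` (kJ/mol).
    Heats are the forward-model prediction plus i.i.d. Gaussian noise of
    standard deviation ``noise_sd`` (joules); the default is 1% of the
    magnitude of the first-injection heat.
    """
    n = float(truth["n"])
    kd = float(truth["kd"])
    dh = float(truth["dh"])
    if kd <= 0:
        raise ValueError(f"K_D must be > 0, got {kd}")
    clean = predict_injection_heats({"n": n, "ka": 1.0 / kd, "dh": dh}, protocol)
    if noise_sd is None:
        noise_sd = 0.01 * abs(clean[0])
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = _rng(seed, _KIND_TITRATION)
    heats = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean.copy()
    return SyntheticTitration(
        heats=heats,
        truth={"n": n, "kd": kd, "dh": dh},
        protocol=protocol,
        noise_sd=float(noise_sd),
    )


# ---------------------------------------------------------------------------
# energy-term tables

DEFAULT_TERM_RANGES = {
    # kJ/mol, spanning the magnitudes typical of CB[7] complexes
    "e_int": (-290.0, -220.0),
    "e_disp": (-185.0, -150.0),
    "g_solv": (255.0, 285.0),
    "minus_t_ds": (-75.0, 45.0),
    "e_def_host": (125.0, 160.0),
    "e_def_guest": (10.0, 25.0),
}


@dataclass
class SyntheticEnergyTable:
    """Per-conformer energy-term table plus embedded assembled/combined truth."""

    table: pd.DataFrame          # one row per conformer; g_solv blank when inherited
    row_truth: pd.DataFrame      # complex_id, conformer, dg_calcd
    combined_truth: pd.DataFrame  # complex_id, combined_dg
    temperature: float

    def write(self, basepath) -> None:
        base = Path(basepath)
        self.table.to_csv(base.with_suffix(".csv"), index=False)
        truth = {
            "temperature_K": self.temperature,
            "rows": self.row_truth.to_dict(orient="records"),
            "combined": self.combined_truth.to_dict(orient="records"),
        }
        base.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))


def gen_energy_table(
    n_complexes: int,
    n_conformers: int,
    term_ranges: Optional[dict] = None,
    seed: int = 0,
    temperature: float = T_STANDARD,
) -> SyntheticEnergyTable:
    """Random per-conformer energy-term tables with known ΔG truth.

    Every conformer row carries the six additive components; the solvation
    term is drawn once per complex and tabulated only on the first
    conformer (blank otherwise), mirroring how published tables inherit
    complex-level terms. The embedded truth holds the per-row assembled
    ΔG_calcd (exact six-term sum) and the per-complex Boltzmann-combined
    ΔG.
    """
    if n_complexes < 1 or n_conformers < 1:
        raise ValueError("n_complexes and n_conformers must be >= 1")
    ranges = dict(DEFAULT_TERM_RANGES)
    if term_ranges:
        ranges.update(term_ranges)
    for name in ENERGY_TERM_FIELDS:
        lo, hi = ranges[name]
        if not (math.isfinite(lo) and math.isfinite(hi)) or hi < lo:
            raise ValueError(f"empty or invalid range for term {name!r}: {(lo, hi)}")

    rng = _rng(seed, _KIND_ENERGY_TABLE)
    rows, truth_rows, combined_rows = [], [], []
    for ci in range(n_complexes):
        cid = f"complex_{ci + 1}"
        g_solv = rng.uniform(*ranges["g_solv"])
        dgs = []
        for k in range(n_conformers):
            vals = {
                name: rng.uniform(*ranges[name])
                for name in ENERGY_TERM_FIELDS
                if name != "g_solv"
            }
            terms = EnergyTerms(
                g_solv=g_solv,
                inherited=frozenset() if k == 0 else frozenset({"g_solv"}),
                **vals,
            )
            dg = hostas_assemble(terms)
            dgs.append(dg)
            rows.append(
                {
                    "complex_id": cid,
                    "conformer": k + 1,
                    **vals,
                    "g_solv": g_solv if k == 0 else np.nan,
                }
            )
            truth_rows.append({"complex_id": cid, "conformer": k + 1, "dg_calcd": dg})
        combined_rows.append(
            {"complex_id": cid, "combined_dg": boltzmann_combine(dgs, temperature)}
        )
    cols = ["complex_id", "conformer", *ENERGY_TERM_FIELDS]
    return SyntheticEnergyTable(
        table=pd.DataFrame(rows)[cols],
        row_truth=pd.DataFrame(truth_rows),
        combined_truth=pd.DataFrame(combined_rows),
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# BCP tables

#: Jeffrey energetic bands sampled with a margin away from the 16.7 and
#: 62.8 kJ/mol boundaries so planted labels survive any rounding.
_EC_BANDS = {"Weak": (2.0, 16.2), "Moderate": (17.2, 62.3), "Strong": (63.3, 140.0)}
_GC_BANDS = {"Strong": (0.95, 1.45), "Moderate": (1.55, 2.15), "Weak": (2.25, 3.15)}


@dataclass
class SyntheticBCPTable:
    """BCP property table (au x 10^3) with planted classification labels."""

    table: pd.DataFrame   # d, angle, rho, lap, V
    truth: pd.DataFrame   # planted GC, EC, HC per row

    def write(self, basepath) -> None:
        base = Path(basepath)
        self.table.to_csv(base.with_suffix(".csv"), index=False)
        self.truth.to_csv(base.with_suffix(".truth.csv"), index=False)


def gen_bcp_table(
    n_rows: int,
    class_mix: Optional[dict] = None,
    rho_range: tuple = (3.0, 40.0),
    seed: int = 0,
) -> SyntheticBCPTable:
    """Generate BCP rows satisfying the local virial identity exactly.

    Rows are constructed from a potential energy density V (chosen to plant
    a Jeffrey energetic class) and a Laplacian ∇²ρ (chosen to plant a
    Hayashi class): since the consumer derives G = (¼∇²ρ − V)/2 and
    H = V + G, the identity ¼∇²ρ = 2G + V holds to machine precision by
    construction. ``class_mix`` gives Hayashi-class proportions
    (default equal thirds) and must sum to 1; distances plant the geometric
    class. All planted labels sit a margin away from every decision
    boundary, so the classifier recovers them with certainty.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if rho_range[0] < 0:
        raise ValueError(f"rho must be non-negative, got range {rho_range}")
    mix = dict(class_mix or {"pCS": 1 / 3, "rCS": 1 / 3, "SS": 1 / 3})
    unknown = set(mix) - {"pCS", "rCS", "SS"}
    if unknown:
        raise ValueError(f"unknown Hayashi class(es) in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"class_mix proportions must sum to 1, got {total}")

    rng = _rng(seed, _KIND_BCP_TABLE)
    hc_names = sorted(mix)
    hc_probs = np.array([mix[k] for k in hc_names])
    ec_names = list(_EC_BANDS)
    gc_names = list(_GC_BANDS)

    rows, truths = [], []
    for i in range(n_rows):
        hc = hc_names[rng.choice(len(hc_names), p=hc_probs)]
        ec = ec_names[rng.integers(len(ec_names))]
        gc = gc_names[rng.integers(len(gc_names))]

        e_kj = rng.uniform(*_EC_BANDS[ec])
        v_au = -(e_kj / KCAL_TO_KJ - 0.33) / 172.5        # < 0 always
        if hc == "pCS":                                    # H > 0 needs lap > -4V
            lap_au = -4.0 * v_au * (1.0 + rng.uniform(0.15, 2.0))
        elif hc == "rCS":                                  # 0 < lap < -4V gives H < 0
            lap_au = -4.0 * v_au * rng.uniform(0.05, 0.85)
        else:                                              # SS: lap < 0, G >= 0 needs |lap| <= 4|V|
            lap_au = -abs(v_au) * rng.uniform(0.2, 3.8)

        d = rng.uniform(*_GC_BANDS[gc])
        rows.append(
            {
                "bond": f"O{i + 1}...HN{i + 1}",
                "angle": rng.uniform(90.0, 180.0),
                "d": d,
                "rho": rng.uniform(*rho_range),
                "lap": lap_au * 1e3,
                "V": v_au * 1e3,
            }
        )
        truths.append({"GC": gc, "EC": ec, "HC": hc})
    return SyntheticBCPTable(table=pd.DataFrame(rows), truth=pd.DataFrame(truths))


# ---------------------------------------------------------------------------
# toy host-guest structures

@dataclass
class GuestSpec:
    """Requested pose of one guest disorder component.

    ``n_height`` — distance (Å) of the charged nitrogen below the portal
    plane (toward the cavity); ``axial_angle`` — requested
    ∠(Cen1-Cen2-N) in degrees; ``phenyl_tilt`` — requested aryl-ring tilt
    against the equatorial plane, degrees in [0, 90];
    ``halogen_distance`` — optional distance of a para halogen beyond the
    far-portal centroid.
    """

    n_height: float = 0.2
    axial_angle: float = 5.0
    phenyl_tilt: float = 80.0
    halogen_distance: Optional[float] = None


@dataclass
class ToyComplex:
    structure: StructureModel
    selections: PoseSelections
    truth: list = field(default_factory=list)  # of PoseDescriptors

    def write(self, basepath) -> None:
        """Both structure dialects plus a ground-truth JSON sidecar."""
        base = Path(basepath)
        write_structure(self.structure, base.with_suffix(".xyz"), "labeled_xyz")
        write_structure(self.structure, base.with_suffix(".cif"), "cif_min")
        truth = [
            {
                "disorder_group": t.disorder_group,
                "occupancy": t.occupancy,
                "d_n_plane1": t.d_n_plane1,
                "angle_cen1_cen2_n": t.angle_cen1_cen2_n,
                "angle_phenyl_plane2": t.angle_phenyl_plane2,
                "d_cen1prime_halogen": t.d_cen1prime_halogen,
            }
            for t in self.truth
        ]
        base.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))


def _ring(prefix: str, element: str, n: int, radius: float, z: float,
          phase: float = 0.0) -> list:
    pts = []
    for k in range(n):
        t = phase + 2.0 * math.pi * k / n
        pts.append(
            AtomSite(
                label=f"{prefix}{k + 1}",
                element=element,
                pos=np.array([radius * math.cos(t), radius * math.sin(t), z]),
            )
        )
    return pts


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def gen_toy_complex(
    portal_radius: float = 3.5,
    equatorial_radius: float = 4.4,
    guest_spec: Optional[Sequence[GuestSpec]] = None,
    occupancies: Optional[Sequence[float]] = None,
    portal_half_height: float = 3.05,
    n_portal: int = 7,
    seed: int = 0,
) -> ToyComplex:
    """Idealized barrel host with pseudo-guests at requested poses.

    The host is two ``n_portal``-fold rings of oxygens at z = ±h and a
    2·``n_portal`` ring of equatorial carbons at z = 0, so the fitted
    portal plane is exactly z = h and the equatorial plane exactly z = 0.
    Each guest disorder component places its charged nitrogen to realise
    the requested height below the portal plane and axial angle exactly,
    and a six-membered aryl ring tilted by exactly the requested angle.
    The embedded truth therefore closes the descriptor round trip to
    numerical precision. The seed only randomizes the azimuthal placement
    of each guest, to which every descriptor is invariant.
    """
    if portal_radius <= 0 or equatorial_radius <= 0:
        raise ValueError("radii must be > 0")
    if n_portal < 3:
        raise ValueError("each plane-defining ring needs at least 3 atoms")
    specs = list(guest_spec) if guest_spec is not None else [GuestSpec()]
    occs = list(occupancies) if occupancies is not None else [1.0] * len(specs)
    if len(occs) != len(specs):
        raise ValueError("occupancies and guest_spec must have equal length")
    if any(not (0.0 < o <= 1.0) for o in occs):
        raise ValueError("occupancies must be in (0, 1]")
    if sum(occs) > 1.0 + 1e-9:
        raise ValueError("occupancies must sum to <= 1 for one disorder assembly")

    rng = _rng(seed, _KIND_TOY_COMPLEX)
    zp = portal_half_height
    atoms = _ring("O1_", "O", n_portal, portal_radius, zp)
    atoms += _ring("O2_", "O", n_portal, portal_radius, -zp)
    atoms += _ring("CE", "C", 2 * n_portal, equatorial_radius, 0.0)

    multi = len(specs) > 1
    truth = []
    any_halogen = any(s.halogen_distance is not None for s in specs)
    for gi, (spec, occ) in enumerate(zip(specs, occs)):
        group = gi + 1 if multi else 0
        if not (0.0 <= spec.n_height < zp):
            raise ValueError(
                f"n_height must be in [0, {zp}) so the nitrogen stays cavity-side"
            )
        if not (0.0 <= spec.axial_angle < 90.0):
            raise ValueError("axial_angle must be in [0, 90) degrees")
        if not (0.0 <= spec.phenyl_tilt <= 90.0):
            raise ValueError("phenyl_tilt must be in [0, 90] degrees")
        rot = _rot_z(rng.uniform(0.0, 2.0 * math.pi))

        z_n = zp - spec.n_height
        x_n = z_n * math.tan(math.radians(spec.axial_angle))
        guest = [AtomSite("N29", "N", rot @ np.array([x_n, 0.0, z_n]), occ, group)]

        tilt = math.radians(spec.phenyl_tilt)
        normal = np.array([math.sin(tilt), 0.0, math.cos(tilt)])
        u = np.array([math.cos(tilt), 0.0, -math.sin(tilt)])  # in-plane, ⟂ normal
        v = np.cross(normal, u)
        center = np.array([0.6, 0.0, -0.8])
        for k in range(6):
            t = 2.0 * math.pi * k / 6
            p = center + 1.39 * (math.cos(t) * u + math.sin(t) * v)
            guest.append(AtomSite(f"CP{k + 1}", "C", rot @ p, occ, group))
        if spec.halogen_distance is not None:
            guest.append(
                AtomSite(
                    "X1", "Cl",
                    rot @ np.array([0.0, 0.0, -zp - spec.halogen_distance]),
                    occ, group,
                )
            )
        elif any_halogen:
            # keep labels resolvable in every group when any group has one
            guest.append(
                AtomSite("X1", "Cl", rot @ np.array([0.0, 0.0, -zp - 1.5]), occ, group)
            )
        atoms += guest
        truth.append(
            PoseDescriptors(
                disorder_group=group,
                occupancy=occ,
                d_n_plane1=spec.n_height,
                angle_cen1_cen2_n=spec.axial_angle,
                angle_phenyl_plane2=spec.phenyl_tilt,
                d_cen1prime_halogen=(
                    spec.halogen_distance
                    if spec.halogen_distance is not None
                    else (1.5 if any_halogen else None)
                ),
            )
        )

    selections = PoseSelections(
        portal_o=tuple(f"O1_{k + 1}" for k in range(n_portal)),
        portal_o_prime=tuple(f"O2_{k + 1}" for k in range(n_portal)),
        equatorial_c=tuple(f"CE{k + 1}" for k in range(2 * n_portal)),
        n_charged="N29",
        phenyl=tuple(f"CP{k + 1}" for k in range(6)),
        halogen="X1" if any_halogen else None,
    )
    return ToyComplex(
        structure=StructureModel(atoms=atoms), selections=selections, truth=truth
    )
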