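"""Binding-pose descriptors from occupancy-aware crystal coordinates.

For barrel-shaped hosts like cucurbit[7]uril the binding pose of a cationic
guest is summarised by a few geometric quantities defined from the host
frame (see :func:`pose_descriptors`):

* ``Plane1``/``Cen1`` — least-squares plane and centroid of the portal
  carbonyl oxygens nearest the guest's ammonium nitrogen;
* ``Plane2``/``Cen2`` — plane and centroid of the equatorial carbons;
* ``d(N⋯Plane1)`` — how far the charged nitrogen sits from the portal plane;
* ``∠(Cen1-Cen2-N)`` — vertex angle at Cen2; small values mean the nitrogen
  sits on the portal axis;
* ``∠(Phenyl··Plane2)`` — tilt of the guest's aryl ring against the
  equatorial plane, folded to [0, 90]°.

Structures are read either from a minimal CIF subset (cell + atom_site
loop, parsed with gemmi, fractional coordinates orthogonalised on read) or
from ``labeled_xyz``, a plain-text dialect carrying label, element,
Cartesian coordinates, occupancy and disorder group. Internally everything
is Cartesian ångströms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "StructureModel",
    "Plane",
    "PoseDescriptors",
    "HBondGeometry",
    "PoseSelections",
    "read_structure",
    "write_structure",
    "centroid",
    "fit_plane",
    "point_plane_distance",
    "vertex_angle",
    "plane_plane_angle",
    "pose_descriptors",
    "hbond_geometry",
]


@dataclass
class AtomSite:
    label: str
    element: str
    pos: np.ndarray  # Cartesian Å, shape (3,)
    occupancy: float = 1.0
    disorder_group: int = 0  # 0 = ordered

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ValueError("pos must be a 3-vector")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")


@dataclass
class StructureModel:
    """A list of occupancy-aware atom sites in Cartesian ångströms."""

    atoms: list
    cell: Optional[tuple] = None  # (a, b, c, alpha, beta, gamma) if from CIF

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            key = (a.label, a.disorder_group)
            if key in seen:
                raise ValueError(
                    f"duplicate label {a.label!r} in disorder group {a.disorder_group}"
                )
            seen.add(key)

    def get(self, label: str, disorder_group: Optional[int] = None) -> AtomSite:
        """Resolve a label, preferring the requested disorder group, then 0."""
        groups = [disorder_group, 0] if disorder_group is not None else [None]
        for g in groups:
            for a in self.atoms:
                if a.label == label and (g is None or a.disorder_group == g):
                    return a
        raise KeyError(f"no atom with label {label!r}"
                       + (f" in disorder group {disorder_group} (or 0)"
                          if disorder_group is not None else ""))

    def select(self, labels: Sequence[str], disorder_group: Optional[int] = None):
        return [self.get(lb, disorder_group) for lb in labels]

    def coords(self, labels: Sequence[str], disorder_group: Optional[int] = None):
        return np.array([a.pos for a in self.select(labels, disorder_group)])

    def disorder_groups(self) -> list:
        return sorted({a.disorder_group for a in self.atoms if a.disorder_group != 0})

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        """Rigid-body copy: x → R x + t."""
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return StructureModel(
            atoms=[
                AtomSite(a.label, a.element, rot @ a.pos + t, a.occupancy, a.disorder_group)
                for a in self.atoms
            ],
            cell=None,
        )


# ---------------------------------------------------------------------------
# I/O

def read_structure(path, dialect: str) -> StructureModel:
    if dialect == "cif_min":
        return _read_cif_min(path)
    if dialect == "labeled_xyz":
        return _read_labeled_xyz(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'cif_min' or 'labeled_xyz'")


def _read_cif_min(path) -> StructureModel:
    small = gemmi.read_small_structure(str(path))
    if small.cell.a == 0:
        raise ValueError(f"{path}: CIF has fractional coordinates but no cell")
    atoms = []
    for site in small.sites:
        cart = small.cell.orthogonalize(site.fract)
        group = site.disorder_group if site.disorder_group else 0
        element = site.type_symbol or site.element.name
        atoms.append(
            AtomSite(
                label=site.label,
                element=element,
                pos=np.array([cart.x, cart.y, cart.z]),
                occupancy=site.occ if site.occ > 0 else 1.0,
                disorder_group=group,
            )
        )
    if not atoms:
        raise ValueError(f"{path}: no atom_site loop found")
    c = small.cell
    return StructureModel(atoms=atoms, cell=(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))


def _read_labeled_xyz(path) -> StructureModel:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: truncated labeled_xyz file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: expected an atom count")
    atoms = []
    for i, ln in enumerate(lines[2 : 2 + natoms], start=3):
        parts = ln.split()
        if len(parts) < 5:
            raise ValueError(
                f"{path}: line {i}: expected 'label element x y z [occ [group]]'"
            )
        label, element = parts[0], parts[1]
        xyz = [float(v) for v in parts[2:5]]
        occ = float(parts[5]) if len(parts) > 5 else 1.0
        group = int(parts[6]) if len(parts) > 6 else 0
        atoms.append(AtomSite(label, element, np.array(xyz), occ, group))
    if len(atoms) != natoms:
        raise ValueError(f"{path}: header says {natoms} atoms, found {len(atoms)}")
    return StructureModel(atoms=atoms)


def write_structure(model: StructureModel, path, dialect: str) -> None:
    if dialect == "labeled_xyz":
        lines = [str(len(model.atoms)), "labeled_xyz: label element x y z occ group"]
        for a in model.atoms:
            x, y, z = (float(v) for v in a.pos)
            lines.append(
                f"{a.label} {a.element} {x!r} {y!r} {z!r} "
                f"{float(a.occupancy)!r} {a.disorder_group}"
            )
        Path(path).write_text("\n".join(lines) + "\n")
        return
    if dialect == "cif_min":
        _write_cif_min(model, path)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_cif_min(model: StructureModel, path) -> None:
    # enclose the model in a padded orthorhombic box so fractional
    # coordinates are well defined even for a cell-free Cartesian model
    if model.cell is not None:
        cell = gemmi.UnitCell(*model.cell)
        shift = np.zeros(3)
    else:
        xyz = np.array([a.pos for a in model.atoms])
        lo, hi = xyz.min(axis=0) - 5.0, xyz.max(axis=0) + 5.0
        span = hi - lo
        cell = gemmi.UnitCell(span[0], span[1], span[2], 90.0, 90.0, 90.0)
        shift = lo
    lines = [
        "data_synthetic",
        f"_cell_length_a {cell.a:.6f}",
        f"_cell_length_b {cell.b:.6f}",
        f"_cell_length_c {cell.c:.6f}",
        f"_cell_angle_alpha {cell.alpha:.6f}",
        f"_cell_angle_beta {cell.beta:.6f}",
        f"_cell_angle_gamma {cell.gamma:.6f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
        "_atom_site_disorder_group",
    ]
    for a in model.atoms:
        frac = cell.fractionalize(gemmi.Position(*(a.pos - shift)))
        group = str(a.disorder_group) if a.disorder_group else "."
        lines.append(
            f"{a.label} {a.element} {frac.x:.9f} {frac.y:.9f} {frac.z:.9f} "
            f"{a.occupancy:.4f} {group}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# primitive descriptors

def centroid(sites: Sequence) -> np.ndarray:
    """Unweighted mean position of a selection (Å)."""
    if len(sites) == 0:
        raise ValueError("empty selection")
    pts = np.array([_as_point(s) for s in sites])
    return pts.mean(axis=0)


def _as_point(obj) -> np.ndarray:
    return obj.pos if isinstance(obj, AtomSite) else np.asarray(obj, dtype=float)


@dataclass
class Plane:
    """Total-least-squares plane: unit normal, a point on it, rms residual."""

    normal: np.ndarray
    point: np.ndarray
    rms: float


def fit_plane(sites: Sequence, orient_toward=None) -> Plane:
    """Least-squares plane through ≥3 non-collinear atoms.

    Minimises the sum of squared perpendicular distances (total least
    squares via the smallest principal direction of the centred selection);
    the plane passes through the selection centroid. With ``orient_toward``,
    the normal is flipped to point at that reference (e.g. the cavity
    interior).
    """
    pts = np.array([_as_point(s) for s in sites])
    if len(pts) < 3:
        raise ValueError(f"need at least 3 atoms to fit a plane, got {len(pts)}")
    center = pts.mean(axis=0)
    centered = pts - center
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection; plane undefined")
    normal = vt[-1]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    if orient_toward is not None:
        ref = _as_point(orient_toward)
        if np.dot(ref - center, normal) < 0:
            normal = -normal
    return Plane(normal=normal, point=center, rms=rms)


def point_plane_distance(point, plane: Plane, signed: bool = False) -> float:
    """Perpendicular distance from a point to a plane (Å).

    Unsigned by default; the signed variant is positive on the side the
    normal points to (the cavity side, when the plane was oriented).
    """
    d = float(np.dot(_as_point(point) - plane.point, plane.normal))
    return d if signed else abs(d)


def vertex_angle(a, b, c) -> float:
    """Angle at vertex ``b`` of the triangle a-b-c, degrees in [0, 180]."""
    u = _as_point(a) - _as_point(b)
    v = _as_point(c) - _as_point(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("zero-length arm; angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def plane_plane_angle(p1: Plane, p2: Plane) -> float:
    """Acute dihedral angle between two planes, degrees in [0, 90]."""
    cosang = abs(float(np.dot(p1.normal, p2.normal)))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# composite descriptors

@dataclass(frozen=True)
class PoseSelections:
    """Label sets defining the host frame and the guest probes.

    ``portal_o`` are the portal oxygens nearest the charged nitrogen
    (Plane1/Cen1); ``portal_o_prime`` the opposite portal (Cen1′);
    ``equatorial_c`` the equatorial carbons (Plane2/Cen2); ``n_charged``
    the guest's ammonium nitrogen; ``phenyl`` the aryl-ring atoms;
    ``halogen`` an optional para substituent.
    """

    portal_o: tuple
    equatorial_c: tuple
    n_charged: str
    phenyl: tuple
    portal_o_prime: tuple = ()
    halogen: Optional[str] = None


@dataclass
class PoseDescriptors:
    """Binding-pose descriptors for one guest disorder group."""

    disorder_group: int
    occupancy: float
    d_n_plane1: float            # Å
    angle_cen1_cen2_n: float     # degrees
    angle_phenyl_plane2: float   # degrees, folded to [0, 90]
    d_cen1prime_halogen: Optional[float] = None  # Å


@dataclass
class HBondGeometry:
    donor: str
    hydrogen: str
    acceptor: str
    d_da: float       # donor⋯acceptor distance, Å
    angle_dha: float  # angle at H, degrees


def pose_descriptors(
    structure: StructureModel, selections: PoseSelections
) -> list:
    """Compute pose descriptors for every guest disorder group.

    Host selections resolve in the ordered part of the model; guest labels
    resolve per disorder group, so each crystallographically resolved pose
    yields its own record carrying the refined occupancy. Structures with
    no guest disorder yield a single record with occupancy 1.
    """
    if len(selections.portal_o) < 3 or len(selections.equatorial_c) < 3:
        raise ValueError("plane selections need at least 3 atoms each")
    try:
        portal_sites = structure.select(selections.portal_o)
        equator_sites = structure.select(selections.equatorial_c)
    except KeyError as err:
        raise KeyError(f"unresolvable host selection: {err}") from err
    cen2 = centroid(equator_sites)
    cen1 = centroid(portal_sites)
    plane1 = fit_plane(portal_sites, orient_toward=cen2)
    plane2 = fit_plane(equator_sites)

    cen1_prime = (
        centroid(structure.select(selections.portal_o_prime))
        if selections.portal_o_prime
        else None
    )

    groups = structure.disorder_groups() or [0]
    records = []
    for g in groups:
        n_atom = structure.get(selections.n_charged, g)
        phenyl_sites = structure.select(selections.phenyl, g)
        phenyl_plane = fit_plane(phenyl_sites)
        d_hal = None
        if selections.halogen is not None and cen1_prime is not None:
            hal = structure.get(selections.halogen, g)
            d_hal = float(np.linalg.norm(hal.pos - cen1_prime))
        records.append(
            PoseDescriptors(
                disorder_group=g,
                occupancy=n_atom.occupancy,
                d_n_plane1=point_plane_distance(n_atom.pos, plane1),
                angle_cen1_cen2_n=vertex_angle(cen1, cen2, n_atom.pos),
                angle_phenyl_plane2=plane_plane_angle(phenyl_plane, plane2),
                d_cen1prime_halogen=d_hal,
            )
        )
    return records


def hbond_geometry(
    structure: StructureModel, donor: str, hydrogen: str, acceptor: str,
    disorder_group: Optional[int] = None,
) -> HBondGeometry:
    """Donor⋯acceptor distance and D-H⋯A angle for three labelled atoms."""
    d = structure.get(donor, disorder_group)
    h = structure.get(hydrogen, disorder_group)
    a = structure.get(acceptor, disorder_group)
    return HBondGeometry(
        donor=donor,
        hydrogen=hydrogen,
        acceptor=acceptor,
        d_da=float(np.linalg.norm(d.pos - a.pos)),
        angle_dha=vertex_angle(d.pos, h.pos, a.pos),
    )
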