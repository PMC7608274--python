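"""Geometric and steric features on the protein model.

Three groups of operations live here:

* region/topology geometry — modelled-region membership and the
  intracellular/extracellular *sidedness* of a residue, defined by the angle
  at the protein centre of mass between the query Calpha and the Calpha of an
  intracellular reference residue (< 90 deg means intracellular; the
  C-terminal domain and unmodelled parts are excluded);
* mutant side-chain construction — idealized side chains built by NeRF from
  embedded internal-coordinate templates, one placement per canonical rotamer;
* a clash (goodness-of-fit) proxy — a van der Waals sphere-overlap penalty,
  minimized over rotamers.  The score is <= 0, with more negative meaning a
  worse steric overlap; it is an ordinal stand-in for a contact-dot score and
  shares only the sign convention with such scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable

import numpy as np
from scipy.spatial import cKDTree

from ._sidechain import ROTAMER_CHIS, SIDECHAIN_TEMPLATES

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import TopologyAnnotation

# Bondi-style van der Waals radii, angstroms.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_NEIGHBOUR_RADIUS = 5.0


class InsufficientAtomsError(ValueError):
    """Raised when a model lacks the atoms an operation requires."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    radius: float

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    index: int
    aa: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinModel:
    """Single-chain structure with per-atom coordinates and vdW radii."""

    residues: list[Residue]
    chain_id: str = "A"
    _by_index: dict[int, Residue] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        indices = [r.index for r in self.residues]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValueError("residue indices must be strictly increasing")
        self._by_index = {r.index: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> Residue | None:
        return self._by_index.get(index)

    def atom_coords(self) -> np.ndarray:
        return np.array(
            [a.xyz for r in self.residues for a in r.atoms], dtype=float
        ).reshape(-1, 3)

    def sequence(self) -> dict[int, str]:
        return {r.index: r.aa for r in self.residues}


class Side(str, Enum):
    INTRACELLULAR = "intracellular"
    EXTRACELLULAR = "extracellular"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class SidednessResult:
    side: Side
    angle_deg: float | None


@dataclass(frozen=True)
class ClashResult:
    score: float
    rotamer_id: int
    n_overlapping_atoms: int


# ---------------------------------------------------------------------------
# geometry


def centre_of_mass(model: ProteinModel) -> np.ndarray:
    """Unweighted mean of all atom coordinates."""
    coords = model.atom_coords()
    if coords.size == 0:
        raise ValueError("model has no atoms")
    return coords.mean(axis=0)


def in_modelled_region(topology: "TopologyAnnotation", position: int) -> bool:
    return any(lo <= position <= hi for lo, hi in topology.modelled_ranges)


def sidedness(
    model: ProteinModel, topology: "TopologyAnnotation", position: int
) -> SidednessResult:
    """Intracellular/extracellular assignment of a residue.

    The angle at the centre of mass between the vectors to the query Calpha
    and to the reference Calpha is computed; < 90 deg counts as intracellular.
    CTD and unmodelled positions are excluded.
    """
    lo, hi = topology.ctd_range
    if lo <= position <= hi or not in_modelled_region(topology, position):
        return SidednessResult(Side.EXCLUDED, None)
    com = centre_of_mass(model)
    query = model.residue(position)
    ref = model.residue(topology.reference_residue)
    if query is None or query.atom("CA") is None:
        raise InsufficientAtomsError(f"no CA atom at position {position}")
    if ref is None or ref.atom("CA") is None:
        raise InsufficientAtomsError(
            f"no CA atom at reference residue {topology.reference_residue}"
        )
    v1 = query.atom("CA").coords - com
    v2 = ref.atom("CA").coords - com
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate geometry: CA coincides with centre of mass")
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    side = Side.INTRACELLULAR if angle < 90.0 else Side.EXTRACELLULAR
    return SidednessResult(side, angle)


# ---------------------------------------------------------------------------
# NeRF side-chain construction


def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float
) -> np.ndarray:
    """Place a new atom from three reference atoms and internal coordinates.

    ``bond`` = |c - new|, ``angle_deg`` = angle(b, c, new),
    ``torsion_deg`` = dihedral(a, b, c, new).
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= norm
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def rotamer_count(alt_aa: str) -> int:
    return len(ROTAMER_CHIS[alt_aa])


def place_sidechain(
    model: ProteinModel, position: int, alt_aa: str, rotamer_id: int
) -> list[Atom]:
    """Build the mutant side chain at ``position`` for one canonical rotamer.

    Backbone atoms are untouched; glycine yields an empty set.  The template
    geometry is idealized, so the placement is a conformer model rather than a
    refined structure.
    """
    if alt_aa not in SIDECHAIN_TEMPLATES:
        raise ValueError(f"unknown amino acid {alt_aa!r}")
    chis = ROTAMER_CHIS[alt_aa]
    if not 0 <= rotamer_id < len(chis):
        raise ValueError(f"rotamer_id {rotamer_id} out of range for {alt_aa}")
    residue = model.residue(position)
    if residue is None:
        raise ValueError(f"no residue {position} in model")
    placed: dict[str, np.ndarray] = {}
    for name in ("N", "CA", "C"):
        atom = residue.atom(name)
        if atom is None:
            raise InsufficientAtomsError(
                f"backbone atom {name} missing at position {position}"
            )
        placed[name] = atom.coords
    chi = chis[rotamer_id]
    out: list[Atom] = []
    for name, element, (ra, rb, rc), bond, angle, torsion in SIDECHAIN_TEMPLATES[alt_aa]:
        if isinstance(torsion, tuple):
            _, chi_i, offset = torsion
            torsion_deg = chi[chi_i - 1] + offset
        else:
            torsion_deg = torsion
        xyz = nerf_place(placed[ra], placed[rb], placed[rc], bond, angle, torsion_deg)
        placed[name] = xyz
        out.append(Atom(name, element, tuple(float(v) for v in xyz), VDW_RADII[element]))
    return out


# ---------------------------------------------------------------------------
# clash scoring


class ClashEnvironment:
    """Reusable neighbour index over a model's atoms for repeated clash calls."""

    def __init__(self, model: ProteinModel):
        self.model = model
        coords, radii, res_idx = [], [], []
        for r in model.residues:
            for a in r.atoms:
                coords.append(a.xyz)
                radii.append(a.radius)
                res_idx.append(r.index)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(radii, dtype=float)
        self.res_idx = np.asarray(res_idx, dtype=int)
        self.tree = cKDTree(self.coords) if len(self.coords) else None
        self.max_radius = float(self.radii.max()) if len(self.radii) else 0.0


def _rotamer_penalty(
    env: ClashEnvironment,
    position: int,
    sidechain: Iterable[Atom],
    neighbour_radius: float,
) -> tuple[float, int]:
    penalty = 0.0
    overlapping: set[int] = set()
    for atom in sidechain:
        q = atom.coords
        idx = env.tree.query_ball_point(q, neighbour_radius + env.max_radius)
        if not idx:
            continue
        idx = np.asarray(idx)
        idx = idx[env.res_idx[idx] != position]
        if idx.size == 0:
            continue
        d = np.linalg.norm(env.coords[idx] - q, axis=1)
        overlap = atom.radius + env.radii[idx] - d
        hit = overlap > 0
        penalty += float(np.sum(overlap[hit] ** 2))
        overlapping.update(idx[hit].tolist())
    return penalty, len(overlapping)


def clash_score(
    model: ProteinModel,
    position: int,
    alt_aa: str,
    neighbour_radius: float = DEFAULT_NEIGHBOUR_RADIUS,
    scale: float = 1.0,
    environment: ClashEnvironment | None = None,
) -> ClashResult:
    """Minimal sphere-overlap penalty over canonical rotamers, negated.

    For each rotamer the penalty is sum over pairs (mutant side-chain atom,
    atom of any other residue) of max(0, r_i + r_j - d)^2; the reported score
    is -scale * min-over-rotamers, and the minimizing rotamer is returned.
    """
    env = environment if environment is not None else ClashEnvironment(model)
    if env.tree is None:
        raise InsufficientAtomsError("model has no atoms")
    best: tuple[float, int, int] | None = None
    for rot_id in range(rotamer_count(alt_aa)):
        sidechain = place_sidechain(model, position, alt_aa, rot_id)
        penalty, n_overlap = _rotamer_penalty(env, position, sidechain, neighbour_radius)
        if best is None or penalty < best[0]:
            best = (penalty, rot_id, n_overlap)
    penalty, rot_id, n_overlap = best
    score = -scale * penalty if penalty > 0 else 0.0
    return ClashResult(score=score, rotamer_id=rot_id, n_overlapping_atoms=n_overlap)
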