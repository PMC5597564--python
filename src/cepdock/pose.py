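"""Molecular pose model: structures, the docking genome, and its kinematic decoder.

A ligand pose is encoded as a real vector of ``7 + T`` genes:

* genes 0-2 — rigid-body translation (Å),
* genes 3-6 — orientation as a unit quaternion ``(w, x, y, z)``,
* genes 7.. — ``T`` torsion angles (radians, wrapped to ``(-pi, pi]``),
  one per rotatable bond of the ligand's torsion tree.

Decoding applies the torsions depth-first from the root block outward (the
order the rotatable-bond tree is declared in), then rotates the whole ligand
about the centroid of its root-block atoms by the quaternion, and finally
translates.  Bond lengths and every angle not spanning a rotatable bond are
therefore exactly those of the template conformation.

Pose accuracy is judged by heavy-atom RMSD computed in the receptor frame
(no superposition), with the conventional ``< 2.0 Å`` validity cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "Atom",
    "TorsionNode",
    "LigandTopology",
    "ReceptorModel",
    "Genome",
    "QUATERNION_TOL",
    "RMSD_VALIDITY_CUTOFF",
    "decode",
    "rmsd",
    "is_valid_pose",
    "wrap_angle",
    "random_unit_quaternion",
    "quaternion_to_matrix",
]

#: tolerance for quaternion unit-norm checks; beyond it decode renormalizes
#: with a warning.
QUATERNION_TOL = 1e-9

#: a docked pose is counted valid iff its heavy-atom RMSD to the reference
#: pose is strictly below this value (Å).
RMSD_VALIDITY_CUTOFF = 2.0


@dataclass(frozen=True)
class Atom:
    """One atom: index, element, AutoDock type code, coordinates (Å), charge (e)."""

    id: int
    element: str
    type_code: str
    coords: tuple[float, float, float]
    charge: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.id}: non-finite coordinates {self.coords}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "HD", "HS")


@dataclass(frozen=True)
class TorsionNode:
    """One rotatable bond: rotation axis ``axis_a -> axis_b`` plus the set of
    atom indices distal to the axis that the torsion moves.  Axis atoms are
    never part of ``moved``."""

    axis_a: int
    axis_b: int
    moved: frozenset[int]

    def __post_init__(self) -> None:
        if self.axis_a in self.moved or self.axis_b in self.moved:
            raise ValueError("torsion moved-set must not contain its axis atoms")


@dataclass(frozen=True)
class LigandTopology:
    """Immutable ligand template: atoms in their reference conformation,
    covalent bonds, and the rooted rotatable-bond tree.

    ``torsion_nodes`` are stored in depth-first order from the root block;
    torsion gene ``k`` drives ``torsion_nodes[k]``.  ``root_atoms`` are the
    indices of the rigid root block (the whole-body rotation pivot is their
    centroid).  ``torsdof`` is the declared torsional degree-of-freedom count
    used by the torsional penalty (defaults to ``n_torsions``).
    """

    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int], ...]
    torsion_nodes: tuple[TorsionNode, ...] = ()
    root_atoms: tuple[int, ...] = ()
    torsdof: int | None = None
    name: str = "ligand"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        ids = [a.id for a in self.atoms]
        if ids != list(range(n)):
            raise ValueError("atom ids must be 0..n-1 in order")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bad bond ({i}, {j})")
        seen_moved: set[int] = set()
        for node in self.torsion_nodes:
            if not node.moved:
                raise ValueError("torsion with empty moved-set")
            if not node.moved < set(range(n)):
                raise ValueError("torsion moved-set out of range")
        if not self.root_atoms and n:
            object.__setattr__(self, "root_atoms", tuple(range(n)))
        # root atoms must be proximal: no torsion may move a root atom
        root = set(self.root_atoms)
        for node in self.torsion_nodes:
            if node.moved & root:
                raise ValueError("torsion moves a root-block atom")
        del seen_moved

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_torsions(self) -> int:
        return len(self.torsion_nodes)

    @property
    def genome_length(self) -> int:
        return 7 + self.n_torsions

    @cached_property
    def _template(self) -> np.ndarray:
        arr = np.array([a.coords for a in self.atoms], dtype=float)
        arr.flags.writeable = False
        return arr

    @property
    def template_coords(self) -> np.ndarray:
        return self._template.copy()

    @cached_property
    def root_centroid(self) -> np.ndarray:
        """Whole-body rotation pivot: centroid of the root-block atoms."""
        return self._template[list(self.root_atoms)].mean(axis=0)

    @cached_property
    def _moved_index_arrays(self) -> tuple[np.ndarray, ...]:
        return tuple(
            np.fromiter(node.moved, dtype=int) for node in self.torsion_nodes
        )

    @cached_property
    def heavy_atom_indices(self) -> np.ndarray:
        return np.array(
            [a.id for a in self.atoms if not a.is_hydrogen], dtype=int
        )


@dataclass(frozen=True)
class ReceptorModel:
    """Rigid receptor: atoms plus the rectangular search box
    ``(center, half_extent)`` in Å that bounds ligand translations."""

    atoms: tuple[Atom, ...]
    bounding_box: tuple[tuple[float, float, float], tuple[float, float, float]]
    name: str = "receptor"

    def __post_init__(self) -> None:
        _, half = self.bounding_box
        if not all(h > 0 for h in half):
            raise ValueError("search box must have positive half-extents")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def box_center(self) -> np.ndarray:
        return np.asarray(self.bounding_box[0], dtype=float)

    @property
    def box_half_extent(self) -> np.ndarray:
        return np.asarray(self.bounding_box[1], dtype=float)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# genome


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to the half-open interval ``(-pi, pi]``."""
    wrapped = -((-np.asarray(theta) + np.pi) % (2.0 * np.pi) - np.pi)
    return float(wrapped) if np.isscalar(theta) else wrapped


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation quaternion (w, x, y, z), Shoemake's method."""
    u1, u2, u3 = rng.random(3)
    a, b = math.sqrt(1.0 - u1), math.sqrt(u1)
    return np.array(
        [
            b * math.cos(2 * math.pi * u3),
            a * math.sin(2 * math.pi * u2),
            a * math.cos(2 * math.pi * u2),
            b * math.sin(2 * math.pi * u3),
        ]
    )


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion ``(w, x, y, z)``."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class Genome:
    """Real-coded pose genome: translation (Å), unit quaternion ``(w,x,y,z)``,
    and ``T`` torsion angles in ``(-pi, pi]``."""

    translation: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(4)
        self.torsions = np.asarray(self.torsions, dtype=float).reshape(-1)

    @classmethod
    def identity(cls, n_torsions: int = 0) -> "Genome":
        return cls(np.zeros(3), np.array([1.0, 0, 0, 0]), np.zeros(n_torsions))

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "Genome":
        vec = np.asarray(vec, dtype=float)
        if vec.size < 7:
            raise ValueError(f"genome vector needs >= 7 genes, got {vec.size}")
        return cls(vec[:3], vec[3:7], vec[7:])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.orientation, self.torsions])

    def __len__(self) -> int:
        return 7 + self.torsions.size


def _as_genome(genome: Genome | np.ndarray) -> Genome:
    return genome if isinstance(genome, Genome) else Genome.from_vector(genome)


def _rotate_about_axis(
    coords: np.ndarray, idx: np.ndarray, p0: np.ndarray, p1: np.ndarray, angle: float
) -> None:
    """In-place Rodrigues rotation of ``coords[idx]`` about the line p0->p1."""
    axis = p1 - p0
    norm = math.sqrt(axis @ axis)
    if norm < 1e-12:
        raise ValueError("degenerate torsion axis (coincident atoms)")
    k = axis / norm
    v = coords[idx] - p0
    c, s = math.cos(angle), math.sin(angle)
    # cross(k, v) row-wise, unrolled (np.cross is slow for small arrays)
    kxv = np.empty_like(v)
    kxv[:, 0] = k[1] * v[:, 2] - k[2] * v[:, 1]
    kxv[:, 1] = k[2] * v[:, 0] - k[0] * v[:, 2]
    kxv[:, 2] = k[0] * v[:, 1] - k[1] * v[:, 0]
    coords[idx] = (v * c + kxv * s + ((v @ k) * (1.0 - c))[:, None] * k) + p0


def decode(genome: Genome | np.ndarray, topo: LigandTopology) -> np.ndarray:
    """Realize a genome as Cartesian ligand coordinates (n_atoms x 3, Å).

    Pure and deterministic: torsions are applied depth-first from the root
    outward (each rotation uses the already-torsioned axis positions), then
    the whole ligand is rotated about the root-block centroid by the
    quaternion, then translated.
    """
    g = _as_genome(genome)
    if len(g) != topo.genome_length:
        raise ValueError(
            f"genome length {len(g)} != 7 + {topo.n_torsions} torsions"
        )
    q = g.orientation
    qnorm = np.linalg.norm(q)
    if qnorm == 0.0:
        raise ValueError("zero quaternion")
    if abs(qnorm - 1.0) > QUATERNION_TOL:
        warnings.warn(
            f"non-unit quaternion (|q| = {qnorm:.6g}); renormalizing",
            RuntimeWarning,
            stacklevel=2,
        )
    q = q / qnorm

    coords = topo.template_coords
    moved_arrays = topo._moved_index_arrays
    for k, node in enumerate(topo.torsion_nodes):
        angle = float(g.torsions[k])
        if angle != 0.0:
            _rotate_about_axis(
                coords, moved_arrays[k], coords[node.axis_a], coords[node.axis_b],
                angle,
            )
    pivot = topo.root_centroid
    coords = (coords - pivot) @ quaternion_to_matrix(q).T + pivot + g.translation
    return coords


# ---------------------------------------------------------------------------
# RMSD


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation between two equally ordered coordinate sets,
    computed in a common (receptor) frame with no superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def ligand_rmsd(
    topo: LigandTopology, coords_a: np.ndarray, coords_b: np.ndarray
) -> float:
    """Heavy-atom RMSD between two conformations of the same ligand."""
    heavy = topo.heavy_atom_indices
    return rmsd(np.asarray(coords_a)[heavy], np.asarray(coords_b)[heavy])


def is_valid_pose(rmsd_value: float) -> bool:
    """A docking counts as valid iff RMSD is strictly below 2.0 Å."""
    if rmsd_value < 0:
        raise ValueError("RMSD cannot be negative")
    return rmsd_value < RMSD_VALIDITY_CUTOFF
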