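"""Synthetic trajectories and mixture samples with known ground truth.

Real inputs to the tuning workflow come from MD or normal-mode sampling
of a molecule's energy landscape. For testing, this module emulates
such trajectories for small molecules (2–5 atoms, tree-shaped bond
topology): each frame draws every bond length and every listed bond
angle independently from a Gaussian about its mean, then rebuilds
Cartesian coordinates by natural-extension-reference-frame (NeRF)
placement, keeping unlisted internal coordinates at their equilibrium
values. The generated cluster structure (per-bond and per-angle μ, σ,
optional two-conformer switching) is therefore known exactly by
construction and serves as the oracle for every downstream stage.

A synthetic per-atom target property — a declared smooth function of
local internal coordinates, rigid-motion invariant by construction —
stands in for quantum-derived atomic properties in end-to-end
feature-quality tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .mixture import GaussianComponent, sample_components
from .trajectory import Frame, Trajectory

__all__ = [
    "BondTerm",
    "AngleTerm",
    "ConformerSwitch",
    "OscillatorSpec",
    "LinearBondRule",
    "generate_trajectory",
    "generate_mixture_samples",
    "synthetic_atomic_property",
]


@dataclass(frozen=True)
class BondTerm:
    """Oscillating bond (i, j): length ~ N(mean, σ²). mean=None → equilibrium."""

    i: int
    j: int
    mean: float | None
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"bond sigma must be positive, got {self.sigma}")
        if self.i == self.j:
            raise ValueError("a bond needs two distinct atoms")


@dataclass(frozen=True)
class AngleTerm:
    """Oscillating angle a–vertex–b (radians): θ ~ N(mean, σ²)."""

    a: int
    vertex: int
    b: int
    mean: float | None
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"angle sigma must be positive, got {self.sigma}")
        if len({self.a, self.vertex, self.b}) != 3:
            raise ValueError("an angle needs three distinct atoms")


@dataclass(frozen=True)
class ConformerSwitch:
    """Alternative equilibrium geometry visited with the given per-frame probability."""

    geometry: Frame
    probability: float

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValueError(f"switch probability must lie in [0, 1], got {self.probability}")


@dataclass(frozen=True)
class OscillatorSpec:
    """Ground-truth description of a small oscillating molecule."""

    geometry: Frame
    bonds: tuple[BondTerm, ...]
    angles: tuple[AngleTerm, ...] = ()
    conformer: ConformerSwitch | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bonds", tuple(self.bonds))
        object.__setattr__(self, "angles", tuple(self.angles))
        n = self.geometry.n_atoms
        if self.conformer is not None and self.conformer.geometry.elements != self.geometry.elements:
            raise ValueError("conformer geometry must share the primary topology")
        _build_tree(self.bonds, n)  # validates tree topology eagerly


def _build_tree(bonds: Sequence[BondTerm], n_atoms: int) -> dict[int, list[int]]:
    """Adjacency of the bond graph; error unless it is a tree on ≤5 atoms."""
    if n_atoms > 5:
        raise ValueError(f"supported molecules have at most 5 atoms, got {n_atoms}")
    if len(bonds) != n_atoms - 1:
        raise ValueError(
            f"{n_atoms} atoms require {n_atoms - 1} bonds for a tree topology, "
            f"got {len(bonds)}"
        )
    adj: dict[int, list[int]] = {i: [] for i in range(n_atoms)}
    for b in bonds:
        if not (0 <= b.i < n_atoms and 0 <= b.j < n_atoms):
            raise ValueError(f"bond ({b.i}, {b.j}) references a missing atom")
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    # connectivity check (tree ⟺ connected with n−1 edges)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != n_atoms:
        raise ValueError("bond graph is not connected; only tree topologies are supported")
    return adj


def _dihedral(coords: np.ndarray, s: int, q: int, p: int, x: int) -> float:
    """Signed dihedral s–q–p–x in radians."""
    b1 = coords[q] - coords[s]
    b2 = coords[p] - coords[q]
    b3 = coords[x] - coords[p]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def _nerf_place(
    pos_s: np.ndarray, pos_q: np.ndarray, pos_p: np.ndarray,
    r: float, theta: float, phi: float,
) -> np.ndarray:
    """Place a new atom at distance r from p, angle θ at p w.r.t. q, dihedral φ."""
    bc = pos_p - pos_q
    bc = bc / np.linalg.norm(bc)
    ab = pos_q - pos_s
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:  # collinear reference; pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n = n / norm
    m = np.cross(n, bc)
    d = np.array(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ]
    )
    return pos_p + d[0] * bc + d[1] * m + d[2] * n


def _construction_order(adj: dict[int, list[int]]) -> list[tuple[int, int | None]]:
    """BFS (atom, parent) order rooted at atom 0."""
    order: list[tuple[int, int | None]] = [(0, None)]
    seen = {0}
    queue = [0]
    while queue:
        node = queue.pop(0)
        for nb in sorted(adj[node]):
            if nb not in seen:
                seen.add(nb)
                order.append((nb, node))
                queue.append(nb)
    return order


def _reconstruct(
    geometry: Frame,
    order: list[tuple[int, int | None]],
    parents: dict[int, int | None],
    bond_length: dict[tuple[int, int], float],
    angle_value: Callable[[int, int, int], float],
) -> np.ndarray:
    """NeRF rebuild in BFS order; dihedrals fixed at their equilibrium values."""
    eq = geometry.coordinates
    n = geometry.n_atoms
    coords = np.zeros((n, 3))
    placed: list[int] = []
    for atom, parent in order:
        if parent is None:
            coords[atom] = 0.0
        elif len(placed) == 1:
            r = bond_length[_key(atom, parent)]
            coords[atom] = coords[parent] + np.array([r, 0.0, 0.0])
        else:
            p = parent
            # angle reference q: grandparent if placed, else a placed sibling
            gp = parents.get(p)
            if gp is not None and gp in placed:
                q = gp
            else:
                q = next(a for a in placed if a != p and parents.get(a) == p)
            # dihedral reference s: any placed atom ≠ p, q (equilibrium-consistent)
            s = next((a for a in placed if a not in (p, q)), None)
            r = bond_length[_key(atom, p)]
            theta = angle_value(q, p, atom)
            if s is None:
                phi = 0.0  # plane is arbitrary for the third atom (rigid freedom)
                pos_s = coords[q] + np.array([0.0, 0.0, 1.0])
            else:
                phi = _dihedral(eq, s, q, p, atom)
                pos_s = coords[s]
            coords[atom] = _nerf_place(pos_s, coords[q], coords[p], r, theta, phi)
        placed.append(atom)
    return coords


def _key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def generate_trajectory(
    spec: OscillatorSpec, n_frames: int, seed: int | None = None
) -> Trajectory:
    """Sample ``n_frames`` snapshots of the oscillating molecule.

    Per frame: pick the conformer (independent Bernoulli draw when a
    switch is configured), draw each bond length and each listed angle
    from its Gaussian, and rebuild Cartesians. Unlisted angles and all
    dihedrals stay at the chosen conformer's equilibrium values. Bond
    and angle means apply to the primary geometry; frames visiting the
    alternative conformer oscillate about its own equilibrium internals
    with the same σ.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    adj = _build_tree(spec.bonds, spec.geometry.n_atoms)
    order = _construction_order(adj)
    parents = {atom: parent for atom, parent in order}

    def _angle_term(q: int, p: int, x: int) -> AngleTerm | None:
        for t in spec.angles:
            if t.vertex == p and {t.a, t.b} == {q, x}:
                return t
        return None

    frames: list[Frame] = []
    for _ in range(n_frames):
        use_alt = (
            spec.conformer is not None
            and rng.random() < spec.conformer.probability
        )
        geometry = spec.conformer.geometry if use_alt else spec.geometry

        lengths: dict[tuple[int, int], float] = {}
        for b in spec.bonds:
            eq_len = geometry.distance(b.i, b.j)
            base = b.mean if (b.mean is not None and not use_alt) else eq_len
            lengths[_key(b.i, b.j)] = base + rng.normal(0.0, b.sigma)

        def angle_value(q: int, p: int, x: int) -> float:
            term = _angle_term(q, p, x)
            eq_angle = geometry.angle(q, p, x)
            if term is None:
                return eq_angle
            base = term.mean if (term.mean is not None and not use_alt) else eq_angle
            return base + rng.normal(0.0, term.sigma)

        coords = _reconstruct(geometry, order, parents, lengths, angle_value)
        frames.append(Frame(spec.geometry.elements, coords))
    return Trajectory(tuple(frames), source_path="<synthetic>", stride_applied=1)


def generate_mixture_samples(
    components: Sequence[GaussianComponent], n: int, seed: int = 0
) -> np.ndarray:
    """Ancestral draws from ground-truth components (independent of any fit)."""
    return sample_components(components, n, seed)


@dataclass(frozen=True)
class LinearBondRule:
    """Synthetic atomic property: linear in one bond-length deviation.

    value(atom) = intercept + slope · (r(atom, neighbor) − reference_length)
    """

    neighbor: int
    reference_length: float
    slope: float = 1.0
    intercept: float = 0.0


def synthetic_atomic_property(
    frame: Frame,
    atom_index: int,
    rule: LinearBondRule | Callable[[Frame, int], float],
) -> float:
    """Evaluate a declared smooth local rule (rigid-motion invariant)."""
    if isinstance(rule, LinearBondRule):
        r = frame.distance(atom_index, rule.neighbor)
        return rule.intercept + rule.slope * (r - rule.reference_length)
    return float(rule(frame, atom_index))
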