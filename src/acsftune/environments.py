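"""Pooling of element-typed radial and angular environment samples.

For every center element the pairwise distances r_ij (radial) and the
triples (r_ij, r_ik, θ_ijk) (angular) are collected across all frames of
a trajectory, truncated at a cutoff radius r_c. Two cutoff schemes are
supported: a hard truncation, and a soft scheme in which each sample
carries the value of the cosine cutoff kernel

    f_c(r) = 0.5 · (cos(π r / r_c) + 1)   for r ≤ r_c, else 0

as a weight into the downstream (weighted) mixture fit.

Angular triples are deduplicated: for a trio centred on atom i, only the
unordered neighbor set {j, k} is kept, with a deterministic canonical
(j, k) ordering — the inner angle depends on the origin atom only, so
the three orderings of a trio would otherwise triple-count it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Literal

import numpy as np
import pandas as pd

from .trajectory import Frame, Trajectory

__all__ = [
    "CutoffSpec",
    "RadialSampleSet",
    "AngularSampleSet",
    "cutoff_value",
    "collect_radial",
    "collect_angular",
]


@dataclass(frozen=True)
class CutoffSpec:
    """Cutoff radius r_c (Å) and scheme (``soft`` cosine or ``hard`` truncation)."""

    r_c: float
    scheme: Literal["soft", "hard"] = "hard"

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError(f"cutoff radius must be positive, got {self.r_c}")
        if self.scheme not in ("soft", "hard"):
            raise ValueError(f"cutoff scheme must be 'soft' or 'hard', got {self.scheme!r}")


def cutoff_value(r, spec: CutoffSpec):
    """Evaluate the cutoff kernel at distance(s) ``r`` (Å). Vectorized.

    Soft scheme: 0.5·(cos(π r / r_c) + 1) inside r_c, 0 beyond.
    Hard scheme: indicator of r ≤ r_c.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    inside = r <= spec.r_c
    if spec.scheme == "hard":
        out = inside.astype(float)
    else:
        out = np.where(inside, 0.5 * (np.cos(np.pi * r / spec.r_c) + 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class RadialSampleSet:
    """Pooled r_ij samples for one (center element → neighbor element) pair."""

    center_element: str
    neighbor_element: str
    cutoff: CutoffSpec
    distances: np.ndarray = field(default_factory=lambda: np.empty(0))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    frame_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    atom_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __len__(self) -> int:
        return len(self.distances)

    def to_table(self) -> pd.DataFrame:
        """One sample per row: frame index, atom indices, distance, weight."""
        return pd.DataFrame(
            {
                "frame": self.frame_indices,
                "atom_i": self.atom_pairs[:, 0],
                "atom_j": self.atom_pairs[:, 1],
                "r_ij": self.distances,
                "weight": self.weights,
            }
        )

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


@dataclass
class AngularSampleSet:
    """Pooled (r_ij, r_ik, θ_ijk) samples for one center and unordered neighbor pair.

    ``triples`` has shape (n, 3) with θ in radians; canonical (j, k)
    ordering is applied (see :func:`collect_angular`).
    """

    center_element: str
    neighbor_pair: tuple[str, str]
    cutoff: CutoffSpec
    triples: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    frame_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    atom_triples: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))

    def __len__(self) -> int:
        return len(self.triples)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_indices,
                "atom_i": self.atom_triples[:, 0],
                "atom_j": self.atom_triples[:, 1],
                "atom_k": self.atom_triples[:, 2],
                "r_ij": self.triples[:, 0],
                "r_ik": self.triples[:, 1],
                "theta_deg": np.degrees(self.triples[:, 2]),
                "weight": self.weights,
            }
        )

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def _require_element(traj: Trajectory, element: str) -> None:
    if element not in traj.elements:
        raise ValueError(f"element {element!r} is absent from the trajectory topology")


def collect_radial(
    traj: Trajectory,
    center_element: str,
    neighbor_element: str,
    spec: CutoffSpec,
) -> RadialSampleSet:
    """Pool r_ij over every (frame, ordered pair i→j) within the cutoff.

    Both ordered directions of a homonuclear pair are counted, one
    sample each, since each atom in turn acts as the center.
    """
    _require_element(traj, center_element)
    _require_element(traj, neighbor_element)
    elements = np.asarray(traj.elements)
    centers = np.flatnonzero(elements == center_element)
    neighbors = np.flatnonzero(elements == neighbor_element)

    dist_chunks, frame_chunks, pair_chunks = [], [], []
    for f_idx, frame in enumerate(traj):
        delta = frame.coordinates[centers, None, :] - frame.coordinates[None, neighbors, :]
        dmat = np.linalg.norm(delta, axis=-1)
        ci, nj = np.meshgrid(centers, neighbors, indexing="ij")
        keep = (ci != nj) & (dmat <= spec.r_c)
        dist_chunks.append(dmat[keep])
        frame_chunks.append(np.full(int(keep.sum()), f_idx))
        pair_chunks.append(np.column_stack([ci[keep], nj[keep]]))

    distances = np.concatenate(dist_chunks) if dist_chunks else np.empty(0)
    weights = (
        cutoff_value(distances, spec)
        if spec.scheme == "soft"
        else np.ones_like(distances)
    )
    return RadialSampleSet(
        center_element=center_element,
        neighbor_element=neighbor_element,
        cutoff=spec,
        distances=distances,
        weights=np.atleast_1d(weights),
        frame_indices=np.concatenate(frame_chunks).astype(int)
        if frame_chunks
        else np.empty(0, dtype=int),
        atom_pairs=np.concatenate(pair_chunks)
        if pair_chunks
        else np.empty((0, 2), dtype=int),
    )


def canonical_neighbor_order(
    frame: Frame, i: int, j: int, k: int
) -> tuple[int, int]:
    """Deterministic (j, k) role assignment for an unordered neighbor set.

    When the neighbor elements differ, j is the alphabetically first
    element; when equal, j is the closer neighbor (tie → smaller atom
    index).
    """
    ej, ek = frame.elements[j], frame.elements[k]
    if ej != ek:
        return (j, k) if ej < ek else (k, j)
    rj, rk = frame.distance(i, j), frame.distance(i, k)
    if rj != rk:
        return (j, k) if rj < rk else (k, j)
    return (j, k) if j < k else (k, j)


def _angular_pairs(elements: np.ndarray, i: int, pair: tuple[str, str]):
    """Unordered neighbor index sets {j, k} around center i with the given typing."""
    a, b = pair
    if a == b:
        idx = np.flatnonzero(elements == a)
        idx = idx[idx != i]
        yield from combinations(idx.tolist(), 2)
    else:
        ja = np.flatnonzero(elements == a)
        jb = np.flatnonzero(elements == b)
        for j, k in product(ja.tolist(), jb.tolist()):
            if j != i and k != i and j != k:
                yield (j, k)


def collect_angular(
    traj: Trajectory,
    center_element: str,
    neighbor_pair: tuple[str, str],
    spec: CutoffSpec,
) -> AngularSampleSet:
    """Pool (r_ij, r_ik, θ_ijk) over frames, centers and unordered neighbor sets.

    One sample per (frame, center i, unordered {j, k}) with both
    neighbors inside r_c; θ is the inner angle at i. Under the soft
    scheme the weight is f_c(r_ij)·f_c(r_ik).
    """
    _require_element(traj, center_element)
    for el in neighbor_pair:
        _require_element(traj, el)
    pair = tuple(sorted(neighbor_pair))
    elements = np.asarray(traj.elements)
    centers = np.flatnonzero(elements == center_element)

    triples, weights, frame_ids, atom_ids = [], [], [], []
    for f_idx, frame in enumerate(traj):
        for i in centers.tolist():
            for j0, k0 in _angular_pairs(elements, i, pair):
                j, k = canonical_neighbor_order(frame, i, j0, k0)
                rij, rik = frame.distance(i, j), frame.distance(i, k)
                if rij > spec.r_c or rik > spec.r_c:
                    continue
                theta = frame.angle(j, i, k)
                triples.append((rij, rik, theta))
                if spec.scheme == "soft":
                    weights.append(cutoff_value(rij, spec) * cutoff_value(rik, spec))
                else:
                    weights.append(1.0)
                frame_ids.append(f_idx)
                atom_ids.append((i, j, k))

    return AngularSampleSet(
        center_element=center_element,
        neighbor_pair=pair,
        cutoff=spec,
        triples=np.asarray(triples).reshape(-1, 3),
        weights=np.asarray(weights, dtype=float),
        frame_indices=np.asarray(frame_ids, dtype=int),
        atom_triples=np.asarray(atom_ids, dtype=int).reshape(-1, 3),
    )
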