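"""Evaluation of symmetry functions on structures and AEV assembly.

Per-atom Atomic Environment Vectors (AEVs) are the concatenated
activations of a center element's symmetry-function set. All
activations are sums of non-negative kernel terms, hence non-negative;
they are invariant under rigid rotation, translation, and permutation
of like-element atoms by construction.

Feature post-processing follows the usual descriptor pipeline: min–max
normalization with the column minima/maxima taken from a designated
training subset only (values outside the training range map outside
[0, 1]; no clipping), and pruning of "dead" functions whose activation
never exceeds a threshold on the training rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations, product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .builder import AngularSF, RadialSF, SFSet
from .environments import cutoff_value
from .trajectory import Frame

__all__ = [
    "FeatureMatrix",
    "NormalizationRecord",
    "eval_radial_sf",
    "eval_angular_sf",
    "build_feature_matrix",
    "build_element_matrices",
    "fit_normalizer",
    "apply_normalizer",
    "prune_dead",
]


@dataclass(frozen=True)
class NormalizationRecord:
    """Per-column min/max learned from a training row subset."""

    col_min: np.ndarray
    col_max: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"col_min": self.col_min.tolist(), "col_max": self.col_max.tolist()},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationRecord":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["col_min"]), np.asarray(d["col_max"]))


@dataclass
class FeatureMatrix:
    """Per-(frame, atom) symmetry-function activations.

    ``values`` has one row per (frame, atom) and one column per symmetry
    function in SFSet order; ``row_index`` carries (frame index, atom
    index, element) per row and ``column_labels`` the SF identities.
    """

    values: np.ndarray
    row_index: list[tuple[int, int, str]]
    column_labels: list[str]
    normalization: NormalizationRecord | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        idx = pd.DataFrame(self.row_index, columns=["frame", "atom", "element"])
        return pd.concat(
            [idx, pd.DataFrame(self.values, columns=self.column_labels)], axis=1
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _neighbor_distances(frame: Frame, i: int, element: str) -> np.ndarray:
    idx = [j for j, el in enumerate(frame.elements) if el == element and j != i]
    if not idx:
        return np.empty(0)
    return np.linalg.norm(frame.coordinates[idx] - frame.coordinates[i], axis=1)


def eval_radial_sf(frame: Frame, atom_index: int, sf: RadialSF) -> float:
    """Σ_j exp(−η(r_ij − r_s)²)·f_c(r_ij) over neighbors of the typed element."""
    if frame.elements[atom_index] != sf.center_element:
        raise ValueError(
            f"atom {atom_index} is {frame.elements[atom_index]}, "
            f"but the function is centered on {sf.center_element}"
        )
    r = _neighbor_distances(frame, atom_index, sf.neighbor_element)
    if r.size == 0:
        return 0.0
    fc = cutoff_value(r, sf.cutoff)
    return float(np.sum(np.exp(-sf.eta * (r - sf.r_s) ** 2) * fc))


def _unordered_pairs(frame: Frame, i: int, pair: tuple[str, str]):
    a, b = sorted(pair)
    if a == b:
        idx = [j for j, el in enumerate(frame.elements) if el == a and j != i]
        yield from combinations(idx, 2)
    else:
        ja = [j for j, el in enumerate(frame.elements) if el == a and j != i]
        jb = [j for j, el in enumerate(frame.elements) if el == b and j != i]
        for j, k in product(ja, jb):
            if j != k:
                yield (j, k)


def eval_angular_sf(frame: Frame, atom_index: int, sf: AngularSF) -> float:
    """Sum of the variant's kernel over canonical unordered neighbor pairs."""
    if frame.elements[atom_index] != sf.center_element:
        raise ValueError(
            f"atom {atom_index} is {frame.elements[atom_index]}, "
            f"but the function is centered on {sf.center_element}"
        )
    total = 0.0
    for j, k in _unordered_pairs(frame, atom_index, sf.neighbor_pair):
        rij = frame.distance(atom_index, j)
        rik = frame.distance(atom_index, k)
        theta = frame.angle(j, atom_index, k)
        if sf.variant == "heavily_modified":
            angular = (1.0 + np.cos(theta - sf.theta_s)) ** sf.xi
            radial = np.exp(-sf.eta * (0.5 * (rij + rik) - sf.r_s) ** 2)
            fc = cutoff_value(rij, sf.cutoff) * cutoff_value(rik, sf.cutoff)
        else:
            angular = (1.0 + sf.lam * np.cos(theta)) ** sf.xi
            fc = cutoff_value(rij, sf.cutoff) * cutoff_value(rik, sf.cutoff)
            if sf.variant == "standard":
                rjk = frame.distance(j, k)
                radial = np.exp(-sf.eta * (rij**2 + rik**2 + rjk**2))
                fc *= cutoff_value(rjk, sf.cutoff)
            else:  # modified: no r_jk term, no r_jk cutoff
                radial = np.exp(-sf.eta * (rij**2 + rik**2))
        total += 2.0 ** (1.0 - sf.xi) * angular * radial * fc
    return float(total)


def _eval_sfset(frame: Frame, atom_index: int, sfset: SFSet) -> np.ndarray:
    out = np.empty(len(sfset))
    for col, sf in enumerate(sfset.functions):
        if isinstance(sf, RadialSF):
            out[col] = eval_radial_sf(frame, atom_index, sf)
        else:
            out[col] = eval_angular_sf(frame, atom_index, sf)
    return out


def build_feature_matrix(
    frames: Sequence[Frame], sfsets: Mapping[str, SFSet]
) -> FeatureMatrix:
    """Assemble AEV rows for every (frame, atom), columns in SFSet order.

    Each atom's row holds its own element's symmetry-function
    activations, stacked positionally; the sets of all elements present
    must therefore have equal length (the common case of element-wise
    sets of differing sizes is served by :func:`build_element_matrices`).
    """
    frames = list(frames)
    present = {el for f in frames for el in f.elements}
    missing = sorted(present - set(sfsets))
    if missing:
        raise ValueError(f"no symmetry-function set for element(s): {', '.join(missing)}")
    lengths = {el: len(sfsets[el]) for el in sorted(present)}
    if len(set(lengths.values())) > 1:
        raise ValueError(
            f"SFSet lengths differ across elements ({lengths}); "
            "use build_element_matrices for per-element matrices"
        )
    rows, index = [], []
    for f_idx, frame in enumerate(frames):
        for a_idx, el in enumerate(frame.elements):
            rows.append(_eval_sfset(frame, a_idx, sfsets[el]))
            index.append((f_idx, a_idx, el))
    labels = sfsets[sorted(present)[0]].labels()
    return FeatureMatrix(np.asarray(rows), index, labels)


def build_element_matrices(
    frames: Sequence[Frame], sfsets: Mapping[str, SFSet]
) -> dict[str, FeatureMatrix]:
    """One FeatureMatrix per center element (rows restricted to its atoms)."""
    frames = list(frames)
    present = {el for f in frames for el in f.elements}
    missing = sorted(present - set(sfsets))
    if missing:
        raise ValueError(f"no symmetry-function set for element(s): {', '.join(missing)}")
    out: dict[str, FeatureMatrix] = {}
    for el in sorted(present):
        rows, index = [], []
        for f_idx, frame in enumerate(frames):
            for a_idx, atom_el in enumerate(frame.elements):
                if atom_el != el:
                    continue
                rows.append(_eval_sfset(frame, a_idx, sfsets[el]))
                index.append((f_idx, a_idx, el))
        out[el] = FeatureMatrix(np.asarray(rows), index, sfsets[el].labels())
    return out


def fit_normalizer(
    matrix: FeatureMatrix, training_rows: Sequence[int] | None = None
) -> NormalizationRecord:
    """Column min/max from the training rows only (sklearn MinMaxScaler)."""
    rows = np.arange(len(matrix.row_index)) if training_rows is None else np.asarray(training_rows)
    if rows.size == 0:
        raise ValueError("training row subset must be nonempty")
    scaler = MinMaxScaler().fit(matrix.values[rows])
    return NormalizationRecord(scaler.data_min_.copy(), scaler.data_max_.copy())


def apply_normalizer(matrix: FeatureMatrix, record: NormalizationRecord) -> FeatureMatrix:
    """(x − min)/(max − min) per column; constant columns map to 0; no clipping."""
    span = record.col_max - record.col_min
    span = np.where(span == 0.0, 1.0, span)
    values = (matrix.values - record.col_min) / span
    return replace(matrix, values=values, normalization=record)


def prune_dead(
    matrix: FeatureMatrix,
    activation_threshold: float = 1e-8,
    training_rows: Sequence[int] | None = None,
) -> np.ndarray:
    """Indices of columns whose max activation on the training rows ≥ threshold."""
    if activation_threshold <= 0:
        raise ValueError("activation_threshold must be positive")
    rows = np.arange(len(matrix.row_index)) if training_rows is None else np.asarray(training_rows)
    col_max = matrix.values[rows].max(axis=0)
    return np.flatnonzero(col_max >= activation_threshold)
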