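"""scikit-learn-style front end to the tuning workflow.

`TailoredACSF` is a transformer: ``fit`` learns per-element symmetry
functions from a trajectory (GMM clustering of radial and angular
environments, mapping, resampling) and ``transform`` turns frames into
a per-atom feature matrix, so the whole featurization composes with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .aev import (
    FeatureMatrix,
    apply_normalizer,
    build_element_matrices,
    fit_normalizer,
)
from .builder import SFSet
from .pipeline import RunConfig, run_angular, run_radial
from .trajectory import Frame, Trajectory

__all__ = ["TailoredACSF"]


class TailoredACSF(TransformerMixin, BaseEstimator):
    """Self-tuned atom-centered symmetry-function featurizer.

    Parameters mirror :class:`~acsftune.pipeline.RunConfig`; the most
    important are the cutoff radii (Å), the radial resampling scheme
    with its α/β/K parameters, the component-search limits, and the
    angular selection knobs (afrac, nmax).

    Attributes
    ----------
    sf_sets_ : dict[str, SFSet]
        Tuned symmetry functions per center element.
    reports_ : dict
        Fit reports of the radial and angular branches.
    columns_ : list[str]
        Labels of the transform output columns (concatenated per
        element; an atom activates only its own element's block).
    normalization_ : NormalizationRecord per element or None.
    """

    def __init__(
        self,
        r_c_radial: float = 7.0,
        r_c_angular: float = 3.5,
        cutoff_scheme: str = "hard",
        radial_scheme: str = "tailor",
        radial_n_max: int = 15,
        radial_criterion: str = "min_bic",
        angular: bool = True,
        angular_n_max: int = 8,
        angular_criterion: str = "threshold",
        score_threshold: float = 0.30,
        gradient_threshold: float = 0.40,
        alpha: float = 3.0,
        beta: float = 1.0,
        K: int = 2,
        auxiliary: bool = False,
        min_overlap: float = 0.01,
        afrac: float = 1.0,
        nmax: int = 20,
        normalize: bool = False,
        random_state: int = 0,
    ) -> None:
        self.r_c_radial = r_c_radial
        self.r_c_angular = r_c_angular
        self.cutoff_scheme = cutoff_scheme
        self.radial_scheme = radial_scheme
        self.radial_n_max = radial_n_max
        self.radial_criterion = radial_criterion
        self.angular = angular
        self.angular_n_max = angular_n_max
        self.angular_criterion = angular_criterion
        self.score_threshold = score_threshold
        self.gradient_threshold = gradient_threshold
        self.alpha = alpha
        self.beta = beta
        self.K = K
        self.auxiliary = auxiliary
        self.min_overlap = min_overlap
        self.afrac = afrac
        self.nmax = nmax
        self.normalize = normalize
        self.random_state = random_state

    def _config(self) -> RunConfig:
        return RunConfig(
            out_dir="",
            seed=self.random_state,
            r_c_radial=self.r_c_radial,
            r_c_angular=self.r_c_angular,
            cutoff_scheme=self.cutoff_scheme,
            radial_n_max=self.radial_n_max,
            radial_criterion=self.radial_criterion,
            radial_scheme=self.radial_scheme,
            alpha=self.alpha,
            beta=self.beta,
            K=self.K,
            auxiliary=self.auxiliary,
            min_overlap=self.min_overlap,
            angular_n_max=self.angular_n_max,
            angular_criterion=self.angular_criterion,
            score_threshold=self.score_threshold,
            gradient_threshold=self.gradient_threshold,
            afrac=self.afrac,
            nmax=self.nmax,
        )

    @staticmethod
    def _as_trajectory(X) -> Trajectory:
        if isinstance(X, Trajectory):
            return X
        return Trajectory(tuple(X), source_path="<frames>")

    def fit(self, X, y=None):
        """Tune symmetry functions on a trajectory (or sequence of frames)."""
        traj = self._as_trajectory(X)
        config = self._config()
        radial, radial_report = run_radial(config, traj)
        angular = {el: [] for el in radial}
        angular_report = {}
        if self.angular and traj.elements and len(traj.elements) >= 3:
            angular, angular_report = run_angular(config, traj)
        elements = sorted(set(radial) | set(angular))
        self.sf_sets_ = {
            el: SFSet(el, radial.get(el, []), angular.get(el, [])) for el in elements
        }
        self.reports_ = {"radial": radial_report, "angular": angular_report}
        self.columns_ = [
            f"{el}|{label}"
            for el in elements
            for label in self.sf_sets_[el].labels()
        ]
        self.normalization_ = None
        if self.normalize:
            matrices = build_element_matrices(traj.frames, self.sf_sets_)
            self.normalization_ = {
                el: fit_normalizer(m) for el, m in matrices.items()
            }
        return self

    def transform(self, X) -> np.ndarray:
        """Per-atom AEVs, one row per (frame, atom).

        Columns are the per-element blocks concatenated in element
        order; entries outside an atom's own element block are zero.
        """
        if not hasattr(self, "sf_sets_"):
            raise RuntimeError("this TailoredACSF instance is not fitted yet")
        traj = self._as_trajectory(X)
        matrices = build_element_matrices(traj.frames, self.sf_sets_)
        if self.normalization_ is not None:
            matrices = {
                el: apply_normalizer(m, self.normalization_[el])
                for el, m in matrices.items()
            }
        elements = sorted(self.sf_sets_)
        offsets: dict[str, int] = {}
        total = 0
        for el in elements:
            offsets[el] = total
            total += len(self.sf_sets_[el])
        n_rows = sum(f.n_atoms for f in traj.frames)
        out = np.zeros((n_rows, total))
        row_of = {}
        r = 0
        for f_idx, frame in enumerate(traj.frames):
            for a_idx in range(frame.n_atoms):
                row_of[(f_idx, a_idx)] = r
                r += 1
        for el, matrix in matrices.items():
            off = offsets[el]
            width = matrix.shape[1]
            for local_row, (f_idx, a_idx, _) in enumerate(matrix.row_index):
                out[row_of[(f_idx, a_idx)], off : off + width] = matrix.values[local_row]
        return out

    def element_matrices(self, X) -> dict[str, FeatureMatrix]:
        """Per-element FeatureMatrix objects (row/column metadata included)."""
        if not hasattr(self, "sf_sets_"):
            raise RuntimeError("this TailoredACSF instance is not fitted yet")
        traj = self._as_trajectory(X)
        matrices = build_element_matrices(traj.frames, self.sf_sets_)
        if self.normalization_ is not None:
            matrices = {
                el: apply_normalizer(m, self.normalization_[el])
                for el, m in matrices.items()
            }
        return matrices
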