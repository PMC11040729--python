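"""Workflow wiring: trajectory → sampling → GMM → symmetry functions → AEVs.

`run_radial` and `run_angular` execute the two tuning branches for every
element pairing present in a trajectory and write the resulting
parameter tables plus a JSON fit report (inputs, stride, seeds, BIC
scan). `run_aev` evaluates previously tuned functions on a trajectory
and writes per-element feature matrices. All stages are deterministic
given the configured seeds.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field, asdict
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Literal

import numpy as np

from . import __version__
from .aev import apply_normalizer, build_element_matrices, fit_normalizer, prune_dead
from .builder import (
    AngularSF,
    RadialSF,
    SFSet,
    add_auxiliary,
    map_angular,
    map_radial,
    read_sf_table,
    resample_binary,
    resample_decomposed,
    resample_displaced,
    select_top_angular,
    uniform_radial_basis,
    write_sf_table,
)
from .environments import CutoffSpec, collect_angular, collect_radial
from .mixture import MixtureFit, select_components
from .trajectory import Trajectory, read_xyz_trajectory

__all__ = ["RunConfig", "run_radial", "run_angular", "run_aev"]

RadialScheme = Literal["tailor", "decomposed", "displaced", "binary", "uniform"]


@dataclass
class RunConfig:
    """Flat configuration mirroring the CLI flags.

    Defaults follow the workflow's study conditions: hard cutoff with
    r_c = 7.0 Å for radial and 3.5 Å for angular environments, BIC scan
    up to 15 radial components, binary resampling with α = 3, β = 1,
    and thresholded selection (30% score / 40% gradient) with
    nmax = 20, afrac = 1.0 for the angular branch.
    """

    trajectory: str = ""
    trj_step: int = 1
    out_dir: str = "acsftune_out"
    seed: int = 0
    # cutoff
    r_c_radial: float = 7.0
    r_c_angular: float = 3.5
    cutoff_scheme: Literal["soft", "hard"] = "hard"
    # radial branch
    radial_n_max: int = 15
    radial_criterion: Literal["min_bic", "threshold"] = "min_bic"
    radial_scheme: RadialScheme = "tailor"
    alpha: float = 3.0
    beta: float = 1.0
    K: int = 2
    auxiliary: bool = False
    min_overlap: float = 0.01
    uniform_n: int = 8
    uniform_r_min: float = 0.5
    # angular branch
    angular_n_max: int = 20
    angular_criterion: Literal["min_bic", "threshold"] = "threshold"
    score_threshold: float = 0.30
    gradient_threshold: float = 0.40
    afrac: float = 1.0
    nmax: int = 20
    # aev stage
    training_fraction: float = 1.0
    activation_threshold: float = 1e-8
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.trj_step < 1:
            raise ValueError("trj_step must be a positive integer")
        if self.r_c_radial <= 0 or self.r_c_angular <= 0:
            raise ValueError("cutoff radii must be positive")
        if self.cutoff_scheme not in ("soft", "hard"):
            raise ValueError(f"unknown cutoff scheme {self.cutoff_scheme!r}")
        if self.radial_scheme not in ("tailor", "decomposed", "displaced", "binary", "uniform"):
            raise ValueError(f"unknown radial scheme {self.radial_scheme!r}")
        if self.radial_n_max < 1 or self.angular_n_max < 1:
            raise ValueError("component-search limits must be at least 1")
        if not 0 < self.afrac <= 1:
            raise ValueError("afrac must lie in (0, 1]")
        if self.alpha <= 0 or self.beta <= 0 or self.K < 1:
            raise ValueError("resampling parameters must be positive (K ≥ 1)")
        if not 0 < self.training_fraction <= 1:
            raise ValueError("training_fraction must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat TOML key-value file; keyword overrides win."""
        data = tomllib.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def radial_cutoff(self) -> CutoffSpec:
        return CutoffSpec(self.r_c_radial, self.cutoff_scheme)

    def angular_cutoff(self) -> CutoffSpec:
        return CutoffSpec(self.r_c_angular, self.cutoff_scheme)


def _pair_seed(base: int, tag: str) -> int:
    """Stable sub-seed per element pairing, kept below 2**31."""
    h = 2166136261
    for ch in tag:
        h = (h ^ ord(ch)) * 16777619 % (1 << 31)
    return (base * 1000003 + h) % (1 << 31)


def _load_trajectory(config: RunConfig, traj: Trajectory | None) -> Trajectory:
    if traj is not None:
        return traj
    if not config.trajectory:
        raise ValueError("no trajectory configured")
    return read_xyz_trajectory(config.trajectory, stride=config.trj_step)


def _radial_sfs_from_fit(
    fit: MixtureFit, config: RunConfig, cutoff: CutoffSpec, center: str, neighbor: str
) -> list[RadialSF]:
    scheme = config.radial_scheme
    out: list[RadialSF] = []
    for comp in fit.components:
        if scheme == "tailor":
            out.append(map_radial(comp, cutoff, center, neighbor))
        elif scheme == "decomposed":
            out.extend(resample_decomposed(comp, config.K, cutoff, center, neighbor))
        elif scheme == "displaced":
            out.append(resample_displaced(comp, config.alpha, cutoff, center, neighbor))
        elif scheme == "binary":
            out.extend(resample_binary(comp, config.alpha, config.beta, cutoff, center, neighbor))
    if config.auxiliary and out:
        out = add_auxiliary(out, config.min_overlap)
    return out


def run_radial(
    config: RunConfig, traj: Trajectory | None = None
) -> tuple[dict[str, list[RadialSF]], dict]:
    """Tune radial functions for every ordered element pair of the trajectory.

    Returns ``{center element: [RadialSF, ...]}`` and the fit report;
    when ``config.out_dir`` is set, writes ``radial_sf.tsv`` (+ JSON
    mirror) and ``radial_report.json``.
    """
    trajectory = _load_trajectory(config, traj)
    cutoff = config.radial_cutoff()
    elements = sorted(set(trajectory.elements))
    by_center: dict[str, list[RadialSF]] = {el: [] for el in elements}
    report: dict = {
        "stage": "radial",
        "package_version": __version__,
        "trajectory": trajectory.source_path,
        "n_frames": trajectory.n_frames,
        "trj_step": trajectory.stride_applied,
        "cutoff": {"r_c": cutoff.r_c, "scheme": cutoff.scheme},
        "scheme": config.radial_scheme,
        "seed": config.seed,
        "pairs": {},
    }
    for center in elements:
        for neighbor in elements:
            tag = f"radial:{center}->{neighbor}"
            if config.radial_scheme == "uniform":
                sfs = uniform_radial_basis(
                    config.uniform_n, config.uniform_r_min, cutoff, center, neighbor
                )
                by_center[center].extend(sfs)
                report["pairs"][tag] = {"n_functions": len(sfs), "scheme": "uniform"}
                continue
            samples = collect_radial(trajectory, center, neighbor, cutoff)
            if len(samples) < 2:
                report["pairs"][tag] = {"n_samples": len(samples), "skipped": True}
                continue
            fit = select_components(
                samples.distances,
                samples.weights,
                n_max=min(config.radial_n_max, len(samples)),
                criterion=config.radial_criterion,
                score_threshold=config.score_threshold,
                gradient_threshold=config.gradient_threshold,
                seed=_pair_seed(config.seed, tag),
            )
            sfs = _radial_sfs_from_fit(fit, config, cutoff, center, neighbor)
            by_center[center].extend(sfs)
            report["pairs"][tag] = {
                "n_samples": len(samples),
                "n_components": fit.n_components,
                "bic": fit.bic,
                "converged": fit.converged,
                "seed": fit.seed,
                "components": fit.to_dict(),
                "n_functions": len(sfs),
            }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flat = [sf for sfs in by_center.values() for sf in sfs]
        write_sf_table(flat, out / "radial_sf.tsv")
        (out / "radial_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return by_center, report


def run_angular(
    config: RunConfig, traj: Trajectory | None = None
) -> tuple[dict[str, list[AngularSF]], dict]:
    """Tune angular functions for every (center, unordered neighbor pair) trio."""
    trajectory = _load_trajectory(config, traj)
    cutoff = config.angular_cutoff()
    elements = sorted(set(trajectory.elements))
    by_center: dict[str, list[AngularSF]] = {el: [] for el in elements}
    report: dict = {
        "stage": "angular",
        "package_version": __version__,
        "trajectory": trajectory.source_path,
        "n_frames": trajectory.n_frames,
        "trj_step": trajectory.stride_applied,
        "cutoff": {"r_c": cutoff.r_c, "scheme": cutoff.scheme},
        "afrac": config.afrac,
        "nmax": config.nmax,
        "seed": config.seed,
        "trios": {},
    }
    for center in elements:
        candidates: list[AngularSF] = []
        for pair in combinations_with_replacement(elements, 2):
            tag = f"angular:{center}->{pair[0]},{pair[1]}"
            samples = collect_angular(trajectory, center, pair, cutoff)
            if len(samples) < 2:
                report["trios"][tag] = {"n_samples": len(samples), "skipped": True}
                continue
            fit = select_components(
                samples.triples,
                samples.weights,
                n_max=min(config.angular_n_max, len(samples)),
                criterion=config.angular_criterion,
                score_threshold=config.score_threshold,
                gradient_threshold=config.gradient_threshold,
                seed=_pair_seed(config.seed, tag),
            )
            sfs = [map_angular(c, cutoff, center, pair) for c in fit.components]
            candidates.extend(sfs)
            report["trios"][tag] = {
                "n_samples": len(samples),
                "n_components": fit.n_components,
                "bic": fit.bic,
                "converged": fit.converged,
                "seed": fit.seed,
                "components": fit.to_dict(),
            }
        kept = select_top_angular(candidates, config.afrac, config.nmax)
        by_center[center] = kept
        report["trios"][f"selected:{center}"] = {
            "n_candidates": len(candidates),
            "n_selected": len(kept),
        }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flat = [sf for sfs in by_center.values() for sf in sfs]
        write_sf_table(flat, out / "angular_sf.tsv")
        (out / "angular_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return by_center, report


def load_sfsets(paths: list[str | Path]) -> dict[str, SFSet]:
    """Assemble per-element SFSets from one or more parameter tables."""
    radial: dict[str, list[RadialSF]] = {}
    angular: dict[str, list[AngularSF]] = {}
    for path in paths:
        for sf in read_sf_table(path):
            bucket = radial if isinstance(sf, RadialSF) else angular
            bucket.setdefault(sf.center_element, []).append(sf)
    elements = sorted(set(radial) | set(angular))
    return {
        el: SFSet(el, radial.get(el, []), angular.get(el, [])) for el in elements
    }


def run_aev(
    config: RunConfig,
    sf_paths: list[str | Path] | None = None,
    traj: Trajectory | None = None,
    sfsets: dict[str, SFSet] | None = None,
):
    """Evaluate tuned functions on a trajectory; normalize and prune.

    Writes one feature-matrix TSV per element plus the normalization
    record and surviving column indices as JSON.
    """
    trajectory = _load_trajectory(config, traj)
    if sfsets is None:
        if not sf_paths:
            raise ValueError("run_aev needs sf_paths or explicit sfsets")
        sfsets = load_sfsets(list(sf_paths))
    matrices = build_element_matrices(trajectory.frames, sfsets)
    report: dict = {
        "stage": "aev",
        "package_version": __version__,
        "trajectory": trajectory.source_path,
        "n_frames": trajectory.n_frames,
        "trj_step": trajectory.stride_applied,
        "elements": {},
    }
    results = {}
    for el, matrix in matrices.items():
        n_rows = matrix.shape[0]
        n_train = max(1, int(round(config.training_fraction * n_rows)))
        train_rows = np.arange(n_train)
        keep = prune_dead(matrix, config.activation_threshold, train_rows)
        pruned = matrix
        if keep.size < matrix.shape[1]:
            from dataclasses import replace as _replace

            pruned = _replace(
                matrix,
                values=matrix.values[:, keep],
                column_labels=[matrix.column_labels[i] for i in keep],
            )
        record = None
        if config.normalize and pruned.shape[1] > 0:
            record = fit_normalizer(pruned, train_rows)
            pruned = apply_normalizer(pruned, record)
        results[el] = (pruned, keep, record)
        report["elements"][el] = {
            "n_rows": n_rows,
            "n_training_rows": int(n_train),
            "n_functions": matrix.shape[1],
            "n_retained": int(keep.size),
        }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for el, (matrix, keep, record) in results.items():
            matrix.to_csv(out / f"aev_{el}.tsv")
            if record is not None:
                record.to_json(out / f"aev_{el}_normalization.json")
            (out / f"aev_{el}_columns.json").write_text(
                json.dumps({"retained_columns": keep.tolist()}) + "\n"
            )
        (out / "aev_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return results, report
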