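"""Weighted-EM Gaussian mixtures with BIC-driven component selection.

The radial (1-D) and angular (3-D, full covariance) environment
distributions are decomposed as

    p(x) = Σ_c w_c · N(x | μ_c, Σ_c),   Σ_c w_c = 1,

fitted by expectation–maximization generalized to carry a non-negative
per-sample weight s_n (the soft cosine-cutoff weight of the sample):

    E-step:  r_nc ∝ w_c N(x_n | μ_c, Σ_c)            (Σ_c r_nc = 1)
    M-step:  N_c = Σ_n s_n r_nc
             μ_c = Σ_n s_n r_nc x_n / N_c
             Σ_c = Σ_n s_n r_nc (x_n−μ_c)(x_n−μ_c)ᵀ / N_c + reg·I
             w_c = N_c / Σ_n s_n

The weighted log-likelihood Σ_n s_n · log Σ_c w_c N(x_n | μ_c, Σ_c) is
non-decreasing over iterations (a property the test suite asserts on
every fixture). The component count is chosen by scanning M = 1..n_max
and either taking the minimum-BIC fit or stopping early when both the
relative BIC improvement and the shrinkage of its discrete gradient
fall below user thresholds.

Model-selection scale: BIC = k·ln(n_eff) − 2·ln L̂ with
k = M·(d + d(d+1)/2 + 1) − 1 free parameters (1-D: 3M−1; 3-D: 10M−1)
and n_eff = Σ_n s_n, the weighted-likelihood analogue of the sample
count (equal to n for unit weights).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin

__all__ = [
    "GaussianComponent",
    "MixtureFit",
    "WeightedGaussianMixture",
    "em_fit",
    "bic",
    "select_components",
    "sample_from_mixture",
]


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: weight w, mean μ and covariance Σ.

    1-D components use a (1,) mean and (1, 1) covariance; the scalar
    standard deviation is exposed via :attr:`sigma`. Means mix units
    (Å for radial dimensions, radians for the angular one).
    """

    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if not 0 < self.weight <= 1:
            raise ValueError(f"component weight must be in (0, 1], got {self.weight}")
        if cov.shape != (mean.size, mean.size):
            raise ValueError(f"covariance shape {cov.shape} incompatible with mean {mean.shape}")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive definite")

    @property
    def ndim(self) -> int:
        return self.mean.size

    @property
    def sigma(self) -> float:
        """Standard deviation of a 1-D component."""
        if self.ndim != 1:
            raise ValueError("sigma is defined for 1-D components only")
        return float(np.sqrt(self.covariance[0, 0]))

    def marginal_sigmas(self) -> np.ndarray:
        """Per-dimension marginal standard deviations."""
        return np.sqrt(np.diag(self.covariance))


@dataclass
class MixtureFit:
    """A converged (or iteration-capped) mixture, components sorted by weight."""

    components: list[GaussianComponent]
    log_likelihood: float
    bic: float
    n_iterations: int
    converged: bool
    seed: int
    n_effective: float
    log_likelihood_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: -c.weight)
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, expected 1")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def ndim(self) -> int:
        return self.components[0].ndim

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "ndim": self.ndim,
            "weights": [c.weight for c in self.components],
            "means": [c.mean.tolist() for c in self.components],
            "covariances": [c.covariance.tolist() for c in self.components],
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
            "n_effective": self.n_effective,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureFit":
        comps = [
            GaussianComponent(w, np.asarray(m), np.asarray(c))
            for w, m, c in zip(d["weights"], d["means"], d["covariances"])
        ]
        return cls(
            components=comps,
            log_likelihood=d["log_likelihood"],
            bic=d["bic"],
            n_iterations=d["n_iterations"],
            converged=d["converged"],
            seed=d["seed"],
            n_effective=d["n_effective"],
        )


def _free_parameters(n_components: int, ndim: int) -> int:
    """Free-parameter count of a full-covariance mixture (weights constrained)."""
    per_component = ndim + ndim * (ndim + 1) // 2 + 1
    return n_components * per_component - 1


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at the rows of X, via Cholesky."""
    d = mean.size
    chol = np.linalg.cholesky(cov)
    diff = X - mean
    solved = np.linalg.solve(chol, diff.T)
    maha = np.sum(solved**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


class WeightedGaussianMixture(DensityMixin, BaseEstimator):
    """Full-covariance Gaussian mixture fitted by sample-weighted EM.

    Parameters
    ----------
    n_components : int
        Number of mixture components M.
    tol : float
        Convergence threshold on the relative change of the weighted
        log-likelihood between iterations.
    max_iter : int
        EM iteration cap.
    reg_covar : float
        Value added to the covariance diagonal at every M-step (squared
        units) to guard against collapse onto single points.
    random_state : int
        Seed for the k-means++-style initialization.

    Attributes
    ----------
    weights_, means_, covariances_ : fitted mixture parameters, sorted
        by decreasing weight.
    log_likelihood_ : final weighted log-likelihood.
    log_likelihood_history_ : per-iteration values (non-decreasing).
    converged_, n_iter_, n_effective_ : fit diagnostics.
    """

    def __init__(
        self,
        n_components: int = 1,
        tol: float = 1e-6,
        max_iter: int = 500,
        reg_covar: float = 1e-6,
        random_state: int = 0,
    ) -> None:
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar
        self.random_state = random_state

    # -- initialization -------------------------------------------------
    def _init_parameters(self, X: np.ndarray, s: np.ndarray, rng: np.random.Generator):
        n, d = X.shape
        M = self.n_components
        # k-means++-style seeding of the means, weighted by the sample weights
        probs = s / s.sum()
        centers = [X[rng.choice(n, p=probs)]]
        for _ in range(1, M):
            d2 = np.min(
                [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
            )
            score = s * d2
            if score.sum() <= 0:
                centers.append(X[rng.choice(n, p=probs)])
            else:
                centers.append(X[rng.choice(n, p=score / score.sum())])
        means = np.asarray(centers)
        # hard-assign, then per-cluster weighted covariance
        assign = np.argmin(
            np.sum((X[:, None, :] - means[None, :, :]) ** 2, axis=2), axis=1
        )
        overall = np.cov(X.T, aweights=s, ddof=0).reshape(d, d)
        covs = np.empty((M, d, d))
        for c in range(M):
            mask = assign == c
            if mask.sum() > d:
                covs[c] = np.cov(X[mask].T, aweights=s[mask], ddof=0).reshape(d, d)
            else:
                covs[c] = overall
            covs[c][np.diag_indices(d)] += self.reg_covar
        weights = np.full(M, 1.0 / M)  # equal weights initially
        return weights, means, covs

    # -- EM -------------------------------------------------------------
    def _e_step(self, X, weights, means, covs):
        log_prob = np.column_stack(
            [_log_gaussian(X, means[c], covs[c]) for c in range(self.n_components)]
        )
        weighted = log_prob + np.log(weights)
        log_norm = logsumexp(weighted, axis=1)
        log_resp = weighted - log_norm[:, None]
        return log_norm, np.exp(log_resp)

    def _m_step(self, X, s, resp):
        d = X.shape[1]
        sw = s[:, None] * resp  # (n, M)
        Nc = sw.sum(axis=0)
        Nc = np.maximum(Nc, np.finfo(float).tiny)
        means = (sw.T @ X) / Nc[:, None]
        covs = np.empty((self.n_components, d, d))
        for c in range(self.n_components):
            diff = X - means[c]
            covs[c] = (sw[:, c][:, None] * diff).T @ diff / Nc[c]
            covs[c][np.diag_indices(d)] += self.reg_covar
        weights = Nc / s.sum()
        return weights, means, covs

    def fit(self, X, y=None, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, d = X.shape
        if self.n_components > n:
            raise ValueError(
                f"n_components={self.n_components} exceeds the number of samples ({n})"
            )
        if sample_weight is None:
            s = np.ones(n)
        else:
            s = np.asarray(sample_weight, dtype=float)
            if s.shape != (n,):
                raise ValueError("sample_weight length must match the number of samples")
            if np.any(s <= 0):
                raise ValueError("sample weights must be positive")

        rng = np.random.default_rng(self.random_state)
        weights, means, covs = self._init_parameters(X, s, rng)

        history: list[float] = []
        converged = False
        ll = -np.inf
        for it in range(1, self.max_iter + 1):
            log_norm, resp = self._e_step(X, weights, means, covs)
            new_ll = float(np.sum(s * log_norm))
            history.append(new_ll)
            if np.isfinite(ll) and abs(new_ll - ll) <= self.tol * abs(ll):
                converged = True
                ll = new_ll
                break
            ll = new_ll
            weights, means, covs = self._m_step(X, s, resp)

        order = np.argsort(-weights)
        self.weights_ = weights[order]
        self.means_ = means[order]
        self.covariances_ = covs[order]
        self.log_likelihood_ = ll
        self.log_likelihood_history_ = history
        self.converged_ = converged
        self.n_iter_ = len(history)
        self.n_effective_ = float(s.sum())
        self.n_features_in_ = d
        return self

    def score_samples(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        log_prob = np.column_stack(
            [
                _log_gaussian(X, self.means_[c], self.covariances_[c])
                for c in range(self.n_components)
            ]
        )
        return logsumexp(log_prob + np.log(self.weights_), axis=1)

    def bic(self, n_effective: float | None = None) -> float:
        """k·ln(n_eff) − 2·ln L̂ on the fitted data."""
        n_eff = self.n_effective_ if n_effective is None else n_effective
        if n_eff <= 0:
            raise ValueError("n_effective must be positive")
        k = _free_parameters(self.n_components, self.n_features_in_)
        return k * np.log(n_eff) - 2.0 * self.log_likelihood_

    def responsibilities(self, X, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        _, resp = self._e_step(X, self.weights_, self.means_, self.covariances_)
        return resp

    def to_fit(self, seed: int | None = None) -> MixtureFit:
        comps = [
            GaussianComponent(float(w), m, c)
            for w, m, c in zip(self.weights_, self.means_, self.covariances_)
        ]
        fit = MixtureFit(
            components=comps,
            log_likelihood=self.log_likelihood_,
            bic=self.bic(),
            n_iterations=self.n_iter_,
            converged=self.converged_,
            seed=self.random_state if seed is None else seed,
            n_effective=self.n_effective_,
            log_likelihood_history=list(self.log_likelihood_history_),
        )
        return fit


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def em_fit(
    samples,
    weights=None,
    n_components: int = 1,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg_covar: float = 1e-6,
) -> MixtureFit:
    """Fit an M-component weighted Gaussian mixture; see module docstring."""
    model = WeightedGaussianMixture(
        n_components=n_components,
        tol=tol,
        max_iter=max_iter,
        reg_covar=reg_covar,
        random_state=seed,
    )
    model.fit(samples, sample_weight=weights)
    return model.to_fit(seed=seed)


def bic(fit: MixtureFit, n_effective: float | None = None) -> float:
    """BIC of an existing fit, optionally at an overriding effective size."""
    n_eff = fit.n_effective if n_effective is None else n_effective
    if n_eff <= 0:
        raise ValueError("n_effective must be positive")
    k = _free_parameters(fit.n_components, fit.ndim)
    return float(k * np.log(n_eff) - 2.0 * fit.log_likelihood)


def select_components(
    samples,
    weights=None,
    n_max: int = 15,
    criterion: Literal["min_bic", "threshold"] = "min_bic",
    score_threshold: float = 0.30,
    gradient_threshold: float = 0.40,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureFit:
    """Scan M = 1..n_max and pick the component count.

    ``min_bic`` returns the fit minimizing the BIC over the whole scan.
    ``threshold`` stops early at the first M where the relative BIC
    improvement over M−1 falls below ``score_threshold`` and the
    discrete BIC gradient has shrunk by more than ``gradient_threshold``
    relative to the previous step; if no M qualifies the minimum-BIC fit
    of the scan is returned.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    if criterion not in ("min_bic", "threshold"):
        raise ValueError(f"unknown criterion {criterion!r}")

    fits: list[MixtureFit] = []
    bics: list[float] = []
    errors: list[str] = []
    for m in range(1, n_max + 1):
        try:
            fit = em_fit(
                samples, weights, n_components=m, seed=seed, tol=tol, max_iter=max_iter
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            errors.append(f"M={m}: {exc}")
            continue
        fits.append(fit)
        bics.append(fit.bic)
        if criterion == "threshold" and len(bics) >= 2:
            prev, curr = bics[-2], bics[-1]
            rel_improvement = abs(curr - prev) / abs(prev) if prev != 0 else np.inf
            grad_ok = True
            if len(bics) >= 3:
                grad_prev = abs(bics[-2] - bics[-3])
                grad_curr = abs(curr - prev)
                grad_ok = grad_prev > 0 and (
                    (grad_prev - grad_curr) / grad_prev > gradient_threshold
                )
            if rel_improvement < score_threshold and grad_ok:
                return fit
    if not fits:
        raise RuntimeError(
            "no mixture fit succeeded at any component count: " + "; ".join(errors)
        )
    return fits[int(np.argmin(bics))]


def sample_from_mixture(fit: MixtureFit, n: int, seed: int = 0) -> np.ndarray:
    """Draw n points: component chosen by weight, then a Gaussian draw."""
    if n <= 0:
        raise ValueError("n must be positive")
    return sample_components(fit.components, n, seed)


def sample_components(
    components: Sequence[GaussianComponent], n: int, seed: int = 0
) -> np.ndarray:
    """Ancestral sampling from explicit components (shared by fixtures)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    weights = np.asarray([c.weight for c in components], dtype=float)
    weights = weights / weights.sum()
    counts = rng.multinomial(n, weights)
    chunks = [
        rng.multivariate_normal(c.mean, c.covariance, size=k)
        for c, k in zip(components, counts)
        if k > 0
    ]
    out = np.concatenate(chunks, axis=0)
    rng.shuffle(out, axis=0)
    d = components[0].ndim
    return out[:, 0] if d == 1 else out
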