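"""Mapping of Gaussian-mixture clusters to symmetry-function parameters.

Radial clusters map directly: a 1-D component (μ, σ) becomes a radial
symmetry function with center r_s = μ and width η = 1/(2σ²), so that
exp(−η(r−r_s)²) is the component's own exponential kernel.

Angular (3-D) clusters map to the heavily modified angular form: the
two radial dimensions share a single grid, so r_s is the mean of the
two radial centroids and η comes from the mean of the two marginal
radial standard deviations; the angular offset is pinned at the cluster
centroid (θ_s = μ_θ) and the cosine-power sharpness ξ is fitted
numerically so the normalized kernel 2^(1−ξ)(1+cos(θ−θ_s))^ξ / 2 best
matches the cluster's normalized angular Gaussian in least squares on a
uniform 181-point θ grid over [0, π].

The module also implements the symmetry-breaking resampling layouts
(decomposed / displaced / binary), auxiliary-function insertion between
sparse clusters, the evenly distributed radial baseline, and
weight-ranked selection of angular functions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .environments import CutoffSpec
from .mixture import GaussianComponent

__all__ = [
    "RadialSF",
    "AngularSF",
    "SFSet",
    "map_radial",
    "map_angular",
    "fit_xi",
    "add_auxiliary",
    "resample_decomposed",
    "resample_displaced",
    "resample_binary",
    "uniform_radial_basis",
    "select_top_angular",
    "write_sf_table",
    "read_sf_table",
]

Provenance = Literal[
    "tailor", "auxiliary", "decomposed", "displaced", "binary_lower", "binary_upper", "uniform"
]


@dataclass(frozen=True)
class RadialSF:
    """A two-body symmetry function Σ_j exp(−η(r_ij−r_s)²)·f_c(r_ij)."""

    center_element: str
    neighbor_element: str
    r_s: float  # Å
    eta: float  # Å⁻²
    cutoff: CutoffSpec
    provenance: Provenance = "tailor"
    weight: float | None = None  # originating cluster weight, if any

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.r_s < 0:
            raise ValueError(f"r_s must be non-negative, got {self.r_s}")
        if self.r_s > self.cutoff.r_c and self.provenance not in (
            "displaced",
            "binary_upper",
        ):
            raise ValueError(
                f"r_s={self.r_s} beyond the cutoff is only allowed for "
                f"displaced/binary_upper functions, not {self.provenance!r}"
            )

    @property
    def sigma(self) -> float:
        """Gaussian width σ implied by η = 1/(2σ²)."""
        return 1.0 / math.sqrt(2.0 * self.eta)


@dataclass(frozen=True)
class AngularSF:
    """A three-body symmetry function in one of three variants.

    standard:          2^(1−ξ)(1+λcosθ)^ξ · exp(−η(r_ij²+r_ik²+r_jk²)) · f_c³
    modified:          as standard without the r_jk² term and its cutoff
    heavily_modified:  2^(1−ξ)(1+cos(θ−θ_s))^ξ · exp(−η((r_ij+r_ik)/2−r_s)²) · f_c²
    """

    center_element: str
    neighbor_pair: tuple[str, str]
    r_s: float
    eta: float
    xi: float
    cutoff: CutoffSpec
    variant: Literal["standard", "modified", "heavily_modified"] = "heavily_modified"
    theta_s: float | None = None  # radians, heavily_modified only
    lam: float | None = None  # ±1, standard/modified only
    provenance: str = "tailor"
    weight: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "neighbor_pair", tuple(sorted(self.neighbor_pair)))
        if self.eta <= 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.xi < 1:
            raise ValueError(f"xi must be at least 1, got {self.xi}")
        if self.variant == "heavily_modified":
            if self.theta_s is None:
                raise ValueError("heavily_modified variant requires theta_s")
            if not 0 <= self.theta_s <= math.pi:
                raise ValueError(f"theta_s must lie in [0, π], got {self.theta_s}")
            if self.lam is not None:
                raise ValueError("lambda is not used by the heavily_modified variant")
        else:
            if self.lam not in (1.0, -1.0, 1, -1):
                raise ValueError(f"{self.variant} variant requires lambda = ±1")
            if self.theta_s is not None:
                raise ValueError("theta_s is only used by the heavily_modified variant")


@dataclass
class SFSet:
    """Ordered symmetry functions for one center element, plus provenance metadata.

    Ordering is deterministic: radial functions first, each group sorted
    by (neighbor typing, r_s, θ_s) — the column order of the feature
    matrix downstream.
    """

    center_element: str
    radial: list[RadialSF] = field(default_factory=list)
    angular: list[AngularSF] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radial = sorted(self.radial, key=lambda s: (s.neighbor_element, s.r_s))
        self.angular = sorted(
            self.angular,
            key=lambda s: (s.neighbor_pair, s.r_s, s.theta_s if s.theta_s is not None else -1.0),
        )

    def __len__(self) -> int:
        return len(self.radial) + len(self.angular)

    @property
    def functions(self) -> list[RadialSF | AngularSF]:
        return [*self.radial, *self.angular]

    def labels(self) -> list[str]:
        out = []
        for sf in self.radial:
            out.append(
                f"R:{sf.center_element}-{sf.neighbor_element}"
                f":rs={sf.r_s:.4f}:eta={sf.eta:.4f}:{sf.provenance}"
            )
        for sf in self.angular:
            th = "" if sf.theta_s is None else f":ts={math.degrees(sf.theta_s):.2f}"
            out.append(
                f"A:{sf.center_element}-{sf.neighbor_pair[0]}{sf.neighbor_pair[1]}"
                f":rs={sf.r_s:.4f}:eta={sf.eta:.4f}:xi={sf.xi:.3f}{th}:{sf.variant}"
            )
        return out


# ---------------------------------------------------------------------------
# cluster → parameter mapping
# ---------------------------------------------------------------------------


def map_radial(
    component: GaussianComponent,
    cutoff: CutoffSpec,
    center_element: str = "X",
    neighbor_element: str = "X",
    provenance: Provenance = "tailor",
) -> RadialSF:
    """Map a 1-D cluster to a radial function: r_s = μ, η = 1/(2σ²)."""
    if component.ndim != 1:
        raise ValueError("map_radial requires a 1-D component")
    sigma = component.sigma
    if sigma <= 0:
        raise ValueError(f"component standard deviation must be positive, got {sigma}")
    return RadialSF(
        center_element=center_element,
        neighbor_element=neighbor_element,
        r_s=float(component.mean[0]),
        eta=1.0 / (2.0 * sigma**2),
        cutoff=cutoff,
        provenance=provenance,
        weight=component.weight,
    )


def _xi_loss(xi: float, theta: np.ndarray, target: np.ndarray, theta_s: float) -> float:
    kernel = 2.0 ** (1.0 - xi) * (1.0 + np.cos(theta - theta_s)) ** xi / 2.0
    return float(np.sum((kernel - target) ** 2))


def fit_xi(
    mu_theta: float,
    sigma_theta: float,
    xi_max: float = 1000.0,
    n_grid: int = 181,
) -> float:
    """Least-squares ξ of the cosine-power kernel against a normalized Gaussian.

    The mismatch between 2^(1−ξ)(1+cos(θ−θ_s))^ξ/2 (θ_s pinned at μ_θ)
    and exp(−(θ−μ_θ)²/(2σ_θ²)) is minimized on a uniform ``n_grid``-point
    grid over [0, π]: coarse log-spaced bracketing over [1, ``xi_max``]
    followed by bounded local refinement. ξ ≥ 1 is enforced.
    """
    if sigma_theta <= 0:
        raise ValueError(f"sigma_theta must be positive, got {sigma_theta}")
    theta = np.linspace(0.0, math.pi, n_grid)
    target = np.exp(-((theta - mu_theta) ** 2) / (2.0 * sigma_theta**2))
    grid = np.geomspace(1.0, xi_max, 80)
    losses = np.array([_xi_loss(x, theta, target, mu_theta) for x in grid])
    best = int(np.argmin(losses))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo == hi:
        return float(lo)
    result = minimize_scalar(
        _xi_loss,
        bounds=(lo, hi),
        args=(theta, target, mu_theta),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not result.success:
        raise RuntimeError(
            f"xi optimization failed to converge for sigma_theta={sigma_theta}"
        )
    return float(max(1.0, result.x))


def map_angular(
    component: GaussianComponent,
    cutoff: CutoffSpec,
    center_element: str = "X",
    neighbor_pair: tuple[str, str] = ("X", "X"),
) -> AngularSF:
    """Map a 3-D (r_ij, r_ik, θ) cluster to a heavily modified angular function.

    The single radial grid forces pooling of the two radial dimensions:
    r_s is the mean of μ_rij and μ_rik, η comes from the mean of the two
    marginal σ. θ_s = μ_θ, and ξ is fitted numerically (:func:`fit_xi`).
    """
    if component.ndim != 3:
        raise ValueError("map_angular requires a 3-D component (r_ij, r_ik, θ)")
    mu = component.mean
    sig = component.marginal_sigmas()
    r_s = float(0.5 * (mu[0] + mu[1]))
    sigma_r = float(0.5 * (sig[0] + sig[1]))
    theta_s = float(np.clip(mu[2], 0.0, math.pi))
    xi = fit_xi(theta_s, float(sig[2]))
    return AngularSF(
        center_element=center_element,
        neighbor_pair=neighbor_pair,
        r_s=r_s,
        eta=1.0 / (2.0 * sigma_r**2),
        xi=xi,
        theta_s=theta_s,
        cutoff=cutoff,
        variant="heavily_modified",
        weight=component.weight,
    )


# ---------------------------------------------------------------------------
# auxiliary insertion and resampling layouts
# ---------------------------------------------------------------------------


def add_auxiliary(sfs: Sequence[RadialSF], min_overlap: float = 0.01) -> list[RadialSF]:
    """Insert auxiliary functions between sparse adjacent clusters.

    Functions are scanned in r_s order; for each adjacent pair the
    overlap is the smaller of the two Gaussian values (no cutoff) at the
    midpoint of the centers. Below ``min_overlap`` an auxiliary function
    is inserted at the midpoint with σ = (center gap)/2. Originals are
    untouched; the result is re-sorted by r_s.
    """
    if not 0 < min_overlap < 1:
        raise ValueError(f"min_overlap must be in (0, 1), got {min_overlap}")
    if not sfs:
        raise ValueError("sfs must be nonempty")
    ordered = sorted(sfs, key=lambda s: s.r_s)
    out = list(ordered)
    for left, right in zip(ordered, ordered[1:]):
        mid = 0.5 * (left.r_s + right.r_s)
        overlap = min(
            math.exp(-left.eta * (mid - left.r_s) ** 2),
            math.exp(-right.eta * (mid - right.r_s) ** 2),
        )
        if overlap < min_overlap:
            gap = right.r_s - left.r_s
            sigma = gap / 2.0
            out.append(
                replace(
                    left,
                    r_s=mid,
                    eta=1.0 / (2.0 * sigma**2),
                    provenance="auxiliary",
                    weight=None,
                )
            )
    return sorted(out, key=lambda s: s.r_s)


def resample_decomposed(
    component: GaussianComponent,
    K: int,
    cutoff: CutoffSpec,
    center_element: str = "X",
    neighbor_element: str = "X",
) -> list[RadialSF]:
    """Express one cluster as K subcomponents spanning [μ−σ, μ+σ].

    Centers are evenly spaced over the span (K = 1 degenerates to the
    plain mapping); the common subcomponent width makes adjacent
    Gaussians cross at half height.
    """
    if K < 1:
        raise ValueError(f"K must be at least 1, got {K}")
    mu, sigma = float(component.mean[0]), component.sigma
    if K == 1:
        base = map_radial(component, cutoff, center_element, neighbor_element)
        return [replace(base, provenance="decomposed")]
    centers = np.linspace(mu - sigma, mu + sigma, K)
    spacing = 2.0 * sigma / (K - 1)
    eta = 4.0 * math.log(2.0) / spacing**2  # exp(−η(d/2)²) = 1/2
    return [
        RadialSF(
            center_element=center_element,
            neighbor_element=neighbor_element,
            r_s=float(c),
            eta=eta,
            cutoff=cutoff,
            provenance="decomposed",
            weight=component.weight,
        )
        for c in centers
    ]


def resample_displaced(
    component: GaussianComponent,
    alpha: float,
    cutoff: CutoffSpec,
    center_element: str = "X",
    neighbor_element: str = "X",
) -> RadialSF:
    """Offset the function so the whole cluster sits on its lower tail.

    r_s = μ + α·σ and the width is set from σ_disp = α·σ, so the span
    [μ−α·σ, μ+α·σ] (α = 3 covers 99.7% of the cluster population) maps
    monotonically onto the rising flank.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    mu, sigma = float(component.mean[0]), component.sigma
    sigma_disp = alpha * sigma
    return RadialSF(
        center_element=center_element,
        neighbor_element=neighbor_element,
        r_s=mu + alpha * sigma,
        eta=1.0 / (2.0 * sigma_disp**2),
        cutoff=cutoff,
        provenance="displaced",
        weight=component.weight,
    )


def resample_binary(
    component: GaussianComponent,
    alpha: float,
    beta: float,
    cutoff: CutoffSpec,
    center_element: str = "X",
    neighbor_element: str = "X",
) -> tuple[RadialSF, RadialSF]:
    """Bracket the cluster with a lower/upper function pair.

    Centers at μ ± α·σ, both with width β·σ — an even-resolution
    alternative to the single displaced Gaussian.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"alpha and beta must be positive, got {alpha}, {beta}")
    mu, sigma = float(component.mean[0]), component.sigma
    eta = 1.0 / (2.0 * (beta * sigma) ** 2)
    common = dict(
        center_element=center_element,
        neighbor_element=neighbor_element,
        eta=eta,
        cutoff=cutoff,
        weight=component.weight,
    )
    lower = RadialSF(r_s=max(0.0, mu - alpha * sigma), provenance="binary_lower", **common)
    upper = RadialSF(r_s=mu + alpha * sigma, provenance="binary_upper", **common)
    return lower, upper


def uniform_radial_basis(
    n: int,
    r_min: float,
    cutoff: CutoffSpec,
    center_element: str = "X",
    neighbor_element: str = "X",
) -> list[RadialSF]:
    """Evenly distributed baseline: n centers over [r_min, r_c], half-height crossings."""
    if n < 2:
        raise ValueError(f"n must be at least 2, got {n}")
    if not 0 <= r_min < cutoff.r_c:
        raise ValueError(f"r_min must satisfy 0 ≤ r_min < r_c, got {r_min}")
    centers = np.linspace(r_min, cutoff.r_c, n)
    spacing = (cutoff.r_c - r_min) / (n - 1)
    eta = 4.0 * math.log(2.0) / spacing**2
    return [
        RadialSF(
            center_element=center_element,
            neighbor_element=neighbor_element,
            r_s=float(c),
            eta=eta,
            cutoff=cutoff,
            provenance="uniform",
        )
        for c in centers
    ]


def select_top_angular(
    sfs: Sequence[AngularSF], afrac: float = 1.0, nmax: int | None = None
) -> list[AngularSF]:
    """Keep the top fraction of angular functions by originating cluster weight.

    Functions are ranked by decreasing weight and the first
    ceil(afrac · min(len, nmax)) survive.
    """
    if not 0 < afrac <= 1:
        raise ValueError(f"afrac must be in (0, 1], got {afrac}")
    ranked = sorted(sfs, key=lambda s: -(s.weight if s.weight is not None else 0.0))
    cap = len(ranked) if nmax is None else min(len(ranked), nmax)
    keep = math.ceil(afrac * cap)
    return ranked[:keep]


# ---------------------------------------------------------------------------
# parameter-file I/O (delimited text + JSON mirror, bit-exact round trip)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "kind",
    "center",
    "neighbors",
    "variant",
    "r_s",
    "eta",
    "xi",
    "theta_s_deg",
    "lambda",
    "r_c",
    "cutoff_scheme",
    "provenance",
    "weight",
]


def _sf_row(sf: RadialSF | AngularSF) -> dict:
    if isinstance(sf, RadialSF):
        return {
            "kind": "radial",
            "center": sf.center_element,
            "neighbors": sf.neighbor_element,
            "variant": "",
            "r_s": repr(sf.r_s),
            "eta": repr(sf.eta),
            "xi": "",
            "theta_s_deg": "",
            "lambda": "",
            "r_c": repr(sf.cutoff.r_c),
            "cutoff_scheme": sf.cutoff.scheme,
            "provenance": sf.provenance,
            "weight": "" if sf.weight is None else repr(sf.weight),
        }
    return {
        "kind": "angular",
        "center": sf.center_element,
        "neighbors": ",".join(sf.neighbor_pair),
        "variant": sf.variant,
        "r_s": repr(sf.r_s),
        "eta": repr(sf.eta),
        "xi": repr(sf.xi),
        "theta_s_deg": "" if sf.theta_s is None else repr(math.degrees(sf.theta_s)),
        "lambda": "" if sf.lam is None else repr(float(sf.lam)),
        "r_c": repr(sf.cutoff.r_c),
        "cutoff_scheme": sf.cutoff.scheme,
        "provenance": sf.provenance,
        "weight": "" if sf.weight is None else repr(sf.weight),
    }


def write_sf_table(sfs: Sequence[RadialSF | AngularSF], path: str | Path) -> None:
    """Write one function per row as tab-separated text (full decimal precision).

    A ``.json`` mirror with the same fields is written alongside.
    """
    rows = [_sf_row(sf) for sf in sfs]
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(rows, indent=2) + "\n"
    )


def _sf_from_row(row: dict) -> RadialSF | AngularSF:
    cutoff = CutoffSpec(r_c=float(row["r_c"]), scheme=row["cutoff_scheme"])
    if row["kind"] == "radial":
        return RadialSF(
            center_element=row["center"],
            neighbor_element=row["neighbors"],
            r_s=float(row["r_s"]),
            eta=float(row["eta"]),
            cutoff=cutoff,
            provenance=row["provenance"],
            weight=float(row["weight"]) if row["weight"] else None,
        )
    return AngularSF(
        center_element=row["center"],
        neighbor_pair=tuple(row["neighbors"].split(",")),
        r_s=float(row["r_s"]),
        eta=float(row["eta"]),
        xi=float(row["xi"]),
        theta_s=math.radians(float(row["theta_s_deg"])) if row["theta_s_deg"] else None,
        lam=float(row["lambda"]) if row["lambda"] else None,
        cutoff=cutoff,
        variant=row["variant"],
        provenance=row["provenance"],
        weight=float(row["weight"]) if row["weight"] else None,
    )


def read_sf_table(path: str | Path) -> list[RadialSF | AngularSF]:
    """Read a parameter table written by :func:`write_sf_table`."""
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    return [_sf_from_row(row) for row in frame.to_dict("records")]
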