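"""Cluster → symmetry-function mapping, resampling layouts and selection."""

import math

import numpy as np
import pytest

from acsftune import (
    AngularSF,
    CutoffSpec,
    GaussianComponent,
    add_auxiliary,
    fit_xi,
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

CUT = CutoffSpec(7.0, "hard")


def comp1d(mu, sigma, w=1.0):
    return GaussianComponent(w, [mu], [[sigma**2]])


@pytest.mark.parametrize("mu,sigma,eta", [(2.0, 0.1, 50.0), (6.5, 0.5, 2.0)])
def test_map_radial_center_and_width(mu, sigma, eta):
    sf = map_radial(comp1d(mu, sigma), CUT)
    assert sf.r_s == pytest.approx(mu, abs=1e-14)
    assert sf.eta == pytest.approx(eta, abs=1e-12)


def test_mapped_sf_at_one_sigma_is_exp_minus_half():
    sf = map_radial(comp1d(2.0, 0.1), CUT)
    for r in (1.9, 2.1):
        value = math.exp(-sf.eta * (r - sf.r_s) ** 2)
        assert value == pytest.approx(math.exp(-0.5), abs=1e-12)


def test_map_radial_rejects_degenerate_width():
    with pytest.raises(ValueError):
        GaussianComponent(1.0, [2.0], [[0.0]])


def test_map_angular_reduces_to_radial_mapping_for_equal_marginals():
    cov = np.diag([0.1**2, 0.1**2, 0.2**2])
    comp = GaussianComponent(1.0, [2.0, 2.0, math.radians(104.5)], cov)
    sf = map_angular(comp, CutoffSpec(3.5, "hard"))
    assert sf.variant == "heavily_modified"
    assert sf.r_s == pytest.approx(2.0, abs=1e-12)
    assert sf.eta == pytest.approx(50.0, abs=1e-10)
    assert sf.theta_s == pytest.approx(math.radians(104.5), abs=1e-12)


def test_flat_angular_cluster_drives_xi_to_its_floor():
    assert fit_xi(math.pi / 2, sigma_theta=10.0) == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("sigma_theta", [0.1, 0.2, 0.4])
def test_fitted_xi_matches_dense_grid_oracle(sigma_theta):
    """Bracketing + refinement agrees with a brute-force ξ grid within 5%."""
    mu = math.pi / 2
    theta = np.linspace(0.0, math.pi, 181)
    target = np.exp(-((theta - mu) ** 2) / (2 * sigma_theta**2))
    grid = np.linspace(1.0, 500.0, 20_000)
    losses = [
        np.sum((2.0 ** (1 - x) * (1 + np.cos(theta - mu)) ** x / 2.0 - target) ** 2)
        for x in grid
    ]
    oracle = grid[int(np.argmin(losses))]
    fitted = fit_xi(mu, sigma_theta)
    assert fitted == pytest.approx(oracle, rel=0.05)


@pytest.mark.parametrize("sigma_theta", [0.05, 0.1, 0.2, 0.35, 0.5])
def test_xi_kernel_width_tracks_gaussian_fwhm(sigma_theta):
    """FWHM of the fitted cosine-power kernel matches the Gaussian's within 15%."""
    mu = math.pi / 2
    xi = fit_xi(mu, sigma_theta)
    gauss_fwhm = 2 * math.sqrt(2 * math.log(2)) * sigma_theta
    # kernel half height: 2^(1−ξ)(1+cos δ)^ξ = 2^(1−ξ)·2^ξ/2 ⇒ (1+cos δ) = 2^(1−1/ξ)·... solve numerically
    delta = np.linspace(0, math.pi, 200_001)
    kernel = 2.0 ** (1 - xi) * (1 + np.cos(delta)) ** xi / 2.0
    half = delta[np.argmin(np.abs(kernel - 0.5))]
    assert 2 * half == pytest.approx(gauss_fwhm, rel=0.15)


def test_auxiliary_inserted_between_sparse_pair():
    sfs = [map_radial(comp1d(1.0, 0.05), CUT), map_radial(comp1d(5.0, 0.05), CUT)]
    out = add_auxiliary(sfs, min_overlap=0.01)
    assert len(out) == 3
    aux = [sf for sf in out if sf.provenance == "auxiliary"][0]
    assert aux.r_s == pytest.approx(3.0, abs=1e-12)
    assert aux.sigma == pytest.approx(2.0, abs=1e-12)  # half the center gap
    # originals untouched
    assert {sf.r_s for sf in out if sf.provenance == "tailor"} == {1.0, 5.0}


def test_no_auxiliary_for_overlapping_pair():
    sfs = [map_radial(comp1d(2.0, 0.5), CUT), map_radial(comp1d(2.4, 0.5), CUT)]
    assert len(add_auxiliary(sfs, min_overlap=0.01)) == 2


def test_auxiliary_chain_matches_pairwise_scan_oracle():
    centers = [1.0, 2.5, 4.0, 5.5]
    sfs = [map_radial(comp1d(c, 0.05), CUT) for c in centers]
    out = add_auxiliary(sfs, min_overlap=0.01)
    # oracle: brute-force adjacent-pair scan
    expected_insertions = 0
    for a, b in zip(centers, centers[1:]):
        mid = (a + b) / 2
        if math.exp(-(mid - a) ** 2 / (2 * 0.05**2)) < 0.01:
            expected_insertions += 1
    assert expected_insertions == 3
    assert len(out) == 4 + expected_insertions
    with pytest.raises(ValueError):
        add_auxiliary(sfs, min_overlap=1.5)


def test_decomposed_k1_degenerates_to_plain_mapping():
    comp = comp1d(2.0, 0.1)
    sub = resample_decomposed(comp, 1, CUT)
    base = map_radial(comp, CUT)
    assert len(sub) == 1
    assert sub[0].r_s == base.r_s and sub[0].eta == base.eta
    assert sub[0].provenance == "decomposed"


def test_decomposed_k2_centers():
    sub = resample_decomposed(comp1d(2.0, 0.1), 2, CUT)
    assert [sf.r_s for sf in sub] == pytest.approx([1.9, 2.1], abs=1e-12)


def test_decomposed_k4_grid_and_half_height_crossing():
    sub = resample_decomposed(comp1d(2.0, 0.1), 4, CUT)
    centers = [sf.r_s for sf in sub]
    spacing = 2 * 0.1 / 3
    assert np.allclose(np.diff(centers), spacing, atol=1e-12)
    assert np.allclose(np.array(centers) + np.array(centers)[::-1], 4.0, atol=1e-12)
    # adjacent subcomponents cross at half height
    mid = (centers[0] + centers[1]) / 2
    val = math.exp(-sub[0].eta * (mid - centers[0]) ** 2)
    assert val == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(ValueError):
        resample_decomposed(comp1d(2.0, 0.1), 0, CUT)


def test_displaced_offset_and_width():
    sf = resample_displaced(comp1d(2.0, 0.1), 3.0, CUT)
    assert sf.r_s == pytest.approx(2.3, abs=1e-12)
    assert sf.eta == pytest.approx(1 / (2 * 0.09), abs=1e-10)
    with pytest.raises(ValueError):
        resample_displaced(comp1d(2.0, 0.1), -1.0, CUT)


def test_displaced_sf_monotone_over_cluster_span():
    sf = resample_displaced(comp1d(2.0, 0.1), 3.0, CUT)
    r = np.linspace(2.0 - 0.3, 2.0 + 0.3, 500)
    values = np.exp(-sf.eta * (r - sf.r_s) ** 2)
    assert np.all(np.diff(values) > 0)


def test_three_sigma_cluster_coverage():
    """The α = 3 displaced span [μ−3σ, μ+3σ] holds 99.7% of the population."""
    from scipy.stats import norm

    coverage = norm.cdf(3.0) - norm.cdf(-3.0)
    assert coverage == pytest.approx(0.997, abs=5e-4)


def test_binary_pair_centers_and_symmetry():
    lower, upper = resample_binary(comp1d(2.0, 0.1), 3.0, 1.0, CUT)
    assert (lower.r_s, upper.r_s) == pytest.approx((1.7, 2.3), abs=1e-12)
    assert lower.eta == upper.eta == pytest.approx(50.0, abs=1e-10)
    # equal values exactly at the centroid
    at_mu = lambda sf: math.exp(-sf.eta * (2.0 - sf.r_s) ** 2)
    assert at_mu(lower) == pytest.approx(at_mu(upper), abs=1e-15)
    # β = α reproduces the displaced width
    lo2, _ = resample_binary(comp1d(2.0, 0.1), 3.0, 3.0, CUT)
    disp = resample_displaced(comp1d(2.0, 0.1), 3.0, CUT)
    assert lo2.eta == pytest.approx(disp.eta, abs=1e-12)


def test_binary_difference_monotone_across_cluster():
    lower, upper = resample_binary(comp1d(2.0, 0.1), 3.0, 1.0, CUT)
    r = np.linspace(1.7, 2.3, 400)
    diff = np.exp(-upper.eta * (r - upper.r_s) ** 2) - np.exp(
        -lower.eta * (r - lower.r_s) ** 2
    )
    assert np.all(np.diff(diff) > 0)


def test_uniform_basis_two_points():
    basis = uniform_radial_basis(2, 1.0, CUT)
    assert [sf.r_s for sf in basis] == [1.0, 7.0]
    assert basis[0].eta == pytest.approx(math.log(2) * (2 / 6) ** 2, abs=1e-12)


def test_uniform_basis_29_functions_equal_crossings():
    basis = uniform_radial_basis(29, 0.5, CUT)
    assert len(basis) == 29
    heights = []
    for a, b in zip(basis, basis[1:]):
        mid = (a.r_s + b.r_s) / 2
        heights.append(math.exp(-a.eta * (mid - a.r_s) ** 2))
    assert np.allclose(heights, 0.5, atol=1e-12)
    with pytest.raises(ValueError):
        uniform_radial_basis(3, 8.0, CUT)


def _angular_with_weight(w):
    return AngularSF(
        "O", ("H", "H"), r_s=1.0, eta=10.0, xi=4.0, theta_s=1.8,
        cutoff=CutoffSpec(3.5, "hard"), weight=w,
    )


def test_select_top_angular_rules():
    sfs = [_angular_with_weight(w) for w in np.linspace(0.01, 0.3, 10)]
    assert select_top_angular(sfs, afrac=1.0, nmax=None) == sorted(
        sfs, key=lambda s: -s.weight
    )
    top5 = select_top_angular(sfs, afrac=0.5, nmax=None)
    assert len(top5) == 5
    assert min(s.weight for s in top5) >= max(
        s.weight for s in sfs if s not in top5
    )
    sfs30 = [_angular_with_weight(w) for w in np.linspace(0.01, 0.3, 30)]
    assert len(select_top_angular(sfs30, afrac=1.0, nmax=20)) == 20
    with pytest.raises(ValueError):
        select_top_angular(sfs, afrac=0.0)


def test_sf_table_round_trip_exact(tmp_path):
    comp = comp1d(2.0, 0.1, w=0.7)
    cut_soft = CutoffSpec(7.0, "soft")
    sfs = [
        map_radial(comp, cut_soft, "O", "H"),
        resample_displaced(comp, 3.0, CUT, "O", "H"),
        map_angular(
            GaussianComponent(0.4, [1.0, 1.1, 1.9], np.diag([0.01, 0.01, 0.04])),
            CutoffSpec(3.5, "hard"), "O", ("H", "H"),
        ),
        AngularSF("C", ("H", "O"), 1.0, 5.0, 8.0, CutoffSpec(3.5, "soft"),
                  variant="standard", lam=1.0),
    ]
    path = tmp_path / "sf.tsv"
    write_sf_table(sfs, path)
    back = read_sf_table(path)
    assert len(back) == len(sfs)
    for a, b in zip(sfs, back):
        assert type(a) is type(b)
        assert a.r_s == b.r_s and a.eta == b.eta  # bit-exact via repr
        if isinstance(a, AngularSF):
            assert a.xi == b.xi
            if a.theta_s is not None:
                assert b.theta_s == pytest.approx(a.theta_s, abs=1e-14)
    assert path.with_suffix(".tsv.json").exists()
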