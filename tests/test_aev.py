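"""Symmetry-function evaluation, AEV assembly, normalization and pruning."""

import math

import numpy as np
import pytest

from acsftune import (
    AngularSF,
    CutoffSpec,
    Frame,
    RadialSF,
    SFSet,
    apply_normalizer,
    build_element_matrices,
    build_feature_matrix,
    eval_angular_sf,
    eval_radial_sf,
    fit_normalizer,
    prune_dead,
    uniform_radial_basis,
)
from tests.conftest import apply_rigid, random_rigid_motion, water_geometry

HARD7 = CutoffSpec(7.0, "hard")
HARD35 = CutoffSpec(3.5, "hard")


def test_neighbor_exactly_at_center_gives_unity():
    frame = Frame(("C", "O"), np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]))
    sf = RadialSF("C", "O", r_s=1.5, eta=8.0, cutoff=HARD7)
    assert eval_radial_sf(frame, 0, sf) == pytest.approx(1.0, abs=1e-14)


def test_neighbor_beyond_cutoff_contributes_nothing():
    frame = Frame(("C", "O"), np.array([[0.0, 0.0, 0.0], [7.5, 0.0, 0.0]]))
    sf = RadialSF("C", "O", r_s=1.5, eta=8.0, cutoff=HARD7)
    assert eval_radial_sf(frame, 0, sf) == 0.0


def test_center_element_mismatch_is_an_error(water_frame):
    sf = RadialSF("O", "H", r_s=1.0, eta=8.0, cutoff=HARD7)
    with pytest.raises(ValueError, match="centered on O"):
        eval_radial_sf(water_frame, 1, sf)
    asf = AngularSF("O", ("H", "H"), 1.0, 8.0, 4.0, HARD35, theta_s=1.8)
    with pytest.raises(ValueError, match="centered on O"):
        eval_angular_sf(water_frame, 2, asf)


def test_radial_sum_matches_term_by_term_enumeration():
    rng = np.random.default_rng(0)
    coords = np.vstack([[0.0, 0.0, 0.0], rng.uniform(-2, 2, (3, 3))])
    frame = Frame(("C", "H", "H", "H"), coords)
    sf = RadialSF("C", "H", r_s=1.2, eta=4.0, cutoff=CutoffSpec(7.0, "soft"))
    manual = 0.0
    for j in range(1, 4):
        r = frame.distance(0, j)
        fc = 0.5 * (math.cos(math.pi * r / 7.0) + 1) if r <= 7.0 else 0.0
        manual += math.exp(-4.0 * (r - 1.2) ** 2) * fc
    assert eval_radial_sf(frame, 0, sf) == pytest.approx(manual, abs=1e-12)


def test_heavily_modified_kernel_maximum_is_two(water_frame):
    theta = water_frame.angle(1, 0, 2)
    sf = AngularSF("O", ("H", "H"), r_s=0.96, eta=50.0, xi=16.0, cutoff=HARD35,
                   theta_s=theta)
    assert eval_angular_sf(water_frame, 0, sf) == pytest.approx(2.0, abs=1e-12)


def test_standard_variant_vanishes_at_pi_with_positive_lambda():
    frame = Frame(
        ("C", "O", "O"),
        np.array([[0.0, 0.0, 0.0], [-1.16, 0.0, 0.0], [1.16, 0.0, 0.0]]),
    )
    sf = AngularSF("C", ("O", "O"), 0.0, 0.5, 4.0, HARD35, variant="standard", lam=1.0)
    assert eval_angular_sf(frame, 0, sf) == pytest.approx(0.0, abs=1e-14)


def test_standard_and_modified_variants_differ_by_jk_term(water_frame):
    common = dict(r_s=0.0, eta=0.5, xi=2.0, cutoff=HARD35, lam=-1.0)
    std = AngularSF("O", ("H", "H"), variant="standard", **common)
    mod = AngularSF("O", ("H", "H"), variant="modified", **common)
    rij = rik = 0.96
    rjk = water_frame.distance(1, 2)
    theta = water_frame.angle(1, 0, 2)
    kernel = 2.0 ** (1 - 2.0) * (1 - math.cos(theta)) ** 2.0
    assert eval_angular_sf(water_frame, 0, std) == pytest.approx(
        kernel * math.exp(-0.5 * (rij**2 + rik**2 + rjk**2)), abs=1e-12
    )
    assert eval_angular_sf(water_frame, 0, mod) == pytest.approx(
        kernel * math.exp(-0.5 * (rij**2 + rik**2)), abs=1e-12
    )


def test_like_element_neighbor_swap_leaves_value_unchanged():
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.1, 0.0]])
    frame = Frame(("O", "H", "H"), coords)
    swapped = Frame(("O", "H", "H"), coords[[0, 2, 1]])
    sf = AngularSF("O", ("H", "H"), 1.0, 8.0, 4.0, HARD35, theta_s=1.6)
    assert eval_angular_sf(frame, 0, sf) == pytest.approx(
        eval_angular_sf(swapped, 0, sf), abs=1e-14
    )


def _toy_sfsets(n=5):
    cut = HARD7
    sets = {}
    for el in ("H", "O"):
        radial = [
            RadialSF(el, nb, r_s=rs, eta=6.0, cutoff=cut)
            for nb in ("H", "O")
            for rs in np.linspace(0.8, 2.4, n)
        ]
        sets[el] = SFSet(el, radial=radial[:n])
    return sets


def test_feature_matrix_shape_and_row_order(water_frame):
    sets = _toy_sfsets(5)
    matrix = build_feature_matrix([water_frame], sets)
    assert matrix.shape == (3, 5)
    assert [r[2] for r in matrix.row_index] == ["O", "H", "H"]
    assert np.all(matrix.values >= 0)


def test_duplicated_frame_duplicates_rows(water_frame):
    sets = _toy_sfsets(4)
    m2 = build_feature_matrix([water_frame, water_frame], sets)
    np.testing.assert_array_equal(m2.values[:3], m2.values[3:])


def test_missing_sfset_names_the_element(water_frame):
    sets = _toy_sfsets(3)
    del sets["H"]
    with pytest.raises(ValueError, match="H"):
        build_feature_matrix([water_frame], sets)


def test_unequal_sfset_lengths_direct_to_element_matrices(water_frame):
    sets = _toy_sfsets(3)
    sets["O"] = SFSet("O", radial=sets["O"].radial[:2])
    with pytest.raises(ValueError, match="element_matrices"):
        build_feature_matrix([water_frame], sets)
    per_el = build_element_matrices([water_frame], sets)
    assert per_el["O"].shape == (1, 2)
    assert per_el["H"].shape == (2, 3)


def test_aev_invariance_under_rigid_motion_and_permutation():
    rng = np.random.default_rng(42)
    frame = water_geometry()
    sets = _toy_sfsets(6)
    base = build_feature_matrix([frame], sets).values
    for _ in range(5):
        Q, t = random_rigid_motion(rng)
        moved = apply_rigid(frame, Q, t)
        np.testing.assert_allclose(
            build_feature_matrix([moved], sets).values, base, atol=1e-10
        )
    permuted = Frame(frame.elements, frame.coordinates[[0, 2, 1]])
    perm_vals = build_feature_matrix([permuted], sets).values
    np.testing.assert_allclose(perm_vals[[0, 2, 1]], base, atol=1e-10)


def test_soft_cutoff_aevs_continuous_across_rc():
    eps = 1e-8
    sf = RadialSF("C", "O", r_s=6.0, eta=0.5, cutoff=CutoffSpec(7.0, "soft"))
    below = Frame(("C", "O"), np.array([[0, 0, 0], [7.0 - eps, 0, 0]], dtype=float))
    above = Frame(("C", "O"), np.array([[0, 0, 0], [7.0 + eps, 0, 0]], dtype=float))
    assert abs(eval_radial_sf(below, 0, sf) - eval_radial_sf(above, 0, sf)) < 1e-6


def test_min_max_normalization_contract(water_frame):
    sets = _toy_sfsets(4)
    matrix = build_feature_matrix([water_frame] * 3, sets)
    matrix.values[:, 0] = [2.0, 6.0, 4.0, 1.0, 8.0, 4.0, 4.0, 4.0, 4.0][: len(matrix.row_index)]
    matrix.values[:, 1] = 3.0  # constant column
    record = fit_normalizer(matrix, training_rows=[0, 1, 2])
    normed = apply_normalizer(matrix, record)
    assert normed.values[2, 0] == pytest.approx(0.5)  # 4 in [2, 6]
    assert np.all(normed.values[:3, 0] >= 0) and np.all(normed.values[:3, 0] <= 1)
    # rows outside the training subset may leave [0, 1]
    assert normed.values[4, 0] > 1.0
    np.testing.assert_array_equal(normed.values[:, 1], 0.0)
    with pytest.raises(ValueError):
        fit_normalizer(matrix, training_rows=[])


def test_prune_dead_matches_brute_force_scan(water_spec):
    from acsftune import generate_trajectory

    traj = generate_trajectory(water_spec, 50, seed=3)
    cut = HARD7
    basis = uniform_radial_basis(20, 0.5, cut, "O", "H")
    sets = {
        "O": SFSet("O", radial=basis),
        "H": SFSet("H", radial=[
            RadialSF("H", "O", sf.r_s, sf.eta, cut, "uniform") for sf in basis
        ]),
    }
    matrix = build_feature_matrix(traj.frames, sets)
    kept = prune_dead(matrix, 1e-8)
    brute = [c for c in range(matrix.shape[1]) if matrix.values[:, c].max() >= 1e-8]
    np.testing.assert_array_equal(kept, brute)
    assert len(kept) < matrix.shape[1]  # the basis deliberately overshoots the sampled range
    with pytest.raises(ValueError):
        prune_dead(matrix, 0.0)


def test_identically_zero_column_dropped_single_activation_kept():
    matrix_values = np.array([[0.0, 0.0], [0.0, 0.5]])
    from acsftune.aev import FeatureMatrix

    m = FeatureMatrix(matrix_values, [(0, 0, "H"), (0, 1, "H")], ["a", "b"])
    np.testing.assert_array_equal(prune_dead(m, 1e-8), [1])


def test_conformer_separability_in_aev_space(two_conformer_spec):
    """AEVs separate the two conformer clusters linearly; raw coordinates,
    scrambled by random rigid motions, do not."""
    from sklearn.linear_model import LogisticRegression

    from acsftune import generate_trajectory

    traj = generate_trajectory(two_conformer_spec, 300, seed=9)
    labels = np.array([1 if f.distance(0, 1) > 1.05 else 0 for f in traj])
    cut = HARD7
    sets = {
        "O": SFSet("O", radial=uniform_radial_basis(8, 0.5, cut, "O", "H")),
        "H": SFSet("H", radial=uniform_radial_basis(8, 0.5, cut, "H", "O")),
    }
    matrices = build_element_matrices(traj.frames, sets)
    X = matrices["O"].values
    aev_acc = LogisticRegression(max_iter=2000).fit(X, labels).score(X, labels)
    assert aev_acc > 0.97
    rng = np.random.default_rng(0)
    raw = []
    for frame in traj:
        Q, t = random_rigid_motion(rng)
        raw.append(apply_rigid(frame, Q, t).coordinates.ravel())
    raw = np.asarray(raw)
    raw_acc = LogisticRegression(max_iter=2000).fit(raw, labels).score(raw, labels)
    assert raw_acc < aev_acc - 0.2
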