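"""Perturbation chains, information entropy, zoning, boundary weights."""

import numpy as np
import pytest

from soilrisk.distributions import DistributionSpec
from soilrisk.geodetector import StrataData, factor_q
from soilrisk.pollution import GradeScheme, ScreeningStandard
from soilrisk.spatial import RasterLayer
from soilrisk.synthetic import (
    SamplePoint,
    generate_factor_raster,
    generate_response_with_known_q,
    generate_sample_points,
)
from soilrisk.uncertainty import (
    ClassDistribution,
    PerturbationConfig,
    control_zoning,
    gdm_uncertainty,
    information_entropy,
    neighborhood_weights,
    perturb_classification,
    perturb_points,
    pollution_mcs,
)


def _one_point():
    return [SamplePoint(1000.0, 2000.0, {"Cr": 50.0}, ph=6.0)]


class TestPerturbPoints:
    def test_degenerate_config_is_identity(self):
        cfg = PerturbationConfig(
            n_iter=10, n_keep=5, position_sigma=0.0,
            concentration_specs={"Cr": DistributionSpec("point", (50.0,))},
        )
        (p,) = perturb_points(_one_point(), cfg, iteration=3)
        assert (p.x, p.y, p.conc["Cr"], p.ph) == (1000.0, 2000.0, 50.0, 6.0)

    def test_reproducible_per_iteration(self):
        cfg = PerturbationConfig(n_iter=10, n_keep=5, seed=4)
        a = perturb_points(_one_point(), cfg, iteration=7)
        b = perturb_points(_one_point(), cfg, iteration=7)
        c = perturb_points(_one_point(), cfg, iteration=8)
        assert a[0].x == b[0].x and a[0].y == b[0].y
        assert a[0].x != c[0].x

    def test_positional_sigma(self):
        """SD of X-displacement over many perturbations is ~10 m."""
        cfg = PerturbationConfig(n_iter=10, n_keep=5, position_sigma=10.0, seed=1)
        dx = np.array(
            [perturb_points(_one_point(), cfg, it)[0].x - 1000.0 for it in range(20_000)]
        )
        assert dx.std(ddof=1) == pytest.approx(10.0, rel=0.03)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            PerturbationConfig(position_sigma=-1.0)


def _dist(counts_2d_list, labels=("a", "b", "c")):
    counts = np.asarray(counts_2d_list)
    grid = RasterLayer((0.0, float(10 * counts.shape[1])), 10.0,
                       np.zeros(counts.shape[1:]))
    return ClassDistribution(counts=counts, labels=tuple(labels),
                             grid=grid, n_keep=int(counts.sum(axis=0).max()))


class TestEntropy:
    def test_certain_outcome_is_zero(self):
        d = _dist([[[3000]], [[0]], [[0]]])
        assert information_entropy(d).values[0, 0] == 0.0

    def test_uniform_is_log_m(self):
        d = _dist([[[1000]], [[1000]], [[1000]]])
        assert information_entropy(d).values[0, 0] == pytest.approx(np.log(3), abs=1e-12)

    def test_near_degenerate_direct_sum(self):
        d = _dist([[[2999]], [[1]], [[0]]])
        expected = -(2999 / 3000) * np.log(2999 / 3000) - (1 / 3000) * np.log(1 / 3000)
        assert information_entropy(d).values[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_random_counts_match_oracle(self, rng):
        counts = rng.integers(0, 50, size=(4, 6, 6))
        counts[:, 0, 0] = 0  # a nodata cell
        d = _dist(counts, labels=list("wxyz"))
        ent = information_entropy(d)
        assert ent.values[0, 0] == ent.nodata
        for i in range(6):
            for j in range(6):
                if (i, j) == (0, 0):
                    continue
                c = counts[:, i, j].astype(float)
                p = c[c > 0] / c.sum()
                assert ent.values[i, j] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)

    def test_bounds_and_base2(self, rng):
        counts = rng.integers(1, 40, size=(5, 8, 8))
        d = _dist(counts, labels=list("abcde"))
        ent = information_entropy(d)
        assert (ent.values >= 0).all() and (ent.values <= np.log(5) + 1e-12).all()
        ent2 = information_entropy(d, base="2")
        assert np.allclose(ent2.values, ent.values / np.log(2))


class TestControlZoning:
    def test_hand_built_two_by_two(self):
        risk = RasterLayer((0, 20), 10.0, np.array([[0.5, 0.5], [2.0, 2.0]]))
        ent = RasterLayer((0, 20), 10.0, np.array([[0.1, 0.9], [0.1, 0.9]]))
        zones = control_zoning(risk, ent, risk_threshold=1.0, entropy_threshold=0.5)
        assert zones.values.tolist() == [[1, 2], [3, 4]]

    def test_all_low(self):
        risk = RasterLayer((0, 20), 10.0, np.zeros((2, 2)))
        ent = RasterLayer((0, 20), 10.0, np.zeros((2, 2)))
        zones = control_zoning(risk, ent, 1.0, 0.5)
        assert (zones.values == 1).all()

    def test_median_thresholds_partition(self, rng):
        vals_r = rng.uniform(0, 3, (10, 10))
        vals_e = rng.uniform(0, 1.5, (10, 10))
        risk = RasterLayer((0, 100), 10.0, vals_r)
        ent = RasterLayer((0, 100), 10.0, vals_e)
        zones = control_zoning(risk, ent, np.median(vals_r), np.median(vals_e))
        labels, counts = np.unique(zones.values, return_counts=True)
        assert set(labels) == {1, 2, 3, 4}
        assert counts.sum() == 100

    def test_misaligned_rejected(self):
        risk = RasterLayer((0, 20), 10.0, np.zeros((2, 2)))
        ent = RasterLayer((0, 30), 10.0, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            control_zoning(risk, ent, 1.0, 0.5)


def brute_force_ck(values, nodata, i, j, window=5):
    """25-term direct evaluation of the inverse-distance category weights."""
    half = window // 2
    entries = []
    for x in range(i - half, i + half + 1):
        for y in range(j - half, j + half + 1):
            if 0 <= x < values.shape[0] and 0 <= y < values.shape[1]:
                if values[x, y] != nodata:
                    d = np.sqrt((x - i) ** 2 + (y - j) ** 2) + 1.0
                    entries.append((values[x, y], 1.0 / d))
    total = sum(w for _, w in entries)
    ck = {}
    for lab, w in entries:
        ck[lab] = ck.get(lab, 0.0) + w / total
    return ck


class TestNeighborhoodWeights:
    def test_homogeneous_window(self):
        ras = RasterLayer((0, 70), 10.0, np.full((7, 7), 3), nodata=-1, kind="categorical")
        nw = neighborhood_weights(ras, 3, 3)
        assert nw.ck == {3: pytest.approx(1.0)}

    def test_center_unique_category_dominates(self):
        vals = np.ones((7, 7), dtype=int)
        vals[3, 3] = 2
        ras = RasterLayer((0, 70), 10.0, vals, nodata=-1, kind="categorical")
        nw = neighborhood_weights(ras, 3, 3)
        # center's own D = 1 gives the largest single-pixel weight
        oracle = brute_force_ck(vals, -1, 3, 3)
        assert nw.ck[2] == pytest.approx(oracle[2], abs=1e-12)
        assert nw.ck[2] == pytest.approx(max(nw.weights.ravel()), abs=1e-12)

    def test_two_category_pattern_against_oracle(self, rng):
        vals = rng.integers(1, 3, size=(9, 9))
        ras = RasterLayer((0, 90), 10.0, vals, nodata=-1, kind="categorical")
        for (i, j) in [(4, 4), (0, 0), (8, 2), (1, 7)]:  # interior + borders
            nw = neighborhood_weights(ras, i, j)
            oracle = brute_force_ck(vals, -1, i, j)
            assert set(nw.ck) == set(oracle)
            for k in oracle:
                assert nw.ck[k] == pytest.approx(oracle[k], abs=1e-12)
            assert sum(nw.ck.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_nodata_rejected(self):
        ras = RasterLayer((0, 30), 10.0, np.full((3, 3), -1), nodata=-1, kind="categorical")
        with pytest.raises(ValueError):
            neighborhood_weights(ras, 1, 1)


class TestPerturbClassification:
    def test_homogeneous_fixed_point(self):
        ras = RasterLayer((0, 80), 10.0, np.full((8, 8), 2), nodata=-1, kind="categorical")
        out = perturb_classification(ras, seed=3)
        assert np.array_equal(out.values, ras.values)

    def test_label_set_preserved(self, rng):
        vals = rng.integers(1, 5, size=(12, 12))
        ras = RasterLayer((0, 120), 10.0, vals, nodata=-1, kind="categorical")
        out = perturb_classification(ras, seed=8)
        assert set(np.unique(out.values)) <= set(np.unique(vals))

    def test_nodata_unchanged(self, rng):
        vals = rng.integers(1, 4, size=(10, 10))
        vals[2, 3] = -1
        ras = RasterLayer((0, 100), 10.0, vals, nodata=-1, kind="categorical")
        out = perturb_classification(ras, seed=1)
        assert out.values[2, 3] == -1

    def test_assignment_frequencies_match_ck(self):
        """Empirical category frequencies of one cell track its C_k weights."""
        vals = np.ones((5, 5), dtype=int)
        vals[:, 3:] = 2
        ras = RasterLayer((0, 50), 10.0, vals, nodata=-1, kind="categorical")
        nw = neighborhood_weights(ras, 2, 2)
        n = 4000
        hits = sum(
            perturb_classification(ras, seed=s).values[2, 2] == 1 for s in range(n)
        )
        p = nw.ck[1]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


def _toy_setup():
    std = ScreeningStandard.from_dict({"Cr": 150.0})
    scheme = GradeScheme()
    return std, scheme


class TestPollutionMcs:
    def test_count_conservation_and_degenerate(self, small_region):
        pts = generate_sample_points(small_region, 50, seed=2)
        std, scheme = _toy_setup()
        cfg = PerturbationConfig(
            n_iter=8, n_keep=4, position_sigma=0.0,
            concentration_specs={}, seed=5,
        )
        dist, _ = pollution_mcs(pts, small_region, std, scheme, cfg)
        totals = dist.counts.sum(axis=0)
        assert (totals == 4).all()
        # no randomness -> every cell's mass on a single class
        assert (dist.counts.max(axis=0) == 4).all()

    def test_hand_checkable_two_point_iteration(self):
        """Single element, two points, 1-cell grid: Pn per iteration by hand."""
        from shapely.geometry import box

        from soilrisk.synthetic import StudyRegion

        region = StudyRegion(polygon=box(0, 0, 10, 10), cell_size=10.0, nrows=1, ncols=1)
        pts = [
            SamplePoint(0.0, 5.0, {"Cr": 150.0}, ph=6.0),
            SamplePoint(10.0, 5.0, {"Cr": 450.0}, ph=6.0),
        ]
        std, scheme = _toy_setup()
        cfg = PerturbationConfig(n_iter=3, n_keep=3, position_sigma=0.0, seed=0)
        dist, stack = pollution_mcs(
            pts, region, std, scheme, cfg, k_neighbors=2, pn_stack_every=1
        )
        # equidistant points -> conc = 300, Pi = 2 = Pave = Pmax -> Pn = 2
        for ras in stack:
            assert ras.values[0, 0] == pytest.approx(2.0)
        assert dist.counts[scheme.index_of(2.0), 0, 0] == 3

    def test_stack_thinning(self, small_region):
        pts = generate_sample_points(small_region, 30, seed=9)
        std, scheme = _toy_setup()
        cfg = PerturbationConfig(n_iter=6, n_keep=6, seed=1)
        _, stack = pollution_mcs(
            pts, small_region, std, scheme, cfg, pn_stack_every=2
        )
        assert len(stack) == 3


class TestGdmUncertainty:
    def test_single_category_immune(self, small_region):
        ras = RasterLayer(
            small_region.origin, 1000.0,
            np.ones((small_region.nrows, small_region.ncols), dtype=int),
            nodata=-1, kind="categorical",
        )
        strata = generate_factor_raster(small_region, 4, seed=2)
        y = generate_response_with_known_q(strata, 0.5, seed=3)
        res = gdm_uncertainty(y, {"flat": ras}, n_runs=5, seed=1)
        assert res.factor_sd["flat"] == 0.0

    def test_q_samples_and_sd(self, small_region):
        a = generate_factor_raster(small_region, 4, seed=5)
        b = generate_factor_raster(small_region, 3, seed=6)
        y = generate_response_with_known_q(a, 0.6, seed=7)
        res = gdm_uncertainty(y, {"a": a, "b": b}, n_runs=6, seed=9)
        assert res.factor_samples.shape == (6, 2)
        assert list(res.interaction_samples.columns) == ["a*b"]
        assert ((res.factor_samples >= 0) & (res.factor_samples <= 1)).all().all()
        assert res.factor_sd["a"] >= 0

    def test_narrow_patches_more_perturbable(self, small_region):
        """Boundary-dense stratifications show larger q spread under perturbation."""
        narrow = generate_factor_raster(small_region, 40, "voronoi", seed=11)
        wide = generate_factor_raster(small_region, 3, "blocks", seed=11)
        y = generate_response_with_known_q(narrow, 0.5, seed=12)
        rn = gdm_uncertainty(y, {"f": narrow}, n_runs=30, seed=13)
        rw = gdm_uncertainty(y, {"f": wide}, n_runs=30, seed=13)
        assert rn.factor_sd["f"] > rw.factor_sd["f"]

    def test_reproducible(self, small_region):
        a = generate_factor_raster(small_region, 4, seed=5)
        y = generate_response_with_known_q(a, 0.4, seed=1)
        r1 = gdm_uncertainty(y, {"a": a}, n_runs=4, seed=2)
        r2 = gdm_uncertainty(y, {"a": a}, n_runs=4, seed=2)
        assert r1.factor_samples.equals(r2.factor_samples)
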