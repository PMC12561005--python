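import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cafprox as cp
from cafprox import CellTable, CellType, SimulationConfig
from conftest import offspring_fraction


def table_from_xy(xy, cell_type=CellType.CAF, prefix="s"):
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    return CellTable.from_arrays(xy[:, 0], xy[:, 1], cell_type, prefix)


def brute_force_nn(sxy, txy):
    """O(n*m) pairwise minimum; per-pair distances via the same hypot
    primitive as the implementation so equality is bit-exact."""
    sxy = np.atleast_2d(np.asarray(sxy, float))
    txy = np.atleast_2d(np.asarray(txy, float))
    d = np.hypot(
        sxy[:, 0][:, None] - txy[:, 0][None, :],
        sxy[:, 1][:, None] - txy[:, 1][None, :],
    )
    return d.min(axis=1)


class TestNearestNeighborDistances:
    def test_pythagorean_triple(self):
        res = cp.nearest_neighbor_distances(
            table_from_xy([(0, 0)]), table_from_xy([(3, 4), (6, 8)], CellType.OSCC, "t")
        )
        assert res.distances.tolist() == [5.0]

    def test_coincident_source_and_target(self):
        res = cp.nearest_neighbor_distances(
            table_from_xy([(1, 1)]), table_from_xy([(1, 1)], CellType.OSCC, "t")
        )
        assert res.distances.tolist() == [0.0]

    def test_empty_targets_rejected(self):
        with pytest.raises(cp.EmptyTargetError):
            cp.nearest_neighbor_distances(
                table_from_xy([(0, 0)]), CellTable.empty()
            )

    def test_matches_brute_force_exactly_on_200_instances(self):
        """KD-tree accelerated distances == O(n*m) pairwise minima, bit-exact."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n, m = rng.integers(1, 40), rng.integers(1, 20)
            sxy = rng.uniform(0, 1000, (n, 2))
            txy = rng.uniform(0, 1000, (m, 2))
            res = cp.nearest_neighbor_distances(
                table_from_xy(sxy), table_from_xy(txy, CellType.OSCC, "t")
            )
            np.testing.assert_array_equal(res.distances, brute_force_nn(sxy, txy))

    @given(
        st.lists(
            st.tuples(st.floats(0, 1e4, allow_nan=False), st.floats(0, 1e4, allow_nan=False)),
            min_size=1,
            max_size=25,
        ),
        st.lists(
            st.tuples(st.floats(0, 1e4, allow_nan=False), st.floats(0, 1e4, allow_nan=False)),
            min_size=1,
            max_size=15,
        ),
    )
    def test_brute_force_equivalence_property(self, s, t):
        res = cp.nearest_neighbor_distances(
            table_from_xy(s), table_from_xy(t, CellType.OSCC, "t")
        )
        np.testing.assert_array_equal(res.distances, brute_force_nn(s, t))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        sxy = rng.uniform(0, 500, (100, 2))
        txy = rng.uniform(0, 500, (30, 2))
        theta, shift = 0.7, np.array([123.0, -45.0])
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        d0 = cp.nearest_neighbor_distances(
            table_from_xy(sxy), table_from_xy(txy, CellType.OSCC, "t")
        ).distances
        d1 = cp.nearest_neighbor_distances(
            table_from_xy(sxy @ rot.T + shift),
            table_from_xy(txy @ rot.T + shift, CellType.OSCC, "t"),
        ).distances
        np.testing.assert_allclose(d1, d0, atol=1e-9)


class TestRadialHistogram:
    def result(self, distances):
        return cp.ProximityResult(
            source_type="CAF", target_type="OSCC", distances=np.asarray(distances, float),
            direction="CAF->nearest OSCC",
        )

    def test_hand_enumerated_counts(self):
        prof = cp.radial_histogram(self.result([5, 15, 95, 105]))
        assert prof.counts.tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 0, 1]
        assert prof.n_within_outer == 3

    def test_boundary_distance_falls_in_upper_bin(self):
        prof = cp.radial_histogram(self.result([10.0]))
        assert prof.counts.tolist() == [0, 1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_counts_sum_to_n_within_outer(self):
        rng = np.random.default_rng(3)
        prof = cp.radial_histogram(self.result(rng.uniform(0, 200, 500)))
        assert prof.counts.sum() == prof.n_within_outer

    def test_non_divisible_binning_rejected(self):
        with pytest.raises(cp.ConfigError):
            cp.radial_histogram(self.result([5.0]), bin_width=30, outer=100)

    def test_clustered_pattern_profile_shape(self):
        """Monte-Carlo over 20 seeds: per-area density peaks in the first
        bin and mean counts fall strictly beyond the modal bin, the
        gradual-decline signature of CAFs clustered around tumor cells."""
        counts = np.zeros(10)
        dens = np.zeros(10)
        for seed in range(20):
            geom = cp.make_interface(2000, 150, 20, seed)
            cfg = SimulationConfig(clustered_fraction=1.0, rng_seed=seed)
            refs = cp.simulate_reference_cells(geom, cfg)
            cells = cp.simulate_cafs(geom, refs, cfg)
            res = cp.nearest_neighbor_distances(
                cells.select(CellType.CAF), refs.select(CellType.OSCC)
            )
            prof = cp.radial_histogram(res, density=True, tissue=geom)
            counts += prof.counts
            dens += prof.density
        assert np.argmax(dens) == 0  # per-area density highest within 10 um
        assert (np.diff(dens) < 0).all()  # gradual decline with distance
        mode = int(np.argmax(counts))
        tail = counts[mode:]
        # strictly decreasing where the Monte-Carlo estimate is stable
        stable = tail >= 50
        assert (np.diff(tail)[stable[:-1]] < 0).all()


class TestFractionWithin:
    def result(self, distances):
        return cp.ProximityResult(
            source_type="CAF", target_type="OSCC",
            distances=np.asarray(distances, float), direction="CAF->nearest OSCC",
        )

    def test_hand_counted_fraction(self):
        s = cp.fraction_within(self.result([10, 20, 60, 110]))
        assert s.fraction == pytest.approx(2 / 3)
        assert (s.n_within_inner, s.n_within_outer) == (2, 3)

    def test_all_within_inner_gives_one(self):
        assert cp.fraction_within(self.result([1, 2, 3])).fraction == 1.0

    def test_undefined_when_no_source_within_outer(self):
        s = cp.fraction_within(self.result([150, 200]))
        assert not s.defined and math.isnan(s.fraction)

    def test_inner_not_below_outer_rejected(self):
        with pytest.raises(cp.ConfigError):
            cp.fraction_within(self.result([10]), inner=100, outer=100)

    def test_cumulative_fraction_monotone_in_inner_radius(self):
        rng = np.random.default_rng(5)
        res = self.result(rng.rayleigh(30, 2000))
        fracs = [
            cp.fraction_within(res, inner=r, outer=100).fraction
            for r in (10, 20, 30, 40, 50, 60, 70, 80, 90, 99.999)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] <= 1.0

    def test_pure_offspring_fraction_matches_81_percent(self, sparse_setup):
        geom, refs = sparse_setup
        s = offspring_fraction(geom, refs, sigma=27.5, n=5000, seed=12)
        assert s.fraction == pytest.approx(0.81, abs=0.03)

    @pytest.mark.parametrize("sigma", [23.8, 27.5, 30.6, 36.7])
    def test_parameter_recovery_against_closed_form(self, sparse_setup, sigma):
        """Pipeline fraction estimate matches the truncated Rayleigh CDF."""
        geom, refs = sparse_setup
        s = offspring_fraction(geom, refs, sigma=sigma, n=5000, seed=31)
        assert s.fraction == pytest.approx(
            cp.truncated_rayleigh_fraction(sigma), abs=0.03
        )

    def test_csr_baseline_tends_to_area_ratio(self):
        """Uniform CAFs around one central reference: fraction -> 0.25."""
        geom = cp.make_flat_geometry(1000, 1000, tumor_zone_height=300)
        band = geom.stromal_band
        cx = (band.bounds[0] + band.bounds[2]) / 2
        cy = (band.bounds[1] + band.bounds[3]) / 2
        ref = CellTable.from_arrays([cx], [cy], CellType.OSCC, "ref")
        cfg = SimulationConfig(
            clustered_fraction=0, spindle_fraction=1.0, n_cafs=40000, rng_seed=8
        )
        cafs = cp.simulate_cafs(geom, CellTable.empty(), cfg)
        res = cp.nearest_neighbor_distances(cafs, ref)
        s = cp.fraction_within(res)
        assert s.fraction == pytest.approx(0.25, abs=0.03)


class TestStratifiedProximity:
    def test_identical_strata_give_identical_summaries(self, default_cells):
        strat = cp.stratified_proximity(
            {"a": default_cells, "b": default_cells}
        )
        a, b = strat.per_stratum["a"], strat.per_stratum["b"]
        for target in a:
            assert a[target].fraction == b[target].fraction
            assert a[target].n_within_outer == b[target].n_within_outer

    def test_thin_and_thick_strata_reproduce_printed_fractions(self):
        """Thin stroma (sigma 23.8) ~89%, thick stroma (sigma 36.7) ~62%."""
        tables = {}
        for label, thickness, sigma in (("thin", 100.0, 23.8), ("thick", 200.0, 36.7)):
            geom = cp.make_flat_geometry(2600, thickness, tumor_zone_height=2400)
            refs = cp.sparse_reference_table(geom, 20, seed=1)
            cfg = SimulationConfig(
                band_thickness=thickness,
                clustered_fraction=1.0,
                displacement_scale_sigma=sigma,
                spindle_fraction=1.0,
                n_cafs=5000,
                rng_seed=17,
            )
            cafs = cp.simulate_cafs(geom, refs, cfg)
            tables[label] = cp.concat_tables([refs, cafs])
        strat = cp.stratified_proximity(tables)
        thin = strat.per_stratum["thin"]["OSCC"].fraction
        thick = strat.per_stratum["thick"]["OSCC"].fraction
        assert thin == pytest.approx(0.89, abs=0.03)
        assert thick == pytest.approx(0.62, abs=0.03)
        assert thin > thick

    def test_absent_reference_type_flagged_undefined(self, default_cells):
        caf_only = default_cells.select(CellType.CAF)
        strat = cp.stratified_proximity({"only": caf_only})
        assert not strat.per_stratum["only"]["OSCC"].defined

    def test_empty_strata_rejected(self):
        with pytest.raises(cp.ConfigError):
            cp.stratified_proximity({})
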