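import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hazpop.hazards import (
    CycloneTrack,
    FloodEvent,
    FrequencyGrid,
    PrecipCube,
    cyclone_frequency,
    decile_weights,
    detect_drought_events,
    drought_frequency,
    flood_frequency,
    monthly_medians,
    to_deciles,
    valid_cell_mask,
)
from hazpop.raster import EARTH_RADIUS_KM, CellAreaGrid, GridSpec, Raster


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def haversine_oracle(lon1, lat1, lon2, lat2):
    """Textbook spherical law of cosines distance (km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    cosang = (math.sin(p1) * math.sin(p2)
              + math.cos(p1) * math.cos(p2) * math.cos(dl))
    return EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, cosang)))


def cyclone_oracle(tracks, spec, radii):
    """Brute force: every cell center against every track point."""
    counts = np.zeros(spec.shape, dtype=int)
    for track in tracks:
        radius = radii[track.category]
        for r in range(spec.n_rows):
            for c in range(spec.n_cols):
                lon, lat = spec.cell_center(r, c)
                if any(haversine_oracle(lon, lat, plon, plat) <= radius
                       for plon, plat in track.points):
                    counts[r, c] += 1
    return counts


def drought_oracle(series, min_median_mm=1.0, start_month=1):
    """Exhaustive scan over all maximal runs of qualifying months."""
    series = list(series)
    meds = monthly_medians(np.array(series), start_month)
    qual = []
    for i, p in enumerate(series):
        m = (i + start_month - 1) % 12
        qual.append(meds[m] >= min_median_mm and p <= 0.5 * meds[m])
    events, i = 0, 0
    while i < len(qual):
        if qual[i]:
            j = i
            while j < len(qual) and qual[j]:
                j += 1
            if j - i >= 3:
                events += 1
            i = j
        else:
            i += 1
    return events


def decile_oracle_distinct(counts_pos):
    """Positional decile assignment, valid when all counts are distinct."""
    order = np.argsort(counts_pos)
    n = counts_pos.size
    dec = np.empty(n, dtype=int)
    for pos, idx in enumerate(order):
        dec[idx] = pos * 10 // n + 1
    return dec


# ---------------------------------------------------------------------------
# cyclone
# ---------------------------------------------------------------------------

EQ_SPEC = GridSpec(n_rows=8, n_cols=12, cell_size=1.0,
                   origin_lon=0.0, origin_lat=4.0)
RADII = {1: 50.0, 2: 100.0, 3: 150.0, 4: 200.0, 5: 250.0, 6: 300.0}


class TestCycloneFrequency:
    def test_single_track_matches_brute_force(self):
        track = CycloneTrack("a", ((2.5, 0.5), (4.5, 0.5), (6.5, 0.5)), 3)
        got = cyclone_frequency([track], EQ_SPEC, RADII)
        np.testing.assert_array_equal(
            got.counts, cyclone_oracle([track], EQ_SPEC, RADII))
        assert got.counts.max() == 1
        assert got.counts.sum() > 0

    def test_two_identical_events_double(self):
        track = CycloneTrack("a", ((3.5, 1.5),), 2)
        twin = CycloneTrack("b", ((3.5, 1.5),), 2)
        one = cyclone_frequency([track], EQ_SPEC, RADII)
        two = cyclone_frequency([track, twin], EQ_SPEC, RADII)
        np.testing.assert_array_equal(two.counts, 2 * one.counts)

    def test_revisiting_track_tallies_once(self):
        # one event loops over the same cell five times -> count stays 1
        pt = (5.5, 0.5)
        track = CycloneTrack("loop", tuple([pt, (6.5, 0.5)] * 5), 1)
        got = cyclone_frequency([track], EQ_SPEC, RADII)
        assert got.counts.max() == 1

    def test_empty_track_list_gives_zero_grid(self):
        got = cyclone_frequency([], EQ_SPEC, RADII)
        assert (got.counts == 0).all()

    def test_unknown_category_errors(self):
        track = CycloneTrack("a", ((3.5, 1.5),), 6)
        with pytest.raises(ValueError, match="category"):
            cyclone_frequency([track], EQ_SPEC, {1: 50.0})

    def test_non_monotone_radii_rejected(self):
        track = CycloneTrack("a", ((3.5, 1.5),), 1)
        bad = {**RADII, 2: 10.0}
        with pytest.raises(ValueError, match="non-decreasing"):
            cyclone_frequency([track], EQ_SPEC, bad)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tracks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tracks = []
        for i in range(4):
            pts = tuple(
                (float(rng.uniform(0, 12)), float(rng.uniform(-4, 4)))
                for _ in range(rng.integers(1, 5))
            )
            tracks.append(CycloneTrack(f"t{i}", pts, int(rng.integers(1, 7))))
        got = cyclone_frequency(tracks, EQ_SPEC, RADII)
        np.testing.assert_array_equal(
            got.counts, cyclone_oracle(tracks, EQ_SPEC, RADII))

    def test_event_additivity(self, rng):
        a = [CycloneTrack("a", ((2.5, 0.5), (3.5, 0.5)), 4)]
        b = [CycloneTrack("b", ((8.5, -2.5),), 2)]
        fa = cyclone_frequency(a, EQ_SPEC, RADII)
        fb = cyclone_frequency(b, EQ_SPEC, RADII)
        fab = cyclone_frequency(a + b, EQ_SPEC, RADII)
        np.testing.assert_array_equal(fab.counts, fa.counts + fb.counts)


class TestFloodFrequency:
    def test_one_degree_box_hits_one_cell(self):
        # oracle: center-in-box containment
        ev = FloodEvent("f", 3, 1, 4, 2)
        got = flood_frequency([ev], EQ_SPEC)
        assert got.counts.sum() == 1
        assert got.counts[EQ_SPEC.index_of(3.5, 1.5)] == 1

    def test_three_events_accumulate(self):
        ev = FloodEvent("f", 3, 1, 4, 2)
        got = flood_frequency([ev] * 3, EQ_SPEC)
        assert got.counts.max() == 3
        assert got.counts.sum() == 3

    def test_event_outside_grid_is_ignored(self):
        ev = FloodEvent("f", 100, 50, 103, 53)
        got = flood_frequency([ev], EQ_SPEC)
        assert (got.counts == 0).all()

    def test_corners_must_be_integral(self):
        with pytest.raises(ValueError, match="whole degrees"):
            FloodEvent("f", 0.5, 0, 2, 2)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            FloodEvent("f", 3, 1, 3, 2)

    def test_center_in_box_oracle_random(self, rng):
        events = [
            FloodEvent(f"f{i}",
                       int(rng.integers(0, 10)), int(rng.integers(-4, 2)),
                       int(rng.integers(10, 13)), int(rng.integers(2, 5)))
            for i in range(10)
        ]
        got = flood_frequency(events, EQ_SPEC)
        expected = np.zeros(EQ_SPEC.shape, dtype=int)
        for ev in events:
            for r in range(EQ_SPEC.n_rows):
                for c in range(EQ_SPEC.n_cols):
                    lon, lat = EQ_SPEC.cell_center(r, c)
                    if ev.lon_min <= lon <= ev.lon_max and \
                            ev.lat_min <= lat <= ev.lat_max:
                        expected[r, c] += 1
        np.testing.assert_array_equal(got.counts, expected)


# ---------------------------------------------------------------------------
# drought
# ---------------------------------------------------------------------------

class TestDetectDroughtEvents:
    def test_constant_series_has_no_events(self):
        assert detect_drought_events(np.full(48, 80.0)) == 0

    def test_inserted_four_month_deficit_found(self):
        # oracle: exhaustive scan of qualifying runs
        rng = np.random.default_rng(7)
        series = 100.0 * rng.uniform(0.9, 1.1, 48)
        meds = monthly_medians(series)
        for i in range(20, 24):
            series[i] = 0.4 * meds[i % 12]
        assert detect_drought_events(series) == 1
        assert drought_oracle(series) == 1

    def test_two_month_deficit_is_no_event(self):
        rng = np.random.default_rng(7)
        series = 100.0 * rng.uniform(0.9, 1.1, 48)
        meds = monthly_medians(series)
        for i in range(20, 22):
            series[i] = 0.4 * meds[i % 12]
        assert detect_drought_events(series) == 0

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            detect_drought_events([1.0, 2.0])

    def test_boundary_exactly_half_median_qualifies(self):
        series = np.full(48, 100.0)
        series[10:13] = 50.0  # exactly 50% of the unperturbed median
        meds = np.full(12, 100.0)
        assert detect_drought_events(series, medians=meds) == 1

    def test_zero_median_below_floor_never_qualifies(self):
        # hyper-arid cell: all-zero rainfall is not perpetual drought
        assert detect_drought_events(np.zeros(48)) == 0

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=200), min_size=36,
                    max_size=72),
           st.integers(min_value=1, max_value=12))
    def test_matches_exhaustive_oracle(self, series, start_month):
        got = detect_drought_events(series, start_month=start_month)
        assert got == drought_oracle(series, start_month=start_month)

    def test_thousand_random_series_match_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(36, 61))
            series = rng.gamma(2.0, 30.0, n)
            series[rng.random(n) < 0.25] *= 0.1  # sprinkle deficits
            sm = int(rng.integers(1, 13))
            assert detect_drought_events(series, start_month=sm) == \
                drought_oracle(series, start_month=sm)


class TestDroughtFrequency:
    def _cube(self, values, spec=None):
        spec = spec or GridSpec(2, 2, 2.5, 0.0, 2.5)
        return PrecipCube(spec, values, start_month=1)

    def test_constant_cube_all_zero(self):
        cube = self._cube(np.full((48, 2, 2), 90.0))
        assert (drought_frequency(cube).counts == 0).all()

    def test_single_cell_deficit_isolated(self):
        vals = np.full((48, 2, 2), 90.0)
        vals[20:24, 1, 0] = 36.0
        counts = drought_frequency(self._cube(vals)).counts
        assert counts[1, 0] == 1
        assert counts.sum() == 1

    def test_arid_cell_reports_no_drought(self):
        vals = np.full((48, 2, 2), 90.0)
        vals[:, 0, 1] = 0.0
        counts = drought_frequency(self._cube(vals)).counts
        assert counts[0, 1] == 0


# ---------------------------------------------------------------------------
# mask, deciles, weights
# ---------------------------------------------------------------------------

def uniform_area_world(density_values, agri_values):
    """1-cell-per-value strip with unit-ish areas for mask boundary tests."""
    n = len(density_values)
    spec = GridSpec(1, n, 1.0, 0.0, 0.5)
    from hazpop.raster import cell_areas
    areas = cell_areas(spec)
    pop = Raster(spec, np.array([[d * areas.areas[0, i]
                                  for i, d in enumerate(density_values)]]))
    agri = Raster(spec, np.array([agri_values], dtype=float))
    return pop, areas, agri


class TestValidCellMask:
    def test_density_rule_boundaries(self):
        pop, areas, agri = uniform_area_world(
            [4.0, 4.0, 5.0, 6.0], [0, 1, 0, 0])
        mask = valid_cell_mask(pop, areas, agri)
        assert mask.tolist() == [[False, True, True, True]]

    def test_spec_mismatch_errors(self, spec_3x3, spec_20x20):
        pop = Raster(spec_3x3, np.ones((3, 3)))
        from hazpop.raster import cell_areas
        areas = cell_areas(spec_20x20)
        agri = Raster(spec_3x3, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            valid_cell_mask(pop, areas, agri)


class TestToDeciles:
    def _grid(self, counts):
        counts = np.atleast_2d(np.asarray(counts))
        spec = GridSpec(counts.shape[0], counts.shape[1], 1.0, 0.0,
                        counts.shape[0] / 2)
        return FrequencyGrid(spec, counts)

    def test_hundred_distinct_counts_balanced(self):
        counts = np.arange(1, 101).reshape(10, 10)
        freq = self._grid(counts)
        dec = to_deciles(freq, np.ones_like(counts, dtype=bool)).deciles
        np.testing.assert_array_equal(
            np.sort(dec.ravel()), np.repeat(np.arange(1, 11), 10))
        # oracle: positional assignment over distinct sorted counts
        oracle = decile_oracle_distinct(counts.ravel()).reshape(10, 10)
        np.testing.assert_array_equal(dec, oracle)

    def test_identical_positive_counts_all_top_decile(self):
        freq = self._grid(np.full((3, 4), 7))
        dec = to_deciles(freq, np.ones((3, 4), dtype=bool)).deciles
        assert (dec == 10).all()

    def test_zero_count_cells_get_zero(self):
        freq = self._grid(np.array([[0, 1, 2, 3]]))
        dec = to_deciles(freq, np.ones((1, 4), dtype=bool)).deciles
        assert dec[0, 0] == 0
        assert (dec[0, 1:] > 0).all()

    def test_invalid_cells_excluded(self):
        freq = self._grid(np.array([[5, 5, 5, 5]]))
        mask = np.array([[True, True, False, False]])
        dec = to_deciles(freq, mask).deciles
        assert dec.tolist() == [[10, 10, 0, 0]]

    def test_no_positive_cells_all_zero(self):
        freq = self._grid(np.zeros((2, 2), dtype=int))
        dec = to_deciles(freq, np.ones((2, 2), dtype=bool)).deciles
        assert (dec == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_order_isomorphism_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 40, (12, 12))
        mask = rng.random((12, 12)) < 0.8
        freq = self._grid(counts)
        dec = to_deciles(freq, mask).deciles
        pos = mask & (counts > 0)
        cvals, dvals = counts[pos], dec[pos]
        for i in range(len(cvals)):
            same = cvals == cvals[i]
            assert (dvals[same] == dvals[i]).all()
            assert (dvals[cvals < cvals[i]] <= dvals[i]).all()
        assert set(np.unique(dec)) <= set(range(11))

    @pytest.mark.parametrize("n", [10, 23, 57, 100, 101, 250])
    def test_decile_balance_distinct_counts(self, n, rng):
        counts = rng.permutation(np.arange(1, n + 1))
        pad = -(-n // 10) * 10  # next multiple of 10 for a rectangular grid
        arr = np.zeros(pad, dtype=int)
        arr[:n] = counts
        freq = self._grid(arr.reshape(-1, 10))
        mask = np.ones(freq.counts.shape, dtype=bool)
        dec = to_deciles(freq, mask).deciles
        sizes = np.bincount(dec[freq.counts > 0], minlength=11)[1:]
        assert sizes.sum() == n
        assert sizes.min() >= n // 10 - 1
        assert sizes.max() <= -(-n // 10) + 1


class TestDecileWeights:
    def test_linear_mapping(self):
        spec = GridSpec(1, 11, 1.0, 0.0, 0.5)
        from hazpop.hazards import DecileGrid
        dec = DecileGrid(spec, np.arange(11).reshape(1, 11))
        w = decile_weights(dec).weights
        np.testing.assert_allclose(w, np.arange(11).reshape(1, 11) / 10.0)
        assert w[0, 10] == 1.0
        assert w[0, 0] == 0.0
        assert set(np.round(w * 10).ravel()) <= set(range(11))
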