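import numpy as np
import pytest

from crossfeed.lattice_domain import CONSUMER, EMPTY, PRODUCER, Occupancy, build_lattice
from crossfeed.quantify import (
    ColonyRaster,
    InvalidInputError,
    compute_metrics,
    consumer_producer_ratio,
    count_jackpot_events,
    edge_profile,
    intermixing_index,
    rasterize_state,
)
from crossfeed.synthetic_data import gen_wedge_colony


def disk_raster(radius_px=100, label=PRODUCER, pixel_size=1.0):
    n = 2 * radius_px + 1
    rows, cols = np.indices((n, n))
    r = np.hypot(rows - radius_px, cols - radius_px)
    labels = np.where(r <= radius_px, label, EMPTY).astype(np.uint8)
    return ColonyRaster(labels, pixel_size, center=(radius_px, radius_px))


class TestColonyRaster:
    def test_invalid_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            ColonyRaster(np.full((4, 4), 7, dtype=np.uint8), 1.0)

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(InvalidInputError):
            ColonyRaster(np.zeros((4, 4), dtype=np.uint8), 0.0)

    def test_center_defaults_to_centroid(self):
        labels = np.zeros((11, 11), dtype=np.uint8)
        labels[2:5, 6:9] = PRODUCER
        r = ColonyRaster(labels, 1.0)
        assert r.center == (3.0, 7.0)

    def test_from_channels_threshold(self):
        p = np.array([[10.0, 0.0], [1.0, 5.0]])
        c = np.array([[0.0, 20.0], [1.0, 2.0]])
        r = ColonyRaster.from_channels(p, c, threshold=5.0, pixel_size_um=1.0)
        assert r.labels[0, 0] == PRODUCER
        assert r.labels[0, 1] == CONSUMER
        assert r.labels[1, 0] == EMPTY
        assert r.labels[1, 1] == PRODUCER

    @pytest.mark.parametrize("suffix", [".tiff", ".png"])
    def test_file_round_trip(self, tmp_path, suffix):
        raster, _ = gen_wedge_colony(radius_px=40, n_jackpots=2, seed=1)
        path = tmp_path / f"colony{suffix}"
        raster.write(path)
        back = ColonyRaster.read(path, pixel_size_um=raster.pixel_size_um)
        np.testing.assert_array_equal(back.labels, raster.labels)


@pytest.fixture(scope="module")
def lat():
    return build_lattice(800.0, 20.0)


class TestRasterizeState:

    def test_empty_occupancy_all_empty(self, lat):
        ras = rasterize_state(Occupancy.empty(lat), lat, 10.0)
        assert (ras.labels == EMPTY).all()

    def test_single_node_compact_blob(self, lat):
        occ = Occupancy.empty(lat)
        c = int(np.argmin(lat.radii()))
        occ.strain[c] = CONSUMER
        ras = rasterize_state(occ, lat, 5.0)
        labs = set(np.unique(ras.labels))
        assert labs == {EMPTY, CONSUMER}
        # blob is compact: all consumer pixels within one spacing of centre
        rows, cols = np.nonzero(ras.labels == CONSUMER)
        d = np.hypot(rows - ras.center[0], cols - ras.center[1]) * 5.0
        assert d.max() <= lat.spacing + 5.0

    def test_disk_area_within_five_percent(self, lat):
        occ = Occupancy.empty(lat)
        radius = 300.0
        occ.strain[lat.radii() <= radius] = PRODUCER
        ras = rasterize_state(occ, lat, 4.0)
        area_px = (ras.labels == PRODUCER).sum() * 4.0**2
        assert area_px == pytest.approx(np.pi * radius**2, rel=0.05)


class TestEdgeProfile:
    def test_perfect_disk(self):
        ras = disk_raster(80)
        prof = edge_profile(ras, n_bins=36)
        assert np.nanmax(np.abs(prof - 80.0)) <= 1.5  # ± ~1 pixel

    def test_extended_wedge_only_in_its_bins(self):
        n, c = 171, 85.0
        rows, cols = np.indices((n, n))
        r = np.hypot(rows - c, cols - c)
        theta = np.arctan2(rows - c, cols - c)
        labels = np.where(r <= 60, PRODUCER, EMPTY).astype(np.uint8)
        wedge = (np.abs(theta) < 0.2) & (r <= 75)
        labels[wedge] = PRODUCER
        big = ColonyRaster(labels, 1.0, center=(c, c))
        prof = edge_profile(big, n_bins=72)
        theta_bins = (np.arange(72) + 0.5) / 72 * 2 * np.pi - np.pi
        in_wedge = np.abs(theta_bins) < 0.15
        far = np.abs(theta_bins) > 0.3
        assert (prof[in_wedge] > 70).all()
        assert (prof[far] < 62).all()

    def test_matches_brute_force_scan(self):
        raster, _ = gen_wedge_colony(radius_px=50, n_jackpots=2, seed=3)
        n_bins = 40
        prof = edge_profile(raster, n_bins=n_bins)
        expect = np.full(n_bins, -np.inf)
        h, w = raster.labels.shape
        for i in range(h):
            for j in range(w):
                if raster.labels[i, j] == EMPTY:
                    continue
                dy = (i - raster.center[0]) * raster.pixel_size_um
                dx = (j - raster.center[1]) * raster.pixel_size_um
                r = np.hypot(dx, dy)
                b = int((np.arctan2(dy, dx) + np.pi) / (2 * np.pi) * n_bins)
                b = min(b, n_bins - 1)
                expect[b] = max(expect[b], r)
        expect[np.isneginf(expect)] = np.nan
        np.testing.assert_allclose(prof, expect, rtol=1e-12)

    def test_empty_raster_rejected(self):
        with pytest.raises(InvalidInputError):
            edge_profile(ColonyRaster(np.zeros((5, 5), dtype=np.uint8), 1.0), 16)

    def test_min_bins(self):
        with pytest.raises(InvalidInputError):
            edge_profile(disk_raster(20), n_bins=4)


class TestConsumerProducerRatio:
    def test_all_producer_ring_is_zero(self):
        assert consumer_producer_ratio(disk_raster(80), ring_width_px=20) == 0.0

    def test_half_half_ring_is_one(self):
        n = 161
        rows, cols = np.indices((n, n))
        r = np.hypot(rows - 80, cols - 80)
        labels = np.where(r <= 80, np.where(cols >= 80, CONSUMER, PRODUCER), EMPTY)
        ras = ColonyRaster(labels.astype(np.uint8), 1.0, center=(80.0, 80.0))
        assert consumer_producer_ratio(ras, ring_width_px=20) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_wedge_geometry_oracle(self, seed):
        raster, truth = gen_wedge_colony(
            radius_px=250, n_jackpots=4, seed=seed, wedge_inner_frac=0.3
        )
        ratio = consumer_producer_ratio(raster, ring_width_px=40)
        assert ratio == pytest.approx(truth.expected_edge_ratio, rel=0.03)

    def test_all_consumer_ring_is_inf(self):
        ras = disk_raster(60, label=CONSUMER)
        assert consumer_producer_ratio(ras, ring_width_px=10) == np.inf


class TestIntermixingIndex:
    def test_single_strain_zero(self):
        assert intermixing_index(disk_raster(80), offset_px=20) == 0.0

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_alternating_wedges(self, k):
        n = 201
        rows, cols = np.indices((n, n))
        r = np.hypot(rows - 100, cols - 100)
        theta = np.arctan2(rows - 100.0, cols - 100.0)
        sector = np.floor((theta + np.pi) / (2 * np.pi) * k).astype(int) % 2
        labels = np.where(r <= 100, np.where(sector == 0, PRODUCER, CONSUMER), EMPTY)
        ras = ColonyRaster(labels.astype(np.uint8), 1.0, center=(100.0, 100.0))
        idx = intermixing_index(ras, offset_px=20)
        sampling_radius = 100.0 - 20.0  # edge minus offset, in µm at 1 µm/px
        expected = k / (2 * np.pi * sampling_radius)
        assert idx == pytest.approx(expected, rel=0.15)

    def test_doubling_wedges_doubles_index(self):
        vals = {}
        for k in (4, 8):
            n = 201
            rows, cols = np.indices((n, n))
            r = np.hypot(rows - 100, cols - 100)
            theta = np.arctan2(rows - 100.0, cols - 100.0)
            sector = np.floor((theta + np.pi) / (2 * np.pi) * k).astype(int) % 2
            labels = np.where(r <= 100, np.where(sector == 0, PRODUCER, CONSUMER), EMPTY)
            ras = ColonyRaster(labels.astype(np.uint8), 1.0, center=(100.0, 100.0))
            vals[k] = intermixing_index(ras, offset_px=20)
        assert vals[8] == pytest.approx(2 * vals[4], rel=0.05)

    def test_per_pixel_normalization_option(self):
        raster, _ = gen_wedge_colony(radius_px=100, n_jackpots=2, seed=0, pixel_size_um=3.0)
        per_um = intermixing_index(raster, offset_px=20, per_um=True)
        per_px = intermixing_index(raster, offset_px=20, per_um=False)
        assert per_px == pytest.approx(per_um * 3.0, rel=1e-9)

    def test_empty_circle_rejected(self):
        with pytest.raises(InvalidInputError):
            intermixing_index(ColonyRaster(np.zeros((5, 5), dtype=np.uint8), 1.0))


def flood_fill_oracle(raster, edge_band_px, min_size_px, n_bins=360):
    """Independent flood fill + per-bin edge computation."""
    from collections import deque

    labels = raster.labels
    h, w = labels.shape
    prof = edge_profile(raster, n_bins=n_bins)
    seen = np.zeros_like(labels, dtype=bool)
    count = 0
    for si in range(h):
        for sj in range(w):
            if labels[si, sj] != CONSUMER or seen[si, sj]:
                continue
            comp = []
            dq = deque([(si, sj)])
            seen[si, sj] = True
            while dq:
                i, j = dq.popleft()
                comp.append((i, j))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if (
                            0 <= ii < h
                            and 0 <= jj < w
                            and not seen[ii, jj]
                            and labels[ii, jj] == CONSUMER
                        ):
                            seen[ii, jj] = True
                            dq.append((ii, jj))
            if len(comp) <= min_size_px:
                continue
            touches = False
            for i, j in comp:
                dy = (i - raster.center[0]) * raster.pixel_size_um
                dx = (j - raster.center[1]) * raster.pixel_size_um
                r = np.hypot(dx, dy)
                b = min(int((np.arctan2(dy, dx) + np.pi) / (2 * np.pi) * n_bins), n_bins - 1)
                if r >= prof[b] - edge_band_px * raster.pixel_size_um:
                    touches = True
                    break
            if touches:
                count += 1
    return count


class TestJackpotCount:
    def test_producer_only_zero(self):
        assert count_jackpot_events(disk_raster(60)) == 0

    def test_wedges_counted_blobs_excluded(self):
        raster, truth = gen_wedge_colony(
            radius_px=120, n_jackpots=3, interior_blobs=2, seed=4
        )
        assert count_jackpot_events(raster, edge_band_px=5, min_size_px=10) == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raster, _ = gen_wedge_colony(
            radius_px=60,
            n_jackpots=int(rng.integers(0, 5)),
            interior_blobs=int(rng.integers(0, 3)),
            label_noise_rate=float(rng.choice([0.0, 0.01])),
            seed=seed,
        )
        got = count_jackpot_events(raster, edge_band_px=4, min_size_px=8)
        assert got == flood_fill_oracle(raster, 4, 8)


class TestInvariances:
    @pytest.mark.parametrize("transform", ["rot90", "fliplr"])
    def test_metric_invariance_under_symmetry(self, transform):
        raster, _ = gen_wedge_colony(radius_px=120, n_jackpots=3, seed=9)
        t = np.rot90(raster.labels) if transform == "rot90" else np.fliplr(raster.labels)
        other = ColonyRaster(t.copy(), raster.pixel_size_um)
        m1 = compute_metrics(raster, ring_width_px=30)
        m2 = compute_metrics(other, ring_width_px=30)
        assert m1.jackpot_count == m2.jackpot_count
        assert m1.consumer_to_producer_ratio == pytest.approx(
            m2.consumer_to_producer_ratio, rel=0.02
        )
        assert m1.intermixing_index == pytest.approx(m2.intermixing_index, rel=0.10)

    def test_occupancy_vs_raster_agreement(self):
        """Metrics from lattice state and its rasterisation agree to ~5 %."""
        lat = build_lattice(1600.0, 20.0)
        occ = Occupancy.empty(lat)
        radii = lat.radii()
        theta = np.arctan2(lat.positions[:, 1], lat.positions[:, 0])
        disk = radii <= 600.0
        occ.strain[disk] = PRODUCER
        wedge = disk & (np.abs(theta) < 0.3) & (radii > 150.0)
        occ.strain[wedge] = CONSUMER
        occ.biomass[disk] = 1e-14
        fine = rasterize_state(occ, lat, 4.0)
        coarse = rasterize_state(occ, lat, 8.0)
        r_fine = consumer_producer_ratio(fine, ring_width_px=25)
        r_coarse = consumer_producer_ratio(coarse, ring_width_px=13)
        assert r_fine == pytest.approx(r_coarse, rel=0.05)
        assert count_jackpot_events(fine, 5, 10) == count_jackpot_events(coarse, 3, 5) == 1
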