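"""Segmentation, spot detection and donut-ratio scoring against planted
ground truth and constructed pixel fixtures."""

import numpy as np
import pandas as pd
import pytest

from sgfound.imaging import (
    GranuleRecord,
    ImageSummary,
    SegmentationParams,
    classify_transfection,
    detect_granules,
    match_cells_to_truth,
    match_detections_to_truth,
    quantify_image,
    score_v5_enrichment,
    segment_cells,
)
from sgfound.synthetic import SceneConfig, simulate_sg_scene
from sgfound.synthetic.scenes import ImageScene

PARAMS = SegmentationParams()


class TestSegmentCells:
    def test_truth_round_trip(self, noiseless_scene):
        cells, labels = segment_cells(noiseless_scene, PARAMS)
        assert len(cells) == noiseless_scene.truth.n_cells
        mapping = match_cells_to_truth(labels, noiseless_scene.truth)
        # one-to-one: every segmented cell maps to a distinct truth cell
        assert sorted(mapping.values()) == list(range(1, 21))

    def test_blank_image_yields_no_cells(self):
        blank = ImageScene(channels={ch: np.full((64, 64), 5.0)
                                     for ch in ("nuclei", "v5", "tial1")})
        cells, _ = segment_cells(blank, PARAMS)
        assert cells == []

    def test_small_nucleus_excluded(self):
        nuc = np.full((96, 96), 10.0)
        nuc[40:43, 40:43] = 200.0            # 9 px, below the minimum area
        nuc[10:22, 60:72] = 200.0            # 144 px nucleus, kept
        scene = ImageScene(channels={"nuclei": nuc,
                                     "v5": np.full((96, 96), 10.0),
                                     "tial1": np.full((96, 96), 10.0)})
        cells, _ = segment_cells(scene, SegmentationParams(cytoplasm_radius_px=5.0))
        assert len(cells) == 1
        assert cells[0].nucleus_area >= 40

    def test_missing_channel_fails(self):
        scene = ImageScene(channels={"v5": np.zeros((8, 8))})
        with pytest.raises(KeyError, match="nuclei"):
            segment_cells(scene, PARAMS)

    def test_cytoplasm_excludes_nucleus(self, noiseless_scene):
        _, labels = segment_cells(noiseless_scene, PARAMS)
        overlap = (labels["nucleus"] > 0) & (labels["cell"] > 0)
        assert np.array_equal(labels["cell"][overlap], labels["nucleus"][overlap])


class TestClassifyTransfection:
    def test_recovers_planted_transfection(self, noisy_scene):
        summary = quantify_image(noisy_scene)
        mapping = match_cells_to_truth(summary.labels, noisy_scene.truth)
        calls = dict(zip(summary.cells.cell_id, summary.cells.is_transfected))
        for cid, tid in mapping.items():
            assert calls[cid] == noisy_scene.truth.transfected[tid - 1]

    def test_no_transfection_all_negative(self):
        scene = simulate_sg_scene(SceneConfig(n_cells=8, transfected_fraction=0.0, seed=11))
        summary = quantify_image(scene)
        assert summary.n_transfected == 0

    def test_full_transfection_with_control_stats(self):
        scene = simulate_sg_scene(SceneConfig(n_cells=8, transfected_fraction=1.0, seed=12))
        cells, labels = segment_cells(scene, PARAMS)
        # reference untransfected distribution from a control scene
        cells, log = classify_transfection(
            cells, scene.channels["v5"], PARAMS, labels=labels,
            control_stats=(100.0, 4.0),
        )
        assert all(c.is_transfected for c in cells)
        assert log["threshold"] > 100.0

    def test_otsu_on_identical_means_fails_with_advice(self):
        params = SegmentationParams(v5_positive_method="otsu_global")
        scene = simulate_sg_scene(SceneConfig(n_cells=5, transfected_fraction=0.0,
                                              noise_sd=0.0, sg_rate=0.0,
                                              sg_rate_untransfected=0.0, seed=13))
        cells, labels = segment_cells(scene, params)
        with pytest.raises(ValueError, match="k_sigma"):
            classify_transfection(cells, scene.channels["v5"], params, labels=labels)


class TestDetectGranules:
    def test_truth_round_trip_noiseless(self, noiseless_scene):
        summary = quantify_image(noiseless_scene)
        truth = noiseless_scene.truth
        matches = match_detections_to_truth(summary.granules, truth)
        assert len(summary.granules) == truth.n_spots
        assert set(matches.truth_spot_id) == set(truth.spots.spot_id)
        # cell assignment agrees with the planted owner
        mapping = match_cells_to_truth(summary.labels, truth)
        owners = dict(zip(truth.spots.spot_id, truth.spots.cell_id))
        for _, row in matches.iterrows():
            assert mapping[row.cell_id] == owners[row.truth_spot_id]

    def test_flat_tial1_no_granules(self):
        scene = simulate_sg_scene(SceneConfig(n_cells=6, sg_rate=0.0,
                                              sg_rate_untransfected=0.0, seed=14))
        summary = quantify_image(scene)
        assert summary.granules == []
        assert summary.cells.n_sg.sum() == 0

    def test_spot_inside_nucleus_not_reported(self):
        scene = simulate_sg_scene(SceneConfig(n_cells=4, sg_rate=0.0,
                                              sg_rate_untransfected=0.0,
                                              noise_sd=0.0, seed=15))
        cells, labels = segment_cells(scene, PARAMS)
        # plant a bright TIAL1 blob at a nucleus centroid
        r, c = (int(round(x)) for x in cells[0].nucleus_centroid)
        tial1 = scene.channels["tial1"].copy()
        yy, xx = np.mgrid[0:tial1.shape[0], 0:tial1.shape[1]]
        tial1 += 200.0 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 2.0 ** 2))
        doped = ImageScene(channels={**scene.channels, "tial1": tial1})
        granules = detect_granules(doped, cells, PARAMS, labels)
        assert granules == []


def _constructed_granule(spot_value, donut_value, radius=4, size=64):
    """One circular granule on a uniform cytoplasm with chosen V5 medians."""
    center = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(yy - center, xx - center)
    spot = dist <= radius
    v5 = np.full((size, size), float(donut_value))
    v5[spot] = spot_value
    labels = {"cell": np.ones((size, size), dtype=np.int32),
              "nucleus": np.zeros((size, size), dtype=np.int32)}
    rr, cc = np.nonzero(spot)
    g = GranuleRecord(granule_id=1, cell_id=1, pixel_count=int(spot.sum()),
                      median_tial1=0.0, pixels=(rr, cc))
    return g, v5, labels, spot


class TestDonutRatio:
    @pytest.mark.parametrize(
        "spot,donut,ratio,enriched",
        [
            (100.0, 100.0, 1.0, False),      # uniform V5: identity case
            (130.0, 100.0, 1.3, True),       # exact constructed medians
            (120.0, 100.0, 1.2, False),      # boundary: strict inequality
        ],
    )
    def test_ratio_and_strict_threshold(self, spot, donut, ratio, enriched):
        g, v5, labels, mask = _constructed_granule(spot, donut)
        g = score_v5_enrichment(g, v5, labels, PARAMS, mask)
        assert g.enrichment_ratio == pytest.approx(ratio, abs=1e-12)
        assert g.is_v5_enriched is enriched

    def test_zero_donut_median_gives_inf_with_warning(self):
        g, v5, labels, mask = _constructed_granule(50.0, 0.0)
        with pytest.warns(UserWarning, match="inf"):
            g = score_v5_enrichment(g, v5, labels, PARAMS, mask)
        assert np.isinf(g.enrichment_ratio)
        assert g.is_v5_enriched is True

    def test_empty_donut_excluded_from_tallies(self):
        g, v5, labels, mask = _constructed_granule(130.0, 100.0)
        labels["cell"][:] = 0  # no owning cytoplasm anywhere around the spot
        g = score_v5_enrichment(g, v5, labels, PARAMS, mask)
        assert g.donut_empty
        assert g.is_v5_enriched is None

    def test_donut_avoids_spots_and_foreign_cytoplasm(self, noiseless_scene):
        summary = quantify_image(noiseless_scene)
        all_spots = np.zeros(noiseless_scene.shape, dtype=bool)
        for g in summary.granules:
            all_spots[g.pixels] = True
        # reconstruct each donut and check the geometric exclusions
        from skimage.morphology import dilation, disk

        for g in summary.granules[:10]:
            spot = np.zeros(noiseless_scene.shape, dtype=bool)
            spot[g.pixels] = True
            donut = dilation(spot, disk(PARAMS.donut_width_px)) & ~spot
            donut &= ~all_spots
            cyto = (summary.labels["cell"] == g.cell_id) & (summary.labels["nucleus"] == 0)
            donut &= cyto
            if donut.any():
                expect = float(np.median(noiseless_scene.channels["v5"][donut]))
                assert g.median_v5_donut == pytest.approx(expect)
            assert not (donut & all_spots).any()


class TestInvariances:
    def test_intensity_scale_invariance(self, noiseless_scene):
        base = quantify_image(noiseless_scene)
        scaled = ImageScene(
            channels={ch: 3.7 * arr for ch, arr in noiseless_scene.channels.items()}
        )
        other = quantify_image(scaled)
        assert len(other.granules) == len(base.granules)
        assert other.n_transfected == base.n_transfected
        flags = sorted((g.cell_id, g.is_v5_enriched) for g in base.granules)
        flags2 = sorted((g.cell_id, g.is_v5_enriched) for g in other.granules)
        assert flags == flags2

    def test_translation_invariance(self, noiseless_scene):
        base = quantify_image(noiseless_scene)
        # shift kept within the border clearance so no cell crosses the
        # edge (border-touching cells are excluded by design)
        shifted = ImageScene(
            channels={ch: np.roll(arr, (3, -3), axis=(0, 1))
                      for ch, arr in noiseless_scene.channels.items()}
        )
        other = quantify_image(shifted)
        assert len(other.granules) == len(base.granules)
        assert sorted(g.pixel_count for g in other.granules) == \
            sorted(g.pixel_count for g in base.granules)


class TestQuantifyImage:
    def test_fraction_arithmetic(self):
        cells = pd.DataFrame(
            dict(cell_id=range(1, 11), is_transfected=[True] * 10,
                 mean_v5=1.0, n_sg=[1, 2, 1, 3] + [0] * 6,
                 n_enriched=0, n_nonenriched=0, n_unscored=0)
        )
        s = ImageSummary(scene_id=0, cells=cells, granules=[])
        assert s.fraction_cells_with_sg() == pytest.approx(0.4)
        assert s.mean_sg_per_cell() == pytest.approx(0.7)

    def test_zero_sg_scene(self):
        scene = simulate_sg_scene(SceneConfig(n_cells=5, sg_rate=0.0,
                                              sg_rate_untransfected=0.0, seed=21))
        s = quantify_image(scene)
        assert s.fraction_cells_with_sg() == 0.0
        assert s.mean_sg_per_cell() == 0.0

    def test_count_conservation(self, noisy_scene):
        s = quantify_image(noisy_scene)
        assert s.cells.n_sg.sum() == len(s.granules)
        scored = s.cells.n_enriched + s.cells.n_nonenriched + s.cells.n_unscored
        assert (scored == s.cells.n_sg).all()

    def test_poisson_rate_recovered(self):
        # planted rate 2.0; pooled over scenes the mean per transfected
        # cell should land within 3 standard errors
        counts = []
        for seed in range(6):
            scene = simulate_sg_scene(SceneConfig(n_cells=20, seed=100 + seed))
            s = quantify_image(scene)
            counts.extend(s.cells[s.cells.is_transfected].n_sg.tolist())
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 2.0) < 3 * se + 1e-9
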