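"""Cytometry: segmentation, IFI, gating, PAD/centromere counting, heterogeneity."""
import numpy as np
import pytest
from skimage.draw import disk

import padcyto as pc
from padcyto.quantify import QuantConfig, gate_cells

from tests.conftest import make_image, make_nucleus


def multi_nucleus_field(centers, radius=14, size=200, level=100.0):
    blue = np.zeros((size, size))
    for cy, cx in centers:
        rr, cc = disk((cy, cx), radius, shape=blue.shape)
        blue[rr, cc] = level
    return make_image(blue=blue, px_per_um=1.0)


class TestSegmentNuclei:
    def test_blank_channel_gives_no_nuclei(self):
        img = make_image(blue=np.zeros((64, 64)), px_per_um=1.0)
        assert pc.segment_nuclei(img) == []

    def test_non_touching_nuclei_recovered_with_areas(self):
        centers = [(30 + 45 * r, 30 + 45 * c) for r in range(3) for c in range(3)]
        centers.append((30, 160))
        img = multi_nucleus_field(centers)
        cfg = QuantConfig(min_nucleus_area_um2=100.0, max_nucleus_area_um2=2000.0)
        records = pc.segment_nuclei(img, cfg)
        assert len(records) == 10
        expected = np.pi * 14**2
        for r in records:
            assert r.area_px == pytest.approx(expected, rel=0.05)

    def test_border_touching_nuclei_dropped(self):
        img = multi_nucleus_field([(5, 100), (100, 100)])
        records = pc.segment_nuclei(img, QuantConfig(min_nucleus_area_um2=100.0,
                                                     max_nucleus_area_um2=2000.0))
        assert len(records) == 1

    def test_merged_nuclei_flagged_oversized(self):
        img = multi_nucleus_field([(100, 90), (100, 110)])  # overlapping discs
        cfg = QuantConfig(min_nucleus_area_um2=100.0, max_nucleus_area_um2=700.0)
        records = pc.segment_nuclei(img, cfg)
        assert len(records) == 1 and records[0].oversized


class TestDNAContent:
    def test_uniform_intensity_sums(self):
        blue = np.full((20, 20), 3.0)
        mask = np.zeros((20, 20), bool)
        mask[:10, :10] = True
        nuc = make_nucleus(mask)
        assert pc.measure_dna_content(nuc, make_image(blue=blue)) == 300.0

    def test_ifi_additive_over_partition(self, rng):
        blue = rng.uniform(0, 50, (30, 30))
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        half_a, half_b = mask.copy(), mask.copy()
        half_a[:, 15:] = False
        half_b[:, :15] = False
        img = make_image(blue=blue)
        whole = pc.measure_dna_content(make_nucleus(mask), img)
        parts = pc.measure_dna_content(make_nucleus(half_a), img) + pc.measure_dna_content(
            make_nucleus(half_b), img
        )
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_replicating_cell_has_double_ifi(self):
        """A noise-free S-G2 (replicated DNA) cell integrates ~2x the 2C signal."""
        base = dict(n_cells=8, noise_sd=0.0, seed=6, count_law=(5, 8),
                    dirichlet_alpha=4.0)
        img2c, _ = pc.simulate_population(
            pc.PopulationParams(dna_class_probs=(1.0, 0.0, 0.0), **base))
        img4c, _ = pc.simulate_population(
            pc.PopulationParams(dna_class_probs=(0.0, 1.0, 0.0), **base))
        ifi_2c = np.mean([pc.segment_nuclei(i)[0].dapi_ifi for i in img2c])
        ifi_4c = np.mean([pc.segment_nuclei(i)[0].dapi_ifi for i in img4c])
        assert ifi_4c / ifi_2c == pytest.approx(2.0, rel=0.07)


class TestGating:
    def _records(self, ifis):
        mask = np.ones((2, 2), bool)
        return [
            pc.NucleusRecord(nucleus_id=i, mask=mask, area_px=4, area_um2=4.0,
                             dapi_ifi=float(v))
            for i, v in enumerate(ifis)
        ]

    def test_identical_ifi_all_2c(self):
        records = self._records([500.0] * 25)
        report = gate_cells(records)
        assert all(r.gate == "2C" for r in records)
        assert report.fractions["2C"] == 1.0

    def test_too_few_cells_left_unassigned(self):
        records = self._records([500.0] * 5)
        report = gate_cells(records)
        assert not report.assigned
        assert all(r.gate == "unassigned" for r in records)

    def test_bimodal_mode_picks_taller_peak(self):
        records = self._records([100.0] * 30 + [200.0] * 10)
        gate_cells(records)
        assert all(r.gate == "2C" for r in records[:30])
        assert all(r.gate == "S-G2" for r in records[30:])

    def test_mixture_fractions_recovered(self):
        """Gated 85/10/5 class fractions match ground truth within 3 points."""
        params = pc.PopulationParams(n_cells=300, seed=2, image_size=128,
                                     px_per_um=6.0, nucleus_radius_um=5.0)
        images, truth = pc.simulate_population(params)
        nuclei, summaries = [], []
        for k, img in enumerate(images):
            nuc, pads, summ = pc.quantify_field(img)
            for n in nuc:
                n.nucleus_id = k
            for s in summ:
                s.nucleus_id = k
            nuclei += nuc
            summaries += summ
        report = gate_cells(nuclei, pad_summaries={s.nucleus_id: s for s in summaries})
        for cls in ("2C", "S-G2", "preapoptotic"):
            true_frac = np.mean([c.dna_class == cls for c in truth.cells])
            assert report.fractions[cls] == pytest.approx(true_frac, abs=0.03)


class TestSegmentPads:
    def test_uniform_square_is_one_pad(self):
        red = np.zeros((40, 40))
        red[10:20, 10:20] = 50.0
        mask = np.ones((40, 40), bool)
        img = make_image(blue=np.ones((40, 40)), red=red, px_per_um=1.0)
        pads = pc.segment_pads(img, make_nucleus(mask), QuantConfig(min_pad_area_um2=1.0))
        assert len(pads) == 1 and pads[0].area_px == 100

    def test_blank_red_plane_gives_no_pads(self):
        img = make_image(blue=np.ones((30, 30)), red=np.zeros((30, 30)))
        assert pc.segment_pads(img, make_nucleus(np.ones((30, 30), bool))) == []

    def test_small_components_filtered(self):
        red = np.zeros((40, 40))
        red[10:20, 10:20] = 50.0
        red[30, 30] = 50.0  # single-pixel speck
        img = make_image(blue=np.ones((40, 40)), red=red, px_per_um=1.0)
        pads = pc.segment_pads(img, make_nucleus(np.ones((40, 40), bool)),
                               QuantConfig(min_pad_area_um2=2.0))
        assert len(pads) == 1


class TestCountCentromeres:
    def _two_pad_setup(self):
        red = np.zeros((40, 40))
        red[5:15, 5:15] = 50.0
        red[25:35, 25:35] = 50.0
        green = np.zeros((40, 40))
        nucleus = make_nucleus(np.ones((40, 40), bool))
        return red, green, nucleus

    def test_no_foci_gives_zero_counts(self):
        red, green, nucleus = self._two_pad_setup()
        img = make_image(blue=np.ones((40, 40)), red=red, green=green)
        pads = pc.segment_pads(img, nucleus, QuantConfig(min_pad_area_um2=1.0))
        pc.count_centromeres(img, pads, nucleus=nucleus)
        assert [p.centromere_count for p in pads] == [0, 0]

    def test_one_focus_per_pad(self):
        red, green, nucleus = self._two_pad_setup()
        green[9:12, 9:12] = 80.0
        green[29:32, 29:32] = 80.0
        img = make_image(blue=np.ones((40, 40)), red=red, green=green)
        pads = pc.segment_pads(img, nucleus, QuantConfig(min_pad_area_um2=1.0))
        pc.count_centromeres(img, pads, nucleus=nucleus)
        assert [p.centromere_count for p in pads] == [1, 1]


class TestHeterogeneity:
    def _measure(self, values, tolerance=0.10):
        img = make_image(green=np.asarray(values, float).reshape(1, -1))
        nuc = make_nucleus(np.ones((1, len(values)), bool))
        return pc.heterogeneity(img, nuc, tolerance=tolerance)

    def test_uniform_is_zero(self):
        assert self._measure([7.0] * 10) == 0.0

    def test_two_level_image_is_one(self):
        assert self._measure([50.0] * 5 + [150.0] * 5) == 1.0

    def test_exact_ten_percent_not_counted(self):
        assert self._measure([90.0, 100.0, 110.0, 100.0]) == 0.0

    def test_scale_invariance(self, rng):
        values = rng.uniform(10, 200, 64)
        assert self._measure(values) == self._measure(values * 17.3)

    def test_monotone_in_tolerance(self, rng):
        values = rng.uniform(10, 200, 256)
        fracs = [self._measure(values, tolerance=t) for t in (0.30, 0.20, 0.10, 0.05)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_zero_field_defined_as_homogeneous(self):
        assert self._measure([0.0] * 8) == 0.0


class TestSummarize:
    def test_basic_aggregation(self):
        from tests.conftest import make_pad

        nuc = make_nucleus(np.ones((4, 4), bool))
        pads = [make_pad(1.0, pad_id=i) for i in range(4)]
        s = pc.summarize_cell(nuc, pads)
        assert (s.n_pads, s.mean_area_um2, s.total_area_um2, s.sqrt_mean_area) == (
            4, 1.0, 4.0, 1.0)
        s9 = pc.summarize_cell(nuc, [make_pad(9.0)])
        assert s9.sqrt_mean_area == 3.0

    def test_zero_pads_flagged(self):
        nuc = make_nucleus(np.ones((4, 4), bool))
        s = pc.summarize_cell(nuc, [])
        assert s.n_pads == 0 and not s.valid_for_fits

    def test_linkage_mismatch_rejected(self):
        from tests.conftest import make_pad

        nuc = make_nucleus(np.ones((4, 4), bool), nucleus_id=1)
        with pytest.raises(ValueError):
            pc.summarize_cell(nuc, [make_pad(1.0, nucleus_id=2)])


class TestExactRecovery:
    """Noise-free, well-separated fields: the pipeline equals ground truth."""

    def test_counts_areas_centromeres_and_gates(self, clean_cohort):
        params, images, truth = clean_cohort
        nuclei, summaries, measured = [], [], []
        for k, (img, cell) in enumerate(zip(images, truth.cells)):
            nuc, pads, summ = pc.quantify_field(img)
            assert len(nuc) == 1
            nuc[0].nucleus_id = k
            summ[0].nucleus_id = k
            assert len(pads) == cell.n_pads
            assert sorted(p.centromere_count for p in pads) == sorted(
                cell.centromere_counts)
            assert summ[0].total_area_um2 == pytest.approx(
                cell.total_pad_area_um2, rel=0.05)
            nuclei += nuc
            summaries += summ
        gate_cells(nuclei, pad_summaries={s.nucleus_id: s for s in summaries})
        for nuc, cell in zip(nuclei, truth.cells):
            assert nuc.gate == cell.dna_class
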