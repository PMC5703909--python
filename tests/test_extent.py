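"""Axial extents: threshold calling, polarity classes, nucleoid relations,
and integrated-intensity DNA-content emulation."""

import numpy as np
import pytest

import rodquant as rq
from conftest import make_config
from test_profiling import profile_from


def extent_with(intervals, cell_id=1, channel="c", flags=()):
    frac = sum(b - a for a, b in intervals)
    return rq.AxialExtent(cell_id, channel, list(intervals), frac * 5.0, frac, "", flags)


class TestMeasureExtent:
    def test_boxcar_recovers_its_span(self):
        n = 100
        s = (np.arange(n) + 0.5) / n
        y = np.where((s >= 0.25) & (s <= 0.75), 200.0, 0.0)
        ext = rq.measure_extent(profile_from(y), background=0.0, alpha=0.3)
        assert len(ext.intervals) == 1
        assert ext.fraction == pytest.approx(0.50, abs=1.0 / n)
        (iv,) = ext.intervals
        assert iv[0] == pytest.approx(0.25, abs=1.0 / n)
        assert iv[1] == pytest.approx(0.75, abs=1.0 / n)

    def test_everywhere_above_threshold_is_full_length(self):
        y = np.full(50, 80.0)
        y[10] = 100.0  # a max must exceed the background
        ext = rq.measure_extent(profile_from(y), background=10.0, alpha=0.3)
        assert ext.fraction == pytest.approx(1.0)
        assert ext.intervals == [(0.0, 1.0)]

    def test_flat_background_profile_is_none(self):
        ext = rq.measure_extent(profile_from(np.full(40, 5.0)), background=5.0)
        assert ext.intervals == [] and ext.polarity == "none"
        assert ext.fraction == 0.0

    def test_short_runs_dropped_and_gaps_merged(self):
        y = np.zeros(60)
        y[5] = 100.0  # 1-bin blip: dropped
        y[30:36] = 100.0
        y[38:44] = 100.0  # gap of 2 bins: merged with previous run
        ext = rq.measure_extent(profile_from(y), background=0.0, alpha=0.3)
        assert len(ext.intervals) == 1
        s0, s1 = ext.intervals[0]
        assert 0.45 < s0 < 0.52 and 0.70 < s1 < 0.76

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            rq.measure_extent(profile_from(np.ones(20)), alpha=1.5)

    def test_nucleoid_fraction_recovery_on_synthetic_cells(self):
        cfg = make_config(
            seed=19, n_cells=15,
            channels=[dict(name="dapi", kind="nucleoid", nucleoid_fraction=0.5,
                           amplitude=rq.extended_amplitude_for_snr(10, 100.0))],
        )
        truths, channels, labels = rq.simulate_field(cfg)
        bg = rq.estimate_background(channels[0], labels)
        geoms = rq.extract_geometry(labels, cfg.pixel_size)
        errs = []
        for g in geoms:
            p = rq.extract_profile(channels[0], labels, g, 100)
            ext = rq.measure_extent(
                p, background=bg, alpha=0.3, psf_sigma_s=cfg.psf_sigma / g.length_px
            )
            errs.append(abs(ext.fraction - 0.5))
        errs = np.array(errs)
        assert np.mean(errs <= 0.03) >= 0.95


class TestClassifyPolarity:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([(0.0, 0.2), (0.8, 1.0)], "bipolar"),
            ([(0.0, 0.25)], "unipolar"),
            ([(0.78, 1.0)], "unipolar"),
            ([(0.42, 0.58)], "midcell"),
            ([(0.0, 1.0)], "diffuse"),  # spans both poles
            ([(0.25, 0.38)], "diffuse"),  # neither polar nor midcell
            ([], "none"),
        ],
    )
    def test_polarity_rules(self, intervals, expected):
        assert rq.classify_polarity(extent_with(intervals)) == expected

    def test_signal_without_qualifying_run_is_diffuse(self):
        ext = extent_with([], flags=("signal_below_min_run",))
        assert rq.classify_polarity(ext) == "diffuse"

    def test_mirror_preserves_bipolar_and_midcell(self):
        for ivs, cls in [([(0.0, 0.2), (0.8, 1.0)], "bipolar"), ([(0.45, 0.55)], "midcell")]:
            mirrored = sorted((1 - b, 1 - a) for a, b in ivs)
            assert rq.classify_polarity(extent_with(mirrored)) == cls


class TestFocusNucleoidRelation:
    def focus(self, s, cell_id=1):
        return rq.Focus(cell_id, "f", (0, 0), s, s * 5.0, 10.0, 1.3, 0.0)

    def test_edge_center_and_hand_cases(self):
        nuc = extent_with([(0.25, 0.75)])
        rels = rq.relate_foci_to_nucleoid(
            [self.focus(0.25), self.focus(0.5), self.focus(0.35)], nuc
        )
        assert rels[0].edge_distance == pytest.approx(0.0) and rels[0].inside_nucleoid
        assert rels[1].edge_distance == pytest.approx(0.5)
        assert rels[2].edge_distance == pytest.approx(0.2)  # 0.1 / 0.5

    def test_outside_focus_is_negative(self):
        nuc = extent_with([(0.25, 0.75)])
        (rel,) = rq.relate_foci_to_nucleoid([self.focus(0.1)], nuc)
        assert rel.edge_distance == pytest.approx(-0.3)
        assert not rel.inside_nucleoid

    def test_empty_nucleoid_flags_undefined(self):
        (rel,) = rq.relate_foci_to_nucleoid([self.focus(0.5)], extent_with([]))
        assert rel.edge_distance is None and "no_nucleoid" in rel.flags

    def test_multi_interval_uses_union_and_flags(self):
        nuc = extent_with([(0.2, 0.4), (0.6, 0.8)])
        (rel,) = rq.relate_foci_to_nucleoid([self.focus(0.5)], nuc)
        assert "multi_interval_union" in rel.flags
        assert rel.edge_distance == pytest.approx(0.5)  # center of the union


class TestIntegratedIntensity:
    def test_blank_cell_is_zero(self):
        labels = np.zeros((30, 30), np.uint16)
        labels[5:15, 5:15] = 1
        img = np.full((30, 30), 7.0)
        df = rq.integrated_cell_intensity(img, labels, background=7.0)
        assert df.integrated_intensity.iloc[0] == 0.0

    def test_uniform_cell_arithmetic(self):
        labels = np.zeros((30, 30), np.uint16)
        labels[5:15, 5:25] = 1
        img = np.full((30, 30), 3.0)
        img[labels == 1] = 12.0
        df = rq.integrated_cell_intensity(img, labels, background=3.0)
        assert df.integrated_intensity.iloc[0] == pytest.approx(200 * 9.0)

    def test_background_mode_estimate(self):
        rng = np.random.default_rng(2)
        labels = np.zeros((200, 200), np.uint16)
        labels[50:100, 50:150] = 1
        img = rng.poisson(100.0, size=(200, 200)).astype(float)
        bg = rq.estimate_background(img, labels)
        assert bg == pytest.approx(100.0, abs=3.0)

    def test_dna_content_ratio_recovered(self):
        cfg = make_config(
            seed=23, n_cells=16,
            channels=[dict(name="dapi", kind="nucleoid",
                           amplitude=rq.extended_amplitude_for_snr(10, 100.0),
                           content_values=(1.0, 2.0), content_probs=(0.5, 0.5))],
        )
        truths, channels, labels = rq.simulate_field(cfg)
        df = rq.integrated_cell_intensity(channels[0], labels).set_index("cell_id")
        per_unit = []
        for t in truths:
            # normalize by nucleoid footprint: intensity / (content * area-ish)
            iv = t.nucleoid_interval["dapi"]
            footprint = (iv[1] - iv[0]) * t.length_um
            per_unit.append(
                df.loc[t.cell_id, "integrated_intensity"] / (t.dna_content * footprint)
            )
        per_unit = np.array(per_unit)
        # after dividing out true content the per-unit signal is constant +-5%
        assert per_unit.std() / per_unit.mean() < 0.05
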