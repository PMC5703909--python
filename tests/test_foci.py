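"""Focus detection and segregation metrics: sub-pixel accuracy, the S and
D_min formulas, and their mirror/scale/range invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rodquant as rq
from rodquant.simulate import _render_gaussian_spot
from conftest import make_config, straight_cell_mask, synth_geom


def make_focus(cell_id, s, length_um, channel="f"):
    return rq.Focus(
        cell_id=cell_id, channel=channel, center=(0.0, 0.0),
        s=s, x_um=s * length_um, amplitude=100.0, fit_sigma=1.3, quality=0.01,
    )


def rect_geom(length_um=10.0):
    # 40 x 140 rectangle, 0-99 px span at chosen pixel size
    labels = straight_cell_mask(shape=(40, 140), row0=15, row1=25, col0=20, col1=120)
    (g,) = rq.extract_geometry(labels, length_um / 99.0)
    return g, labels


class TestDetectFoci:
    def test_blank_cell_yields_no_foci(self):
        # false-positive control: pure Poisson background inside the mask
        g, labels = rect_geom()
        rng = np.random.default_rng(0)
        img = rng.poisson(100.0, size=labels.shape).astype(float)
        foci = rq.detect_foci(img, labels, [g], rq.DetectionParams(psf_sigma=1.3, k_sd=5))
        assert foci == []

    def test_noiseless_spot_localized_to_subpixel(self):
        g, labels = rect_geom()
        img = np.full(labels.shape, 10.0)
        _render_gaussian_spot(img, (20.3, 61.7), 1.3, 3000.0)
        foci = rq.detect_foci(img, labels, [g], rq.DetectionParams(psf_sigma=1.3))
        assert len(foci) == 1
        r, c = foci[0].center
        assert abs(r - 20.3) < 0.05 and abs(c - 61.7) < 0.05
        assert foci[0].fit_sigma == pytest.approx(1.3, abs=0.05)
        assert foci[0].amplitude == pytest.approx(3000.0, rel=0.05)

    def test_two_spots_at_snr10_recovered_within_half_pixel(self):
        g, labels = rect_geom()
        amp = rq.focus_amplitude_for_snr(10, 100.0, 1.3)
        rng = np.random.default_rng(1)
        truth = [(20.0, 45.0), (20.0, 95.0)]  # separation >> 4 sigma
        ideal = np.full(labels.shape, 100.0)
        for center in truth:
            _render_gaussian_spot(ideal, center, 1.3, amp)
        img = rng.poisson(ideal).astype(float)
        foci = rq.detect_foci(img, labels, [g], rq.DetectionParams(psf_sigma=1.3))
        assert len(foci) == 2
        got = sorted(f.center for f in foci)
        for (gr, gc), (tr, tc) in zip(got, truth):
            assert np.hypot(gr - tr, gc - tc) < 0.5

    def test_spot_on_background_is_dropped(self):
        g, labels = rect_geom()
        img = np.full(labels.shape, 10.0)
        _render_gaussian_spot(img, (5.0, 61.0), 1.3, 3000.0)  # outside the mask
        foci = rq.detect_foci(img, labels, [g], rq.DetectionParams(psf_sigma=1.3))
        assert foci == []


class TestSegregationMetrics:
    def test_single_focus_has_s_zero_by_definition(self):
        g, _ = rect_geom(length_um=10.0)
        for s in (0.05, 0.3, 0.77):
            m = rq.compute_segregation_metrics([make_focus(g.cell_id, s, 10.0)], g)
            assert m.S == 0.0
            assert m.D_min == pytest.approx(100 * min(s, 1 - s))

    def test_symmetric_pair_gives_s_100(self):
        # L = 10, foci at 2.5 and 7.5 um: D1 = D2 = 2.5, D = 5
        g, _ = rect_geom(10.0)
        foci = [make_focus(g.cell_id, 0.25, 10.0), make_focus(g.cell_id, 0.75, 10.0)]
        m = rq.compute_segregation_metrics(foci, g)
        assert m.D1 == pytest.approx(2.5) and m.D2 == pytest.approx(2.5)
        assert m.D == pytest.approx(5.0)
        assert m.S == pytest.approx(100.0)
        assert m.D_min == pytest.approx(25.0)

    def test_hand_evaluated_asymmetric_pair(self):
        # L = 10, foci at 1 and 7 um: D = 6, S = 100*6/(6+2) = 75, D_min = 10
        g, _ = rect_geom(10.0)
        foci = [make_focus(g.cell_id, 0.1, 10.0), make_focus(g.cell_id, 0.7, 10.0)]
        m = rq.compute_segregation_metrics(foci, g)
        assert m.D1 == pytest.approx(1.0, abs=1e-12)
        assert m.D2 == pytest.approx(3.0, abs=1e-12)
        assert m.D == pytest.approx(6.0, abs=1e-12)
        assert m.S == pytest.approx(75.0, abs=1e-12)
        assert m.D_min == pytest.approx(10.0, abs=1e-12)

    def test_zero_and_many_foci(self):
        g, _ = rect_geom(10.0)
        m0 = rq.compute_segregation_metrics([], g)
        assert m0.S is None and m0.D_min is None and m0.n_foci == 0
        m3 = rq.compute_segregation_metrics(
            [make_focus(g.cell_id, s, 10.0) for s in (0.1, 0.5, 0.8)], g
        )
        assert m3.S is None
        assert m3.D_min == pytest.approx(10.0)
        assert "multi_foci" in m3.flags

    def test_coincident_foci_flagged_undefined(self):
        g, _ = rect_geom(10.0)
        foci = [make_focus(g.cell_id, 0.4, 10.0), make_focus(g.cell_id, 0.4, 10.0)]
        m = rq.compute_segregation_metrics(foci, g)
        assert m.S is None and "coincident_foci" in m.flags

    def test_foreign_focus_rejected(self):
        g, _ = rect_geom(10.0)
        with pytest.raises(ValueError):
            rq.compute_segregation_metrics([make_focus(g.cell_id + 1, 0.5, 10.0)], g)

    @given(
        st.floats(0.001, 0.999), st.floats(0.001, 0.999),
        st.floats(1.0, 20.0), st.floats(0.1, 10.0),
    )
    def test_mirror_scale_and_range_invariants(self, s1, s2, length, scale):
        if abs(s1 - s2) < 1e-9:
            return
        g = synth_geom(length)
        foci = [make_focus(g.cell_id, s1, length), make_focus(g.cell_id, s2, length)]
        m = rq.compute_segregation_metrics(foci, g)
        assert 0.0 < m.S <= 100.0
        assert 0.0 <= m.D_min <= 50.0
        # mirror: s -> 1 - s
        mirrored = [make_focus(g.cell_id, 1 - s1, length), make_focus(g.cell_id, 1 - s2, length)]
        mm = rq.compute_segregation_metrics(mirrored, g)
        assert mm.S == pytest.approx(m.S, abs=1e-9)
        assert mm.D_min == pytest.approx(m.D_min, abs=1e-9)
        # scale: c * L with fixed fractions
        gs = synth_geom(length * scale)
        scaled = [make_focus(gs.cell_id, s1, length * scale), make_focus(gs.cell_id, s2, length * scale)]
        ms = rq.compute_segregation_metrics(scaled, gs)
        assert ms.S == pytest.approx(m.S, rel=1e-9)
        assert ms.D_min == pytest.approx(m.D_min, rel=1e-9)

    def test_s_is_100_iff_d1_equals_d2(self):
        g, _ = rect_geom(10.0)
        foci = [make_focus(g.cell_id, 0.31, 10.0), make_focus(g.cell_id, 0.69, 10.0)]
        assert rq.compute_segregation_metrics(foci, g).S == pytest.approx(100.0)
        foci = [make_focus(g.cell_id, 0.31, 10.0), make_focus(g.cell_id, 0.68, 10.0)]
        assert rq.compute_segregation_metrics(foci, g).S < 100.0


class TestPopulationMetrics:
    def metrics_with_counts(self, counts):
        g, _ = rect_geom(10.0)
        out = []
        for i, n in enumerate(counts):
            ss = np.linspace(0.2, 0.8, n) if n else []
            foci = [make_focus(g.cell_id, s, 10.0) for s in ss]
            m = rq.compute_segregation_metrics(foci, g)
            m.cell_id = i + 1
            out.append(m)
        return out

    def test_focus_count_tally_percentages(self):
        ms = self.metrics_with_counts([1, 2, 2, 3, 0])
        _, tally = rq.population_metrics(ms)
        assert tally[0] == (1, 20.0)
        assert tally[1] == (1, 20.0)
        assert tally[2] == (2, 40.0)
        assert tally[">2"] == (1, 20.0)

    def test_two_focus_population_keeps_all_rows(self):
        ms = self.metrics_with_counts([2] * 6)
        df, _ = rq.population_metrics(ms, two_focus_only=True)
        assert len(df) == 6
        assert df.S.notna().all()

    def test_no_two_focus_cells_warns_not_errors(self):
        ms = self.metrics_with_counts([1, 1, 3])
        with pytest.warns(UserWarning):
            df, _ = rq.population_metrics(ms, two_focus_only=True)
        assert df.empty
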