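"""Mean control PDF, per-beat quantifiers, windowing, deltas and statistics."""

import numpy as np
import pytest

from ecghc.ordinal import (
    OrdinalPDF,
    jensen_shannon_divergence,
    normalized_entropy,
)
from ecghc.trajectory import (
    PhaseSeries,
    compare_sections,
    control_region,
    control_sections,
    delta_metrics,
    delta_relative,
    mean_control_pdf,
    per_beat_quantifiers,
    window_average,
)


def _series(phase, times, H=None, C=None, jsd=None, pdfs=None):
    times = np.asarray(times, dtype=float)
    n = times.size
    if pdfs is None:
        pdfs = tuple(OrdinalPDF.uniform(3) for _ in range(n))
    z = np.zeros(n)
    return PhaseSeries(
        phase=phase,
        beat_times=times,
        beat_pdfs=tuple(pdfs),
        H=np.asarray(H, float) if H is not None else z,
        C=np.asarray(C, float) if C is not None else z,
        Q=z.copy(),
        jsd=np.asarray(jsd, float) if jsd is not None else z,
    )


class TestMeanControlPdf:
    def test_identical_pdfs_average_to_themselves(self):
        p = OrdinalPDF(np.array([0.5, 0.25, 0.25, 0, 0, 0]), 3, 1)
        mean = mean_control_pdf([p, p, p])
        np.testing.assert_allclose(mean.probs, p.probs)

    def test_two_degenerates_average_to_half_half(self):
        mean = mean_control_pdf(
            [OrdinalPDF.degenerate(3, 1), OrdinalPDF.degenerate(3, 2)]
        )
        np.testing.assert_allclose(mean.probs, [0.5, 0.5, 0, 0, 0, 0])

    def test_mean_beats_random_candidates_at_mean_jsd(self, rng):
        """The componentwise mean is a near-minimizer of the average JSD to
        the beat PDFs; coarse random candidates never beat it."""
        beats = [
            OrdinalPDF(rng.dirichlet(np.full(24, 40.0)), 4, 2) for _ in range(100)
        ]
        mean = mean_control_pdf(beats)
        score = np.mean([jensen_shannon_divergence(b, mean) for b in beats])
        for _ in range(200):
            cand = rng.dirichlet(np.ones(24))
            cand_score = np.mean(
                [jensen_shannon_divergence(b.probs, cand) for b in beats]
            )
            assert score <= cand_score

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            mean_control_pdf([])


class TestPerBeatQuantifiers:
    def test_control_beat_identical_to_reference_has_zero_jsd(self, rng):
        w = np.cumsum(rng.standard_normal(512))
        series = per_beat_quantifiers(np.stack([w, w]), [0.0, 1.0], "control")
        ref = mean_control_pdf(series)
        series = series.with_reference(ref)
        np.testing.assert_allclose(series.jsd, 0.0, atol=1e-12)

    def test_constant_beat_is_fully_ordered_under_tie_rule(self):
        series = per_beat_quantifiers(np.zeros((1, 512)), [0.0], "control")
        assert series.H[0] == 0.0 and series.C[0] == 0.0

    def test_window_count_at_defaults(self):
        series = per_beat_quantifiers(np.random.default_rng(0).random((1, 512)),
                                      [0.0], "control", D=4, tau=2)
        assert series.beat_pdfs[0].n_windows == 506

    def test_entropy_matches_independent_recomputation(self, rng):
        windows = rng.standard_normal((5, 512))
        series = per_beat_quantifiers(windows, np.arange(5.0), "occlusion")
        from conftest import naive_pdf

        for w, h in zip(windows, series.H):
            p = naive_pdf(w, 4, 2)
            assert h == pytest.approx(normalized_entropy(p), rel=1e-12)


class TestWindowAverage:
    def test_constant_quantifiers_give_constant_windows(self):
        s = _series("occlusion", np.linspace(0, 119, 80), H=np.full(80, 0.8),
                    C=np.full(80, 0.15), jsd=np.full(80, 0.02))
        traj = window_average(s, 30.0, phase_duration_s=120.0)
        assert traj.window_centers.size == 4
        np.testing.assert_allclose(traj.H_mean, 0.8)
        np.testing.assert_allclose(traj.jsd_mean, 0.02)

    def test_single_beat_per_window_passes_through(self):
        H = np.array([0.1, 0.2, 0.3])
        s = _series("recovery", [5.0, 20.0, 35.0], H=H)
        traj = window_average(s, 15.0, phase_duration_s=45.0)
        np.testing.assert_allclose(traj.H_mean, H)
        assert traj.n_beats.tolist() == [1, 1, 1]

    def test_linear_trend_recovered_at_window_midpoints(self):
        t = np.linspace(0, 120, 600, endpoint=False)
        s = _series("occlusion", t, H=0.9 - 0.001 * t)
        traj = window_average(s, 30.0, phase_duration_s=120.0)
        np.testing.assert_allclose(
            traj.H_mean, 0.9 - 0.001 * traj.window_centers, atol=1e-4
        )

    def test_empty_windows_marked_not_interpolated(self):
        s = _series("occlusion", [5.0, 65.0], H=[0.5, 0.7])
        traj = window_average(s, 30.0, phase_duration_s=90.0)
        assert traj.n_beats.tolist() == [1, 0, 1]
        assert np.isnan(traj.H_mean[1])

    def test_short_trailing_window_dropped(self):
        s = _series("occlusion", [5.0, 35.0, 61.0], H=[1, 1, 1])
        traj = window_average(s, 30.0, phase_duration_s=64.0)  # 4 s remainder
        assert traj.window_centers.size == 2


class TestDeltaMetrics:
    def test_reference_occlusion_endpoints(self):
        """H falling 0.87 -> 0.76 is a 12.6% drop; C rising 0.12 -> 0.18 is
        a 50% gain."""
        assert delta_relative(0.87, 0.76) == pytest.approx(-0.126, abs=5e-4)
        assert delta_relative(0.12, 0.18) == pytest.approx(0.50, abs=1e-12)

    def test_trajectory_endpoints_use_first_and_last_nonempty(self):
        s = _series("occlusion", [5.0, 65.0, 95.0],
                    H=[0.87, 0.80, 0.76], C=[0.12, 0.15, 0.18])
        traj = window_average(s, 30.0, phase_duration_s=120.0)
        d = delta_metrics(traj)
        assert d.delta_H == pytest.approx((0.76 - 0.87) / 0.87)
        assert d.delta_C == pytest.approx((0.18 - 0.12) / 0.12)

    def test_constant_trajectory_gives_zero_deltas(self):
        s = _series("occlusion", [5.0, 45.0], H=[0.8, 0.8], C=[0.1, 0.1])
        d = delta_metrics(window_average(s, 30.0, phase_duration_s=60.0))
        assert d.delta_H == 0.0 and d.delta_C == 0.0

    def test_requires_two_nonempty_windows(self):
        s = _series("occlusion", [5.0], H=[0.8], C=[0.1])
        with pytest.raises(ValueError, match="2 non-empty"):
            delta_metrics(window_average(s, 30.0, phase_duration_s=30.0))


class TestControlSections:
    def test_four_minutes_of_occlusion_give_eight_sections(self):
        # 4 min at 30 s windows -> 8 occlusion windows -> 8 control sections
        n_sections = int(240.0 // 30.0)
        assert n_sections == 8
        s = _series("control", np.linspace(0, 299, 300),
                    jsd=np.full(300, 0.03))
        out = control_sections(s, n_sections)
        assert out.size == 8
        np.testing.assert_allclose(out, 0.03)

    def test_sections_match_brute_force_partition(self, rng):
        times = np.sort(rng.uniform(0, 300, 200))
        jsd = rng.random(200)
        s = _series("control", times, jsd=jsd)
        out = control_sections(s, 6)
        edges = np.linspace(0, times[-1] + 1e-9, 7)
        for i in range(6):
            sel = (times >= edges[i]) & (times < edges[i + 1])
            assert out[i] == pytest.approx(jsd[sel].mean())


class TestCompareSections:
    def test_identical_samples_not_significant(self, rng):
        x = rng.standard_normal(12)
        res = compare_sections(x, x.copy())
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert not res.significant

    def test_separated_gaussians_use_t_and_detect(self, rng):
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(3.0, 1.0, 15)
        res = compare_sections(a, b)
        assert res.test_used == "t"
        assert res.significant

    def test_skewed_samples_fall_back_to_mann_whitney(self, rng):
        a = np.exp(rng.normal(0, 1.5, 40))
        b = np.exp(rng.normal(1.2, 1.5, 40))
        res = compare_sections(a, b)
        assert res.test_used == "mann-whitney"
        assert res.significant

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="3 patients"):
            compare_sections([1.0, 2.0], [1.0, 2.0, 3.0])


class TestControlRegion:
    def test_single_point_degenerate_box(self):
        s = _series("control", [5.0], H=[0.85], C=[0.13])
        traj = window_average(s, 30.0, phase_duration_s=30.0)
        (h0, h1), (c0, c1) = control_region([traj])
        assert h0 == h1 == 0.85 and c0 == c1 == 0.13

    def test_two_points_span_box(self):
        s = _series("control", [5.0, 35.0], H=[0.84, 0.86], C=[0.14, 0.13])
        traj = window_average(s, 30.0, phase_duration_s=60.0)
        (h0, h1), (c0, c1) = control_region([traj])
        assert (h0, h1) == (0.84, 0.86)
        assert (c0, c1) == (0.13, 0.14)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            control_region([])
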