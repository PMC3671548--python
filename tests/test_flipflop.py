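"""Flip-flop event detection and double-exponential interval fitting."""

import numpy as np
import pytest

import memcurv as mc
from memcurv.core import CholesterolResidence
from memcurv.errors import MemcurvError
from memcurv.flipflop import IntervalHistogram, _debounce_events


def residence_series(states, frame_dt=4.0):
    """Build per-frame residences from a list of per-molecule state lists.

    ``states[m]`` is a list of (leaflet, domain_type) tuples, one per frame.
    """
    n_frames = len(states[0])
    out = []
    for k in range(n_frames):
        leaf = np.array([states[m][k][0] for m in range(len(states))],
                        dtype=object)
        dom = np.array([states[m][k][1] for m in range(len(states))],
                       dtype=object)
        out.append(CholesterolResidence(
            mol_id=np.arange(len(states)), leaflet=leaf, domain=dom,
            domain_type=dom, time=k * frame_dt,
        ))
    return out


U_PC, U_PS = ("upper", "DOPC"), ("upper", "DOPS")
L_PC, L_PS = ("lower", "DOPC"), ("lower", "DOPS")


class TestDetectFlipflops:
    def test_constant_residence_gives_no_events(self):
        res = residence_series([[U_PC] * 8])
        rec = mc.detect_flipflops(res)
        assert rec.n_events == 0
        assert rec.intervals.size == 0

    def test_alternating_molecule_gives_event_per_frame(self):
        res = residence_series([[U_PC, L_PS] * 5 + [U_PC]])
        rec = mc.detect_flipflops(res)
        assert rec.n_events == 10
        assert np.all(rec.intervals == 4.0)

    def test_leaflet_change_within_same_lipid_type_not_counted(self):
        # mixed region: DOPC on both sides -> leaflet change is disregarded
        res = residence_series([[U_PC, L_PC, U_PC, L_PC]])
        rec = mc.detect_flipflops(res)
        assert rec.n_events == 0

    def test_domain_change_without_leaflet_change_not_counted(self):
        res = residence_series([[U_PC, U_PS, U_PC, U_PS]])
        rec = mc.detect_flipflops(res)
        assert rec.n_events == 0

    def test_nonuniform_frame_times_rejected(self):
        res = residence_series([[U_PC, L_PS, U_PC]])
        res[2].time = 100.0
        with pytest.raises(MemcurvError):
            mc.detect_flipflops(res)

    def test_debounce_removes_artifact_keeps_genuine(self):
        # molecule oscillates at frame spacing (artifact), then settles in
        # the opposite leaflet much later (genuine transition)
        states = ([U_PC, L_PS, U_PC, L_PS, U_PC] + [U_PC] * 6
                  + [L_PS] + [L_PS] * 4)
        res = residence_series([states])
        rec_raw = mc.detect_flipflops(res)
        assert rec_raw.n_events == 5
        rec = mc.detect_flipflops(res, debounce=4.0)
        assert rec.n_events == 1
        assert rec.events[0][0] == 11 * 4.0

    def test_planted_schedule_recovered_exactly(self):
        spec = mc.sinusoid_spec(5.0, 50.0, seed=41, n_chol=24, noise_sigma=0.0)
        from memcurv.synthetic import _counts
        n_lip = 2 * int(np.prod(_counts(spec)))
        flips = [mc.PlantedFlip(2, n_lip + 3), mc.PlantedFlip(5, n_lip + 3),
                 mc.PlantedFlip(7, n_lip + 11), mc.PlantedFlip(9, n_lip + 20)]
        frames_gt, events = mc.generate_trajectory([spec] * 12, frame_dt=4.0,
                                                   flip_schedule=flips)
        frames = [f for f, _ in frames_gt]
        leaflets = mc.assign_leaflets(frames[0])
        domains = frames_gt[0][1].domain_assignment()
        residences = [mc.assign_cholesterol_residence(f, leaflets, domains)
                      for f in frames]
        rec = mc.detect_flipflops(residences)
        detected = {(m, t) for m, ts in rec.events.items() for t in ts}
        planted = {(int(r.mol_id), float(r.time))
                   for r in events.itertuples() if r.counted}
        assert detected == planted


class TestDebounceHelper:
    def test_chain_collapses(self):
        times = [0.0, 4.0, 8.0, 12.0]
        a, b = ("upper", "DOPC"), ("lower", "DOPS")
        states = [(a, b), (b, a), (a, b), (b, a)]
        assert _debounce_events(times, states, window=4.0) == []

    def test_separated_events_survive(self):
        a, b = ("upper", "DOPC"), ("lower", "DOPS")
        times = [0.0, 100.0]
        states = [(a, b), (b, a)]
        assert _debounce_events(times, states, window=4.0) == times


class TestIntervalHistogram:
    def test_single_bin(self):
        h = mc.interval_histogram(np.full(7, 4.0), bin_width=4.0)
        assert int(np.sum(h.counts > 0)) == 1 and h.counts.max() == 7

    def test_two_bins(self):
        h = mc.interval_histogram(np.array([4.0, 4.0, 8.0]), bin_width=4.0)
        # 4.0 falls in [4, 8): np.histogram puts boundary values in the
        # right-open bin except the last edge
        assert h.counts.tolist() == [0, 2, 1] or h.counts.tolist() == [2, 1]

    def test_empty_record_is_error(self):
        with pytest.raises(MemcurvError):
            mc.interval_histogram(np.array([]), bin_width=4.0)

    def test_exponential_counts_within_poisson_bands(self):
        draws = mc.generate_intervals([(1.0, 100.0)], 10**5, seed=13)
        h = mc.interval_histogram(draws, bin_width=10.0)
        centers = h.bin_centers
        edges = h.bin_edges
        expected = 10**5 * (np.exp(-edges[:-1] / 100.0)
                            - np.exp(-edges[1:] / 100.0))
        big = expected > 25
        dev = np.abs(h.counts[big] - expected[big]) / np.sqrt(expected[big])
        assert dev.max() < 4.0  # ~3 sigma with a margin for many bins
        assert centers[0] == 5.0


class TestFitDoubleExponential:
    def test_exact_model_recovered(self):
        t_edges = np.arange(301) * 2.0
        t_mid = 0.5 * (t_edges[:-1] + t_edges[1:])
        y = 1000 * np.exp(-t_mid / 4.0) + 100 * np.exp(-t_mid / 300.0)
        fit = mc.fit_double_exponential(
            IntervalHistogram(counts=y, bin_edges=t_edges)
        )
        assert fit.A1 == pytest.approx(1000, rel=1e-3)
        assert fit.t1 == pytest.approx(4.0, rel=1e-3)
        assert fit.A2 == pytest.approx(100, rel=1e-3)
        assert fit.t2 == pytest.approx(300.0, rel=1e-3)

    def test_mixture_monte_carlo_recovery(self):
        draws = mc.generate_intervals([(0.8, 4.0), (0.2, 300.0)], 2 * 10**5,
                                      seed=42)
        hist = mc.interval_histogram(draws, bin_width=2.0)
        fit = mc.fit_double_exponential(hist, frame_dt=4.0)
        assert fit.t1 == pytest.approx(4.0, rel=0.10)
        assert fit.t2 == pytest.approx(300.0, rel=0.10)
        assert not fit.prefer_single
        assert fit.t1_is_frame_artifact  # t1 tracks the 4 ns frame spacing

    def test_single_exponential_data_flags_degeneracy(self):
        draws = mc.generate_intervals([(1.0, 100.0)], 5 * 10**4, seed=7)
        hist = mc.interval_histogram(draws, bin_width=10.0)
        fit = mc.fit_double_exponential(hist)
        assert fit.prefer_single
        assert fit.degenerate

    def test_mle_cross_check_agrees(self):
        draws = mc.generate_intervals([(0.8, 4.0), (0.2, 300.0)], 10**5,
                                      seed=9)
        comps = mc.fit_intervals_mle(draws)
        (w1, m1), (w2, m2) = comps
        assert m1 == pytest.approx(4.0, rel=0.05)
        assert m2 == pytest.approx(300.0, rel=0.05)
        assert w1 == pytest.approx(0.8, abs=0.02)

    def test_t2_error_shrinks_with_sample_size(self):
        errs = []
        for n in (10**3, 10**4, 10**5):
            draws = mc.generate_intervals([(0.8, 4.0), (0.2, 300.0)], n,
                                          seed=1000 + n)
            hist = mc.interval_histogram(draws, bin_width=4.0)
            fit = mc.fit_double_exponential(hist)
            errs.append(abs(fit.t2 - 300.0) / 300.0)
        assert errs[2] < errs[0]
        assert errs[2] < 0.1

    def test_invariant_under_bin_halving(self):
        draws = mc.generate_intervals([(0.8, 4.0), (0.2, 300.0)], 10**5,
                                      seed=3)
        f_a = mc.fit_double_exponential(mc.interval_histogram(draws, 4.0))
        f_b = mc.fit_double_exponential(mc.interval_histogram(draws, 2.0))
        tol = 3 * np.hypot(f_a.stderr[3], f_b.stderr[3]) + 0.02 * f_a.t2
        assert abs(f_a.t2 - f_b.t2) < tol

    def test_too_few_bins_is_error(self):
        h = IntervalHistogram(counts=np.array([5.0, 3.0, 1.0]),
                              bin_edges=np.arange(4) * 4.0)
        with pytest.raises(MemcurvError):
            mc.fit_double_exponential(h)
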