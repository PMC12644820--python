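import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from qreplay.reactivation import (
    CorrelationTriplet,
    EphysSession,
    RippleEvent,
    Unit,
    binless_rate,
    classify_reactivated_pairs,
    classify_reward_modulated,
    coactivity,
    detect_ripples,
    epoch_correlations,
    event_triggered_comparison,
    explained_variance,
    pair_contributions,
    read_session_h5,
    reward_modulation_contingency,
    window_means,
    write_session_h5,
)
from qreplay.reactivation.coactivity import window_means
from qreplay.synthetic import EphysGenConfig, generate_ephys_session

FS = 1250.0


def make_lfp(duration, seed, sd=30.0):
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    pink = np.fft.irfft(spec / np.sqrt(freqs), n)
    return pink / pink.std() * sd


def inject_bursts(lfp, times, amp=80.0, freq=150.0, dur=0.12):
    t = np.arange(len(lfp)) / FS
    for peak in times:
        sel = np.abs(t - peak) <= dur
        tt = t[sel] - peak
        lfp[sel] += amp * np.exp(-0.5 * (tt / (dur / 6)) ** 2) * np.cos(2 * np.pi * freq * tt)
    return lfp


class TestDetectRipples:
    def test_subthreshold_noise_no_events(self):
        rng = np.random.default_rng(0)
        lfp = rng.standard_normal(int(30 * FS))  # 1 uV-scale white noise
        events = detect_ripples(lfp, FS)
        assert all(e.amplitude >= 30.0 for e in events)
        # white noise at this scale cannot reach the 30 uV amplitude floor
        assert events == []

    def test_injected_bursts_recovered(self):
        times = np.arange(2.0, 60.0, 3.0)[:20]
        lfp = inject_bursts(make_lfp(64, seed=1), times, amp=80.0)
        events = detect_ripples(lfp, FS)
        hits = 0
        for t0 in times:
            if any(abs(e.peak - t0) <= 0.010 for e in events):
                hits += 1
        assert hits >= 18

    def test_close_bursts_merged(self):
        # two bursts 20 ms apart must come back as a single merged event
        lfp = inject_bursts(make_lfp(20, seed=2), [10.0], amp=80.0, dur=0.06)
        lfp = inject_bursts(lfp, [10.02], amp=80.0, dur=0.06)
        events = [e for e in detect_ripples(lfp, FS) if 9.5 < e.peak < 10.6]
        assert len(events) == 1

    def test_output_invariants(self):
        times = np.arange(2.0, 58.0, 2.5)
        lfp = inject_bursts(make_lfp(60, seed=3), times, amp=80.0)
        events = detect_ripples(lfp, FS)
        assert len(events) > 0
        for e in events:
            assert 0.010 <= e.duration <= 0.500
            assert 30.0 <= e.amplitude <= 1000.0
        gaps = np.diff([e.peak for e in events])
        starts = np.array([e.start for e in events])
        ends = np.array([e.end for e in events])
        assert np.all(starts[1:] - ends[:-1] >= 0.030 - 1e-9)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            detect_ripples(np.zeros(1000), fs=400.0)


class TestBinlessRate:
    def test_empty_train_zero(self):
        _, rate = binless_rate(np.array([]), 0.0, 10.0)
        assert np.all(rate == 0.0)

    def test_single_spike_unimodal_unit_mass(self):
        times, rate = binless_rate(np.array([5.0]), 0.0, 10.0)
        assert rate.sum() * 0.010 == pytest.approx(1.0, abs=1e-6)
        assert times[np.argmax(rate)] == pytest.approx(5.0, abs=0.011)
        # unimodal: increases to the peak then decreases
        peak = np.argmax(rate)
        assert np.all(np.diff(rate[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(rate[peak:]) <= 1e-12)

    def test_integral_matches_count(self):
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(1.0, 599.0, size=6000))
        _, rate = binless_rate(spikes, 0.0, 600.0)
        assert rate.sum() * 0.010 == pytest.approx(len(spikes), rel=0.01)

    def test_homogeneous_poisson_rate(self):
        rng = np.random.default_rng(5)
        duration, hz = 600.0, 10.0
        n = rng.poisson(hz * duration)
        spikes = np.sort(rng.uniform(0, duration, size=n))
        _, rate = binless_rate(spikes, 0.0, duration)
        se = np.sqrt(hz / duration)
        assert abs(rate.mean() - hz) < 3 * se

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            binless_rate(np.array([2.0, 1.0]), 0.0, 5.0)


class TestClassifyRewardModulated:
    @staticmethod
    def poisson_unit(rate_fn, duration, seed):
        rng = np.random.default_rng(seed)
        dt = 0.002
        t = np.arange(0, duration, dt)
        lam = rate_fn(t) * dt
        counts = rng.poisson(lam)
        return np.repeat(t, counts) + rng.uniform(0, dt, size=counts.sum())[: counts.sum()]

    def test_step_response_detected(self):
        arrivals = 20.0 + 20.0 * np.arange(60)
        def rate(t):
            r = np.full_like(t, 5.0)
            for a in arrivals:
                r[(t > a) & (t <= a + 0.5)] = 15.0
            return r
        spikes = np.sort(self.poisson_unit(rate, 1240.0, seed=6))
        modulated, info = classify_reward_modulated(spikes, arrivals)
        assert modulated

    def test_null_false_positive_rate_stable(self):
        arrivals = 20.0 + 20.0 * np.arange(40)
        rates = []
        for block in range(2):
            flags = []
            for u in range(25):
                rng_seed = 1000 * block + u
                spikes = np.sort(self.poisson_unit(lambda t: np.full_like(t, 8.0), 820.0, rng_seed))
                flag, _ = classify_reward_modulated(spikes, arrivals)
                flags.append(flag)
            rates.append(np.mean(flags))
        # compound false-positive level is small and seed-stable
        assert max(rates) < 0.35
        assert abs(rates[0] - rates[1]) <= 0.25

    def test_silent_unit_not_modulated(self):
        arrivals = 20.0 + 20.0 * np.arange(15)
        modulated, _ = classify_reward_modulated(np.array([]), arrivals)
        assert not modulated

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError, match="at least"):
            classify_reward_modulated(np.array([1.0]), [10.0, 20.0])


class TestContingency:
    def test_symmetric_counts_no_effect(self):
        out = reward_modulation_contingency(10, 100, 10, 100)
        assert out["chi2"] == pytest.approx(0.0)
        assert out["pct_reactivated"] == pytest.approx(out["pct_other"])

    def test_paper_counts(self):
        out = reward_modulation_contingency(52, 163, 50, 360)
        assert out["chi2"] == pytest.approx(23.1889, abs=1e-3)
        assert out["dof"] == 1


class TestExplainedVariance:
    @staticmethod
    def triplet(r_tp, r_tq, r_pq):
        t = CorrelationTriplet.__new__(CorrelationTriplet)
        t.pairs = []
        t.r_task_post, t.r_task_pre, t.r_post_pre = r_tp, r_tq, r_pq
        return t

    def test_no_pre_correlation_reduces_to_r2(self):
        ev, rev = explained_variance(self.triplet(0.5, 0.0, 0.0))
        assert ev == pytest.approx(0.25)

    def test_derived_value(self):
        ev, rev = explained_variance(self.triplet(0.5, 0.3, 0.2))
        assert ev == pytest.approx(0.22161172, abs=1e-6)
        # REV by exchanging PRE and POST, derived independently
        rev_expected = ((0.3 - 0.5 * 0.2) / np.sqrt((1 - 0.25) * (1 - 0.04))) ** 2
        assert rev == pytest.approx(rev_expected, abs=1e-12)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            explained_variance(self.triplet(0.5, 1.0, 0.2))

    def test_exchangeable_epochs_symmetric(self, rng):
        # PRE and POST drawn from the same distribution: EV ~ REV on average
        diffs = []
        for _ in range(200):
            task = rng.standard_normal(50)
            pre = 0.5 * task + rng.standard_normal(50)
            post = 0.5 * task + rng.standard_normal(50)
            ev, rev = explained_variance(
                self.triplet(np.corrcoef(task, post)[0, 1],
                             np.corrcoef(task, pre)[0, 1],
                             np.corrcoef(post, pre)[0, 1])
            )
            diffs.append(ev - rev)
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs))


def make_tiny_session(seed=0, n=5):
    """Deterministic-ish session with n CA1 + n vStr Poisson units."""
    rng = np.random.default_rng(seed)
    duration = 90.0
    units = []
    for region, prefix in (("CA1", "c"), ("vStr", "s")):
        for i in range(n):
            nsp = rng.poisson(8.0 * duration)
            units.append(Unit(f"{prefix}{i}", region, np.sort(rng.uniform(0, duration, nsp))))
    lfp = make_lfp(duration, seed)
    epochs = {"pre": (0.0, 30.0), "task": (30.0, 60.0), "post": (60.0, 90.0)}
    return EphysSession(units=units, lfp=lfp, fs=FS, epochs=epochs)


def fake_ripples(times):
    return [RippleEvent(t - 0.05, t, t + 0.05, 100.0) for t in times]


class TestEpochCorrelations:
    def test_cross_region_pair_count(self):
        sess = make_tiny_session()
        trip = epoch_correlations(
            sess, fake_ripples([5, 10, 15, 20, 25]), fake_ripples([65, 70, 75, 80, 85])
        )
        assert len(trip.pairs) == 25

    def test_independent_units_near_zero(self):
        sess = make_tiny_session(seed=3, n=8)
        trip = epoch_correlations(
            sess, fake_ripples(np.arange(2, 29, 2)), fake_ripples(np.arange(62, 89, 2))
        )
        assert abs(np.mean(trip.corr_task)) < 0.1

    def test_ineligible_session_rejected(self):
        sess = make_tiny_session(n=5)
        sess.units = sess.units[:8]
        with pytest.raises(ValueError, match="5"):
            epoch_correlations(sess, fake_ripples([5]), fake_ripples([65]))

    def test_needs_ripples(self):
        sess = make_tiny_session()
        with pytest.raises(ValueError, match="ripple"):
            epoch_correlations(sess, [], fake_ripples([65]))

    def test_identical_units_full_correlation(self):
        sess = make_tiny_session()
        # duplicate one CA1 unit's spikes into a vStr unit: r = 1 everywhere
        sess.units[5] = Unit("s0", "vStr", sess.units[0].spikes.copy())
        trip = epoch_correlations(
            sess, fake_ripples([5, 10, 15, 20, 25]), fake_ripples([65, 70, 75, 80, 85])
        )
        k = trip.pairs.index(("c0", "s0"))
        assert trip.corr_task[k] == pytest.approx(1.0)


class TestPairContributions:
    @staticmethod
    def triplet_from_vectors(pre, task, post):
        return CorrelationTriplet(
            pairs=[(f"a{i}", f"b{i}") for i in range(len(pre))],
            corr_pre=np.asarray(pre, dtype=float),
            corr_task=np.asarray(task, dtype=float),
            corr_post=np.asarray(post, dtype=float),
        )

    def test_symmetric_pairs_equal_contributions(self, rng):
        task = rng.standard_normal(40)
        pre = rng.standard_normal(40) * 0.1
        post = 0.8 * task + 0.1 * rng.standard_normal(40)
        trip = self.triplet_from_vectors(pre, task, post)
        contrib = pair_contributions(trip)
        # statistically exchangeable pairs: spread of contributions is small
        assert np.nanstd(contrib) < 0.05

    def test_engineered_pair_dominates(self, rng):
        n = 30
        task = rng.standard_normal(n) * 0.2
        pre = rng.standard_normal(n) * 0.2
        post = rng.standard_normal(n) * 0.2
        task[0] = post[0] = 3.0  # one strong carry-over pair
        trip = self.triplet_from_vectors(pre, task, post)
        contrib = pair_contributions(trip)
        assert np.nanargmax(contrib) == 0

    def test_null_contributions_center_on_zero(self, rng):
        n = 60
        trip = self.triplet_from_vectors(
            rng.standard_normal(n), rng.standard_normal(n), rng.standard_normal(n)
        )
        contrib = pair_contributions(trip)
        assert abs(np.nanmean(contrib)) < 0.05

    def test_too_few_pairs(self):
        trip = self.triplet_from_vectors([0.1, 0.2], [0.1, 0.2], [0.1, 0.2])
        with pytest.raises(ValueError):
            pair_contributions(trip)


class TestClassifyReactivatedPairs:
    def test_exact_decile_count(self, rng):
        contrib = rng.standard_normal(20)
        pre = np.zeros(20)
        post = np.ones(20)  # every pair increased PRE -> POST
        labels = classify_reactivated_pairs(contrib, pre, post)
        assert labels.count("reactivated") == 2
        assert labels.count("control") == 2

    def test_decreasing_pair_filtered(self, rng):
        contrib = np.linspace(0, 1, 20)
        pre = np.zeros(20)
        post = np.ones(20)
        post[19] = -1.0  # top contributor whose correlation fell
        labels = classify_reactivated_pairs(contrib, pre, post)
        assert labels[19] == "neither"
        assert labels[18] == "reactivated"

    def test_disjoint_groups(self, rng):
        contrib = rng.standard_normal(50)
        labels = classify_reactivated_pairs(contrib, np.zeros(50), np.ones(50))
        assert not {i for i, l in enumerate(labels) if l == "reactivated"} & {
            i for i, l in enumerate(labels) if l == "control"
        }

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            classify_reactivated_pairs(np.ones(5), np.zeros(5), np.ones(5))


class TestCoactivity:
    def test_identical_traces(self):
        r = np.abs(np.sin(np.linspace(0, 10, 500))) + 0.1
        z = coactivity(r, r)
        expected = (r - r.mean()) / r.std()
        assert np.allclose(z, expected)

    def test_silent_cell_zero_raw(self):
        r = np.abs(np.sin(np.linspace(0, 10, 500))) + 0.1
        with pytest.raises(ValueError, match="zero-variance"):
            coactivity(r, np.zeros_like(r))

    def test_symmetry(self, rng):
        a, b = rng.random(300), rng.random(300)
        assert np.array_equal(coactivity(a, b), coactivity(b, a))

    def test_window_means_zero_length_raises(self):
        with pytest.raises(ValueError, match="positive length"):
            window_means(np.ones(100), np.linspace(0, 10, 100), [5.0], (1.0, 1.0))


class TestEventTriggeredComparison:
    @staticmethod
    def build_pair_means(rng, effect=0.0, n_pairs=40):
        rows = []
        for i in range(n_pairs):
            group = "reactivated" if i < n_pairs // 2 else "control"
            for trial_type in ("high", "medium"):
                value = rng.standard_normal() * 0.5
                if group == "reactivated" and trial_type == "high":
                    value += effect
                rows.append({"pair": f"p{i}", "group": group, "trial_type": trial_type,
                             "value": value})
        return pd.DataFrame(rows)

    def test_null_no_interaction(self, rng):
        df = self.build_pair_means(rng, effect=0.0)
        out = event_triggered_comparison(df, n_permutations=500, seed=1)
        assert out["p_interaction"] > 0.05

    def test_built_in_interaction_detected(self, rng):
        df = self.build_pair_means(rng, effect=1.5, n_pairs=60)
        out = event_triggered_comparison(df, n_permutations=500, seed=1)
        assert out["p_interaction"] < 0.05
        assert out["interaction_statistic"] > 0

    def test_requires_two_trial_types(self, rng):
        df = self.build_pair_means(rng)
        df = df[df["trial_type"] == "high"]
        with pytest.raises(ValueError, match="trial types"):
            event_triggered_comparison(df)


class TestSessionIO:
    def test_h5_round_trip(self, tmp_path):
        cfg = EphysGenConfig(n_ca1=5, n_str=5, n_reactivated_pairs=3, pre_duration=40,
                             task_duration=60, post_duration=40)
        sess, _ = generate_ephys_session(cfg, seed=11)
        path = tmp_path / "sess.h5"
        write_session_h5(sess, path)
        back = read_session_h5(path)
        assert len(back.units) == len(sess.units)
        for a, b in zip(sorted(sess.units, key=lambda u: u.unit_id),
                        sorted(back.units, key=lambda u: u.unit_id)):
            assert a.unit_id == b.unit_id and a.region == b.region
            assert np.array_equal(a.spikes, b.spikes)
        assert np.array_equal(back.lfp, sess.lfp)
        assert back.fs == sess.fs
        assert back.epochs == {k: tuple(v) for k, v in sess.epochs.items()}
        assert len(back.events) == len(sess.events)

    def test_epoch_order_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            EphysSession(units=[], lfp=np.zeros(10), fs=FS,
                         epochs={"pre": (0, 10), "task": (5, 15), "post": (20, 30)})
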