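import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nirsync as ns
from nirsync.core_io import Condition, ValidationError
from nirsync.isc_stats import (
    FISHER_CLIP_DEFAULT,
    FreqCohort,
    fisher_z,
    loo_isc_stack,
    one_sample_t,
    scramble_stack,
    stack_cohort,
)
from nirsync.synthetic_data import band_limited_noise

FS = 3.9063
INTACT = Condition("task", "Intact")
SCRAMBLED = Condition("task", "Scrambled")


def _hb_cohort(rng, n_p=5, n_c=4, n_t=300, shared=0.0):
    s = rng.standard_normal((n_c, n_t))
    out = []
    for _ in range(n_p):
        hbo = shared * s + rng.standard_normal((n_c, n_t))
        hbr = -0.6 * (shared * s) + rng.standard_normal((n_c, n_t))
        out.append(ns.HemoglobinSeries(hbo, hbr, FS, [f"C{i}" for i in range(n_c)]))
    return out


class TestLooISC:
    def test_perfect_synchrony_hits_fisher_ceiling(self, rng):
        base = rng.standard_normal((3, 100))
        cohort = [
            ns.HemoglobinSeries(base, -base, FS, ["a", "b", "c"]) for _ in range(4)
        ]
        isc = ns.loo_isc(cohort, INTACT)
        # HbO correlates +1, HbR correlates +1 (identical series across
        # participants), both z at the clip ceiling
        ceiling = np.arctanh(FISHER_CLIP_DEFAULT)
        np.testing.assert_allclose(isc.values, ceiling, rtol=1e-12)

    def test_white_noise_cohort_near_zero(self, rng):
        cohort = _hb_cohort(rng, n_p=8, n_c=5, n_t=500)
        isc = ns.loo_isc(cohort, INTACT)
        assert np.abs(isc.values).mean() < 0.1

    def test_one_value_per_long_channel(self, rng):
        # the full-montage case: 121 long channels -> 121 ISCs per participant
        cohort = _hb_cohort(rng, n_p=3, n_c=121, n_t=64)
        isc = ns.loo_isc(cohort, INTACT)
        assert isc.values.shape == (3, 121)

    def test_unequal_lengths_truncated(self, rng):
        cohort = _hb_cohort(rng, n_p=3, n_c=2, n_t=200)
        short = ns.HemoglobinSeries(
            cohort[0].hbo[:, :150], cohort[0].hbr[:, :150], FS, ["C0", "C1"]
        )
        isc = ns.loo_isc([short] + cohort[1:], INTACT)
        assert isc.values.shape == (3, 2)

    def test_fewer_than_three_participants_rejected(self, rng):
        with pytest.raises(ValidationError):
            ns.loo_isc(_hb_cohort(rng, n_p=2), INTACT)

    def test_zero_variance_series_recorded_as_zero(self, rng):
        cohort = _hb_cohort(rng, n_p=3, n_c=2, n_t=100)
        cohort[0].hbo[0] = 5.0  # constant channel
        with pytest.warns(UserWarning):
            isc = ns.loo_isc(cohort, INTACT)
        assert np.isfinite(isc.values).all()

    def test_chromophore_average_commutes_with_reordering(self, rng):
        cohort = _hb_cohort(rng, n_p=4, n_c=3, n_t=200)
        isc = ns.loo_isc(cohort, INTACT, participants=list("abcd"))
        perm = [2, 0, 3, 1]
        isc_p = ns.loo_isc(
            [cohort[i] for i in perm], INTACT,
            participants=[list("abcd")[i] for i in perm],
        )
        np.testing.assert_allclose(isc_p.values, isc.values[perm], atol=1e-12)


class TestFisher:
    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_strictly_monotone(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert fisher_z(np.array(lo)) < fisher_z(np.array(hi))

    def test_clip_keeps_values_finite(self):
        assert np.isfinite(fisher_z(np.array([1.0, -1.0]))).all()


class TestPhaseScramble:
    def _series(self, rng, n_t=257):
        hbo = np.stack([band_limited_noise(n_t, FS, rng) for _ in range(3)])
        return ns.HemoglobinSeries(hbo, -0.6 * hbo + 0.1 *
                                   rng.standard_normal((3, n_t)), FS,
                                   ["a", "b", "c"])

    @pytest.mark.parametrize("n_t", [256, 257])  # even and odd lengths
    def test_amplitude_spectrum_variance_and_coupling_preserved(self, rng, n_t):
        hb = self._series(rng, n_t)
        out = ns.phase_scramble(hb, seed=5)
        for a, b in ((hb.hbo, out.hbo), (hb.hbr, out.hbr)):
            np.testing.assert_allclose(
                np.abs(np.fft.rfft(a, axis=1)), np.abs(np.fft.rfft(b, axis=1)),
                atol=1e-9,
            )
            np.testing.assert_allclose(a.var(axis=1), b.var(axis=1), rtol=1e-6)
        # shared rotation preserves the zero-lag HbO-HbR correlation
        for c in range(3):
            r_in = np.corrcoef(hb.hbo[c], hb.hbr[c])[0, 1]
            r_out = np.corrcoef(out.hbo[c], out.hbr[c])[0, 1]
            assert r_out == pytest.approx(r_in, abs=1e-6)

    def test_too_short_series_rejected(self):
        hb = ns.HemoglobinSeries(np.ones((1, 3)), np.ones((1, 3)), FS, ["a"])
        with pytest.raises(ValidationError):
            ns.phase_scramble(hb, seed=0)


class TestFreqEngineEquivalence:
    """The frequency-domain surrogate engine must replicate the explicit
    scramble-then-correlate path exactly (same rng draws)."""

    def test_observed_surrogate_and_dropone_paths_agree(self, rng):
        hbo = rng.standard_normal((6, 4, 201))
        hbr = rng.standard_normal((6, 4, 201))
        eng = FreqCohort(hbo, hbr)
        np.testing.assert_allclose(eng.loo_z(), loo_isc_stack(hbo, hbr), atol=1e-12)
        r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
        so, sr = scramble_stack(hbo, hbr, r1)
        rot = eng.draw_rotation(r2, 6, 4)
        np.testing.assert_allclose(
            eng.loo_z(rot), loo_isc_stack(so, sr), atol=1e-12
        )
        Z = eng.loo_z_drop_one()
        for p in range(6):
            keep = [q for q in range(6) if q != p]
            np.testing.assert_allclose(
                Z[p][keep], loo_isc_stack(hbo[keep], hbr[keep]), atol=1e-12
            )


def brute_force_max_t(observed, surrogates, alpha):
    """Independent oracle: explicit loops over surrogates and channels."""
    n_p, n_c = observed.shape

    def t_of(col):
        m = np.mean(col)
        s = np.std(col, ddof=1)
        return m / (s / np.sqrt(len(col)))

    t_obs = [t_of(observed[:, c]) for c in range(n_c)]
    maxima = []
    for sv in surrogates:
        maxima.append(max(t_of(sv[:, c]) for c in range(n_c)))
    p = [sum(m >= t for m in maxima) / len(maxima) for t in t_obs]
    return np.array(t_obs), np.array(p), [pv < alpha for pv in p]


class TestGroupSignificance:
    def _inputs(self, rng, n_p=4, n_c=3, n_b=50):
        obs = rng.standard_normal((n_p, n_c)) + np.array([1.5, 0.0, 0.2])
        surr = [rng.standard_normal((n_p, n_c)) for _ in range(n_b)]
        return obs, surr

    def test_agrees_with_brute_force_oracle(self, rng):
        obs, surr = self._inputs(rng)
        isc = ns.ISCMatrix(obs, INTACT, ["a", "b", "c", "d"], ["c1", "c2", "c3"])
        surr_m = [
            ns.ISCMatrix(s, INTACT, ["a", "b", "c", "d"], ["c1", "c2", "c3"])
            for s in surr
        ]
        stats = ns.group_significance(isc, surr_m, alpha=0.05)
        t_o, p_o, sig_o = brute_force_max_t(obs, surr, 0.05)
        np.testing.assert_allclose(stats.t, t_o, atol=1e-12)
        np.testing.assert_allclose(stats.p_corrected, p_o, atol=1e-12)
        assert list(stats.significant) == sig_o
        assert stats.dof == 3

    def test_corrected_p_monotone_in_t(self, rng):
        obs, surr = self._inputs(rng, n_c=3)
        isc = ns.ISCMatrix(obs, INTACT, list("abcd"), ["c1", "c2", "c3"])
        surr_m = [ns.ISCMatrix(s, INTACT, list("abcd"), ["c1", "c2", "c3"])
                  for s in surr]
        stats = ns.group_significance(isc, surr_m)
        order = np.argsort(stats.t)
        assert np.all(np.diff(stats.p_corrected[order]) <= 1e-12)

    def test_null_calibration_super_uniform(self):
        # feeding phase-scrambled data as "observed" must not over-reject
        rejected = 0
        reps = 30
        for seed in range(reps):
            r = np.random.default_rng(seed)
            cohort = _hb_cohort(r, n_p=6, n_c=8, n_t=128)
            _, stats = ns.group_analysis(
                cohort, INTACT, n_surrogates=100, alpha=0.05, rng=r
            )
            rejected += stats.significant.any()
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rejected / reps <= 0.05 + 3 * se

    def test_power_on_strong_signal_channels(self):
        hits, fps = [], []
        for seed in range(10):
            r = np.random.default_rng(1000 + seed)
            s = r.standard_normal((5, 400))
            cohort = []
            for _ in range(8):
                hbo = np.vstack([s + 0.3 * r.standard_normal((5, 400)),
                                 r.standard_normal((15, 400))])
                hbr = np.vstack([-0.6 * s + 0.3 * r.standard_normal((5, 400)),
                                 r.standard_normal((15, 400))])
                cohort.append(ns.HemoglobinSeries(
                    hbo, hbr, FS, [f"C{i}" for i in range(20)]))
            _, stats = ns.group_analysis(
                cohort, INTACT, n_surrogates=100, alpha=0.05, rng=r
            )
            hits.append(stats.significant[:5].all())
            fps.append(stats.significant[5:].any())
        assert np.mean(hits) >= 0.9
        assert np.mean(fps) <= 0.2


class TestConditionContrast:
    def test_identical_matrices_yield_nothing(self, rng):
        vals = rng.standard_normal((5, 3))
        a = ns.ISCMatrix(vals, INTACT, list("abcde"), ["c1", "c2", "c3"])
        b = ns.ISCMatrix(vals.copy(), SCRAMBLED, list("abcde"), ["c1", "c2", "c3"])
        pairs = [
            (ns.ISCMatrix(rng.standard_normal((5, 3)), INTACT, list("abcde"),
                          ["c1", "c2", "c3"]),
             ns.ISCMatrix(rng.standard_normal((5, 3)), SCRAMBLED, list("abcde"),
                          ["c1", "c2", "c3"]))
            for _ in range(20)
        ]
        stats = ns.condition_contrast(a, b, pairs)
        np.testing.assert_allclose(stats.t, 0.0, atol=1e-12)
        assert not stats.significant.any()
        assert stats.dof == 4

    def test_mismatched_orders_rejected(self, rng):
        a = ns.ISCMatrix(rng.standard_normal((4, 2)), INTACT, list("abcd"), ["x", "y"])
        b = ns.ISCMatrix(rng.standard_normal((4, 2)), SCRAMBLED, list("dcba"), ["x", "y"])
        with pytest.raises(ValidationError):
            ns.condition_contrast(a, b, [])


class TestLooMasks:
    def _cohorts(self, seed, n_p=5, perturb=None):
        r = np.random.default_rng(seed)
        s = r.standard_normal((2, 300))
        intact, scrambled = [], []
        for i in range(n_p):
            hbo = np.vstack([s + 0.4 * r.standard_normal((2, 300)),
                             r.standard_normal((2, 300))])
            intact.append(ns.HemoglobinSeries(
                hbo, -0.6 * hbo + 0.3 * r.standard_normal((4, 300)), FS,
                ["a", "b", "c", "d"]))
            hbo_s = r.standard_normal((4, 300))
            scrambled.append(ns.HemoglobinSeries(
                hbo_s, -0.6 * hbo_s + 0.3 * r.standard_normal((4, 300)), FS,
                ["a", "b", "c", "d"]))
        if perturb is not None:
            rp = np.random.default_rng(999)
            intact[perturb] = ns.HemoglobinSeries(
                rp.standard_normal((4, 300)), rp.standard_normal((4, 300)),
                FS, ["a", "b", "c", "d"])
        return {INTACT: intact, SCRAMBLED: scrambled}

    def test_one_mask_per_participant_per_contrast(self):
        masks = ns.build_loo_masks(
            self._cohorts(0), ["task"], rng=1, n_surrogates=60
        )
        assert set(masks) == {
            "task_Intact", "task_Scrambled", "task_Intact>Scrambled"
        }
        for v in masks.values():
            assert len(v) == 5
            assert [m.left_out_participant for m in v] == [
                f"P{i + 1:02d}" for i in range(5)
            ]

    def test_left_out_mask_independent_of_own_data(self):
        base = ns.build_loo_masks(self._cohorts(0), ["task"], rng=7, n_surrogates=60)
        pert = ns.build_loo_masks(
            self._cohorts(0, perturb=2), ["task"], rng=7, n_surrogates=60
        )
        for name in base:
            assert base[name][2].channels == pert[name][2].channels

    def test_fewer_than_four_participants_rejected(self):
        with pytest.raises(ValidationError):
            ns.build_loo_masks(self._cohorts(0, n_p=3), ["task"], rng=0,
                               n_surrogates=10)


def test_one_sample_t_matches_scipy(rng):
    from scipy import stats as sstats

    x = rng.standard_normal((7, 4)) + 0.5
    got = one_sample_t(x)
    want = sstats.ttest_1samp(x, 0.0, axis=0).statistic
    np.testing.assert_allclose(got, want, atol=1e-10)
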