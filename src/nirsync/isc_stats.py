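"""Inter-subject correlation and surrogate-based group inference.

ISC is computed leave-one-out: each participant's hemoglobin series is
correlated, channel by channel, with the average series of all remaining
participants; correlations are Fisher-transformed and the HbO and HbR values
averaged into one z per (participant, channel).

Group inference uses phase-scrambled surrogates: each surrogate cohort keeps
every amplitude spectrum (hence autocorrelation) but randomizes Fourier
phases, destroying stimulus alignment.  A one-tailed one-sample t is
computed per channel; the maximum t across channels is recorded per
surrogate, and each observed channel t is compared against that null of
maxima (max-statistic family-wise correction).  Intact > Scrambled
contrasts apply the identical machinery to per-participant ISC differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, Condition, ValidationError
from .preprocess import HemoglobinSeries

__all__ = [
    "ISCMatrix",
    "ChannelStats",
    "Mask",
    "fisher_z",
    "loo_isc",
    "phase_scramble",
    "group_significance",
    "condition_contrast",
    "group_analysis",
    "contrast_analysis",
    "build_loo_masks",
    "stack_cohort",
    "FreqCohort",
    "loo_isc_stack",
    "scramble_stack",
    "one_sample_t",
]

FISHER_CLIP_DEFAULT = 1.0 - 1e-7


@dataclass
class ISCMatrix:
    """Fisher-z ISCs, participants x channels (HbO/HbR averaged)."""

    values: np.ndarray
    condition: Condition
    participants: list[str]
    channels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participants), len(self.channels)):
            raise ValidationError("ISC matrix shape must be participants x channels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ISC matrix contains non-finite values")

    def row(self, participant: str) -> np.ndarray:
        return self.values[self.participants.index(participant)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"participant": p, "channel": c, "isc_z": self.values[i, j]}
            for i, p in enumerate(self.participants)
            for j, c in enumerate(self.channels)
        ]
        return pd.DataFrame(rows)


@dataclass
class ChannelStats:
    """Per-channel group statistics with a max-statistic null."""

    t: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray
    dof: int
    null_max: np.ndarray
    contrast: str
    channels: list[str]

    def significant_channels(self) -> list[str]:
        return [c for c, s in zip(self.channels, self.significant) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channels,
                "t": self.t,
                "p_corrected": self.p_corrected,
                "significant": self.significant,
            }
        )


@dataclass
class Mask:
    """Significant-channel subset for one contrast in one LOO dataset."""

    contrast: str
    left_out_participant: str
    channels: list[str]

    def __len__(self) -> int:
        return len(self.channels)


# --------------------------------------------------------------------------
# Stacked-array kernels (vectorized across participants and channels)
# --------------------------------------------------------------------------


def stack_cohort(cohort_hb: Sequence[HemoglobinSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into (P, C, T) arrays, truncated to the common length."""
    if len(cohort_hb) < 2:
        raise ValidationError("need at least 2 participants")
    n_t = min(h.n_samples for h in cohort_hb)
    ref = cohort_hb[0].channel_ids
    for h in cohort_hb[1:]:
        if h.channel_ids != ref:
            raise ValidationError("cohort members disagree on channel set/order")
    hbo = np.stack([h.hbo[:, :n_t] for h in cohort_hb])
    hbr = np.stack([h.hbr[:, :n_t] for h in cohort_hb])
    return hbo, hbr


def _corr_lastaxis(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along the last axis; zero-variance pairs -> 0."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    num = np.sum(a * b, axis=-1)
    den = np.sqrt(np.sum(a * a, axis=-1) * np.sum(b * b, axis=-1))
    bad = den == 0
    if np.any(bad):
        warnings.warn("zero-variance series encountered; ISC recorded as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    return r


def fisher_z(r: np.ndarray, clip: float = FISHER_CLIP_DEFAULT) -> np.ndarray:
    """atanh with |r| clipped just below 1, keeping perfect correlations finite."""
    return np.arctanh(np.clip(r, -clip, clip))


def loo_isc_stack(
    hbo: np.ndarray, hbr: np.ndarray, clip: float = FISHER_CLIP_DEFAULT
) -> np.ndarray:
    """Leave-one-out Fisher-z ISC from stacked (P, C, T) arrays."""
    n_p = hbo.shape[0]
    out = np.empty(hbo.shape[:2])
    for arr, weight in ((hbo, 0.5), (hbr, 0.5)):
        mean_others = (arr.sum(axis=0, keepdims=True) - arr) / (n_p - 1)
        r = _corr_lastaxis(arr, mean_others)
        z = fisher_z(r, clip)
        if arr is hbo:
            out = weight * z
        else:
            out = out + weight * z
    return out


def scramble_stack(
    hbo: np.ndarray, hbr: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-scramble stacked series; one phase draw per (participant, channel).

    DC and (for even lengths) Nyquist bins are untouched; the same rotation
    is applied to HbO and HbR of a channel, preserving their cross-spectrum
    and hence the expected HbO-HbR anticorrelation.
    """
    n_t = hbo.shape[-1]
    fo = np.fft.rfft(hbo, axis=-1)
    fr = np.fft.rfft(hbr, axis=-1)
    n_f = fo.shape[-1]
    lo = 1
    hi = n_f - 1 if n_t % 2 == 0 else n_f
    phase = rng.uniform(0.0, 2.0 * np.pi, size=hbo.shape[:-1] + (hi - lo,))
    rot = np.exp(1j * phase)
    fo[..., lo:hi] *= rot
    fr[..., lo:hi] *= rot
    return np.fft.irfft(fo, n=n_t, axis=-1), np.fft.irfft(fr, n=n_t, axis=-1)


class FreqCohort:
    """Frequency-domain representation of a stacked cohort.

    Phase scrambling preserves every amplitude spectrum, so surrogate ISCs
    can be computed entirely in the frequency domain: Pearson sums become
    weighted Parseval sums over rFFT bins, with centering realized by
    zeroing the DC bin.  This avoids the inverse transforms of the naive
    scramble-then-correlate path and is exactly equivalent to it (same
    phase draws, same statistic) up to floating-point error.
    """

    def __init__(self, hbo: np.ndarray, hbr: np.ndarray):
        self.n_t = hbo.shape[-1]
        self.Xo = np.fft.rfft(hbo, axis=-1)
        self.Xr = np.fft.rfft(hbr, axis=-1)
        self.Xo[..., 0] = 0.0  # centering
        self.Xr[..., 0] = 0.0
        n_f = self.Xo.shape[-1]
        w = np.full(n_f, 2.0)
        w[0] = 1.0
        if self.n_t % 2 == 0:
            w[-1] = 1.0
        self.w = w
        self.lo = 1
        self.hi = n_f - 1 if self.n_t % 2 == 0 else n_f
        # per-series energy is rotation-invariant
        self.Eo = np.einsum("f,pcf->pc", w, self.Xo.real**2 + self.Xo.imag**2)
        self.Er = np.einsum("f,pcf->pc", w, self.Xr.real**2 + self.Xr.imag**2)

    def draw_rotation(
        self, rng: np.random.Generator, n_series: int, n_channels: int
    ) -> np.ndarray:
        """Unit-modulus rotation per (series, channel, free bin); DC/Nyquist fixed.

        Phase draws replicate :func:`scramble_stack` exactly (same rng
        consumption), so both paths produce identical surrogates.
        """
        n_f = self.Xo.shape[-1]
        rot = np.ones((n_series, n_channels, n_f), dtype=complex)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_series, n_channels, self.hi - self.lo))
        rot[..., self.lo:self.hi] = np.exp(1j * phase)
        return rot

    def loo_z(
        self,
        rot: np.ndarray | None = None,
        subset: Sequence[int] | None = None,
        clip: float = FISHER_CLIP_DEFAULT,
    ) -> np.ndarray:
        """Leave-one-out Fisher-z ISC, optionally phase-rotated / on a subset."""
        idx = slice(None) if subset is None else list(subset)
        out = None
        for X, E in ((self.Xo, self.Eo), (self.Xr, self.Er)):
            Xs = X[idx]
            Es = E[idx]
            if rot is not None:
                Xs = Xs * rot
            n_p = Xs.shape[0]
            S = Xs.sum(axis=0)
            cross = np.einsum("f,pcf->pc", self.w, (Xs * S.conj()).real)
            ES = np.einsum("f,cf->c", self.w, S.real**2 + S.imag**2)
            num = cross - Es
            Em = ES[None, :] - 2.0 * cross + Es
            den2 = Es * Em
            bad = den2 <= 0
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(bad, 0.0, num / np.sqrt(np.where(bad, 1.0, den2)))
            z = fisher_z(r, clip)
            out = 0.5 * z if out is None else out + 0.5 * z
        return out


    def loo_z_drop_one(
        self, rot: np.ndarray | None = None, clip: float = FISHER_CLIP_DEFAULT
    ) -> np.ndarray:
        """Leave-one-out z for every drop-one subcohort at once.

        Returns Z of shape (P, P, C): Z[p, q, c] is participant q's ISC
        within the cohort excluding participant p (diagonal = NaN).  Uses
        the pairwise weighted cross-spectral Gram matrix, so all P
        subcohorts cost one batched matmul instead of P separate passes —
        the workhorse behind leave-one-out mask building.
        """
        out = None
        for X, E in ((self.Xo, self.Eo), (self.Xr, self.Er)):
            Xs = X if rot is None else X * rot
            n_p, n_c, n_f = Xs.shape
            Aw = Xs * self.w
            S = Xs.sum(axis=0)
            cross_full = (
                np.einsum("pcf,cf->pc", Aw.real, S.real)
                + np.einsum("pcf,cf->pc", Aw.imag, S.imag)
            )
            ES_full = (self.w * (S.real**2 + S.imag**2)).sum(axis=-1)  # (C,)
            # G[q, p, c] = sum_f w * Re(X_q conj(X_p)) via batched matmul
            Ar = np.ascontiguousarray(Aw.real.transpose(1, 0, 2))  # (C, P, F)
            Ai = np.ascontiguousarray(Aw.imag.transpose(1, 0, 2))
            Br = np.ascontiguousarray(Xs.real.transpose(1, 2, 0))  # (C, F, P)
            Bi = np.ascontiguousarray(Xs.imag.transpose(1, 2, 0))
            G = (Ar @ Br + Ai @ Bi).transpose(1, 2, 0)  # (q, p, c)
            cross = cross_full[:, None, :] - G  # q's cross with sum-minus-p
            num = cross - E[:, None, :]
            ES_p = ES_full[None, :] - 2.0 * cross_full + E  # (p, c)
            Em = ES_p[None, :, :] - 2.0 * cross + E[:, None, :]
            den2 = E[:, None, :] * Em
            bad = den2 <= 0
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(bad, 0.0, num / np.sqrt(np.where(bad, 1.0, den2)))
            z = fisher_z(r, clip)
            out = 0.5 * z if out is None else out + 0.5 * z
        Z = out.transpose(1, 0, 2)  # (p_dropped, q, c)
        idx = np.arange(Z.shape[0])
        Z[idx, idx, :] = np.nan
        return Z


def one_sample_t(values: np.ndarray) -> np.ndarray:
    """One-sample t across participants (axis 0) per channel."""
    n = values.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 participants for a t-test")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


# --------------------------------------------------------------------------
# Public operations
# --------------------------------------------------------------------------


def loo_isc(
    cohort_hb: Sequence[HemoglobinSeries],
    condition: Condition,
    participants: Sequence[str] | None = None,
    clip: float = FISHER_CLIP_DEFAULT,
) -> ISCMatrix:
    """Leave-one-out ISC matrix for one condition.

    For each participant and channel, the Pearson correlation between the
    participant's series and the mean series of all remaining participants
    is Fisher-transformed, separately for HbO and HbR, and the two z values
    averaged.
    """
    if len(cohort_hb) < 3:
        raise ValidationError("leave-one-out ISC needs at least 3 participants")
    hbo, hbr = stack_cohort(cohort_hb)
    values = loo_isc_stack(hbo, hbr, clip)
    if participants is None:
        participants = [f"P{i + 1:02d}" for i in range(len(cohort_hb))]
    return ISCMatrix(
        values=values,
        condition=condition,
        participants=list(participants),
        channels=list(cohort_hb[0].channel_ids),
    )


def phase_scramble(
    hb: HemoglobinSeries, seed: int | np.random.Generator
) -> HemoglobinSeries:
    """Phase-scrambled surrogate of one participant's hemoglobin series."""
    if hb.n_samples < 4:
        raise ValidationError("series too short to phase-scramble")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hbo, hbr = scramble_stack(hb.hbo, hb.hbr, rng)
    return HemoglobinSeries(
        hbo=hbo,
        hbr=hbr,
        fs=hb.fs,
        channel_ids=list(hb.channel_ids),
        provenance=hb.provenance + ["phase_scramble"],
    )


def _max_t_stats(
    observed: np.ndarray,
    surrogate_values: Iterable[np.ndarray],
    alpha: float,
    dof: int,
    contrast: str,
    channels: Sequence[str],
) -> ChannelStats:
    t_obs = one_sample_t(observed)
    null_max = np.array([one_sample_t(sv).max() for sv in surrogate_values])
    if null_max.size == 0:
        raise ValidationError("surrogate list must be nonempty")
    p = (null_max[None, :] >= t_obs[:, None]).mean(axis=1)
    return ChannelStats(
        t=t_obs,
        p_corrected=p,
        significant=p < alpha,
        dof=dof,
        null_max=null_max,
        contrast=contrast,
        channels=list(channels),
    )


def group_significance(
    isc: ISCMatrix, surrogate_iscs: Sequence[ISCMatrix], alpha: float = 0.05
) -> ChannelStats:
    """Max-t corrected one-tailed group test of positive ISC per channel.

    The corrected p of a channel is the fraction of surrogate *maximum*
    t-scores (across channels) at or above the channel's observed t, so a
    single null distribution controls the family-wise error over channels.
    """
    if isc.values.shape[0] < 2:
        raise ValidationError("need at least 2 participants")
    for s in surrogate_iscs:
        if s.values.shape != isc.values.shape:
            raise ValidationError("surrogate ISC matrices must match the observed shape")
    return _max_t_stats(
        isc.values,
        [s.values for s in surrogate_iscs],
        alpha,
        dof=isc.values.shape[0] - 1,
        contrast=isc.condition.label,
        channels=isc.channels,
    )


def condition_contrast(
    isc_intact: ISCMatrix,
    isc_scrambled: ISCMatrix,
    surrogate_pairs: Sequence[tuple[ISCMatrix, ISCMatrix]],
    alpha: float = 0.05,
) -> ChannelStats:
    """Intact > Scrambled contrast with the identical max-t surrogate null."""
    if (
        isc_intact.participants != isc_scrambled.participants
        or isc_intact.channels != isc_scrambled.channels
    ):
        raise ValidationError("contrast requires matched participant and channel order")
    diff = isc_intact.values - isc_scrambled.values
    surr = [a.values - b.values for a, b in surrogate_pairs]
    name = f"{isc_intact.condition.stimulus}_Intact>Scrambled"
    return _max_t_stats(
        diff, surr, alpha, dof=diff.shape[0] - 1, contrast=name,
        channels=isc_intact.channels,
    )


# --------------------------------------------------------------------------
# Surrogate-driven wrappers operating on raw cohorts
# --------------------------------------------------------------------------


def group_analysis(
    cohort_hb: Sequence[HemoglobinSeries],
    condition: Condition,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    participants: Sequence[str] | None = None,
) -> tuple[ISCMatrix, ChannelStats]:
    """Observed ISC matrix plus max-t group statistics for one condition."""
    rng = np.random.default_rng(rng)
    isc = loo_isc(cohort_hb, condition, participants)
    hbo, hbr = stack_cohort(cohort_hb)
    eng = FreqCohort(hbo, hbr)
    n_p, n_c = hbo.shape[:2]
    surr = [
        eng.loo_z(eng.draw_rotation(rng, n_p, n_c)) for _ in range(n_surrogates)
    ]
    stats = _max_t_stats(
        isc.values, surr, alpha, dof=len(cohort_hb) - 1,
        contrast=condition.label, channels=isc.channels,
    )
    return isc, stats


def contrast_analysis(
    hb_intact: Sequence[HemoglobinSeries],
    hb_scrambled: Sequence[HemoglobinSeries],
    stimulus: str,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    participants: Sequence[str] | None = None,
) -> ChannelStats:
    """Intact > Scrambled max-t contrast computed from hemoglobin series."""
    from .core_io import INTACT, SCRAMBLED

    rng = np.random.default_rng(rng)
    isc_i = loo_isc(hb_intact, Condition(stimulus, INTACT), participants)
    isc_s = loo_isc(hb_scrambled, Condition(stimulus, SCRAMBLED), participants)
    diff = isc_i.values - isc_s.values
    eng_i = FreqCohort(*stack_cohort(hb_intact))
    eng_s = FreqCohort(*stack_cohort(hb_scrambled))
    n_p, n_c = isc_i.values.shape
    surr = []
    for _ in range(n_surrogates):
        z_i = eng_i.loo_z(eng_i.draw_rotation(rng, n_p, n_c))
        z_s = eng_s.loo_z(eng_s.draw_rotation(rng, n_p, n_c))
        surr.append(z_i - z_s)
    return _max_t_stats(
        diff, surr, alpha, dof=diff.shape[0] - 1,
        contrast=f"{stimulus}_Intact>Scrambled", channels=isc_i.channels,
    )


def build_loo_masks(
    cohort_hb: Mapping[Condition, Sequence[HemoglobinSeries]],
    stimuli: Sequence[str],
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
    participants: Sequence[str] | None = None,
    n_surrogates: int | None = None,
) -> dict[str, list[Mask]]:
    """Leave-one-out masks for every condition and Intact > Scrambled contrast.

    For each left-out participant the full group analysis is recomputed on
    the remaining participants only, so each participant's mask never
    touches their own data.  Returns one mask list (ordered by left-out
    participant) per contrast name.
    """
    from .core_io import INTACT, SCRAMBLED

    cfg = config or AnalysisConfig()
    n_sur = n_surrogates if n_surrogates is not None else cfg.n_surrogates
    rng = np.random.default_rng(rng)
    conditions = list(cohort_hb.keys())
    n_p = len(next(iter(cohort_hb.values())))
    if n_p < 4:
        raise ValidationError("leave-one-out masking needs at least 4 participants")
    if participants is None:
        participants = [f"P{i + 1:02d}" for i in range(n_p)]

    engines = {c: FreqCohort(*stack_cohort(cohort_hb[c])) for c in conditions}
    n_c = next(iter(engines.values())).Xo.shape[1]
    channels = cohort_hb[conditions[0]][0].channel_ids
    masks: dict[str, list[Mask]] = {c.label: [] for c in conditions}
    contrasts = []
    for stim in stimuli:
        ci, cs = Condition(stim, INTACT), Condition(stim, SCRAMBLED)
        if ci in cohort_hb and cs in cohort_hb:
            contrasts.append((stim, ci, cs))
            masks[f"{stim}_Intact>Scrambled"] = []

    def _drop_one_t(Z: np.ndarray) -> np.ndarray:
        """(P, P, C) drop-one z values -> (P, C) t over the remaining rows."""
        n = n_p - 1
        mean = np.nanmean(Z, axis=1)
        sd = np.nanstd(Z, axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)

    obs_Z = {c: engines[c].loo_z_drop_one() for c in conditions}
    obs_t = {c: _drop_one_t(obs_Z[c]) for c in conditions}
    obs_t_contrast = {
        stim: _drop_one_t(obs_Z[ci] - obs_Z[cs]) for stim, ci, cs in contrasts
    }

    # one full-cohort phase draw per surrogate per condition, reused across
    # the P drop-one subcohorts (each subcohort test remains a valid
    # surrogate test; only cross-mask correlation is introduced)
    null_max = {c.label: np.empty((n_sur, n_p)) for c in conditions}
    for stim, *_ in contrasts:
        null_max[f"{stim}_Intact>Scrambled"] = np.empty((n_sur, n_p))
    for b in range(n_sur):
        Zs = {}
        for c in conditions:
            eng = engines[c]
            rot = eng.draw_rotation(rng, n_p, n_c)
            Zs[c] = eng.loo_z_drop_one(rot)
            null_max[c.label][b] = _drop_one_t(Zs[c]).max(axis=1)
        for stim, ci, cs in contrasts:
            null_max[f"{stim}_Intact>Scrambled"][b] = _drop_one_t(
                Zs[ci] - Zs[cs]
            ).max(axis=1)

    def _emit(name: str, t_obs: np.ndarray) -> None:
        for p in range(n_p):
            pvals = (null_max[name][:, p][:, None] >= t_obs[p][None, :]).mean(axis=0)
            sig = [ch for ch, pv in zip(channels, pvals) if pv < cfg.alpha]
            masks[name].append(
                Mask(contrast=name, left_out_participant=participants[p], channels=sig)
            )

    for c in conditions:
        _emit(c.label, obs_t[c])
    for stim, *_ in contrasts:
        _emit(f"{stim}_Intact>Scrambled", obs_t_contrast[stim])
    return masks
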