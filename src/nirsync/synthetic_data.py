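"""Synthetic multi-participant fNIRS cohorts with known ground truth.

The generator emulates the statistical structure a narrative-stimulus ISC
analysis assumes:

* one latent band-limited "narrative" signal per condition, shared across
  participants, present in a designated channel subset (a smaller subset for
  Scrambled conditions, mirroring the temporally-restricted synchrony such
  controls evoke);
* a participant-specific scalp-physiology component common to the short and
  long channels of that participant;
* participant- and channel-specific noise;
* anticorrelated HbR (a negative scaling of the HbO shared and scalp parts);
* a forward optical model mapping concentration changes to raw light
  intensities through the modified Beer-Lambert law, with a ~1.1 Hz cardiac
  oscillation (stronger on short channels) and optional multiplicative
  measurement noise.

Because the forward model uses the same extinction table and DPF equation as
the preprocessing inverse, a noise-free cohort round-trips exactly.
All latent components are realised by filtering white noise with the same
Butterworth band (0.005-0.20 Hz) the analysis uses, so the generated signal
survives the analysis filter unattenuated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .core_io import (
    INTACT,
    SCRAMBLED,
    ChannelDef,
    Condition,
    HOMER_EXTINCTION,
    Montage,
    RawRecording,
    ValidationError,
)
from .preprocess import HemoglobinSeries, compute_dpf

__all__ = [
    "CohortParams",
    "SyntheticCohort",
    "SuspenseRatings",
    "Artifact",
    "default_montage",
    "band_limited_noise",
    "generate_cohort",
    "generate_suspense_ratings",
    "inject_motion_artifacts",
]

#: Stimulus durations (seconds) of the four default narrative conditions.
DEFAULT_DURATIONS: dict[str, float] = {
    "BYD_Intact": 478.0,
    "BYD_Scrambled": 463.0,
    "Taken_Intact": 312.0,
    "Taken_Scrambled": 302.0,
}


@dataclass
class CohortParams:
    """Parameters of one synthetic cohort.

    Defaults mirror the acquisition this pipeline targets: 26 participants,
    121 long (~3 cm) and 8 short (0.8 cm) channels, 3.9063 Hz sampling, two
    narrative stimuli each with an Intact and a Scrambled variant.  The
    shared-signal and noise amplitudes are set so that realised
    signal-channel ISCs fall around 0.2-0.4 — the range single-participant
    ISC maps typically span.
    """

    n_participants: int = 26
    n_long_channels: int = 121
    n_short_channels: int = 8
    fs: float = 3.9063
    duration_s: float | Mapping[str, float] | None = None  # None -> stimulus defaults
    stimuli: tuple[str, ...] = ("BYD", "Taken")
    signal_channels_intact: tuple[str, ...] | None = None  # None -> first 40% of long
    signal_channels_scrambled: tuple[str, ...] | None = None  # None -> first 10% of long
    shared_signal_sd: float = 1.0  # micromolar
    noise_sd: float = 2.0
    scalp_sd: float = 1.0
    hbr_ratio: float = -0.6
    cardiac_amp: float = 0.005  # fractional intensity modulation on long channels
    cardiac_freq: float = 1.1
    measurement_noise: float = 0.0  # sd of multiplicative intensity noise
    motion_rate: float = 0.0  # artifacts per minute
    motion_amplitude: float = 10.0  # in units of channel OD sd
    ages: tuple[float, ...] | None = None  # None -> drawn ~ N(23.3, 3.1) in [19, 31]
    wavelengths: tuple[float, ...] = (760.0, 850.0)

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.n_long_channels < 1:
            raise ValidationError("need >= 2 participants and >= 1 long channel")
        if not -1.0 <= self.hbr_ratio < 0.0:
            raise ValidationError("hbr_ratio must lie in [-1, 0)")
        for name in ("shared_signal_sd", "noise_sd", "scalp_sd", "cardiac_amp",
                     "measurement_noise", "motion_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def conditions(self) -> list[Condition]:
        out = []
        for stim in self.stimuli:
            out.append(Condition(stim, INTACT))
            out.append(Condition(stim, SCRAMBLED))
        return out

    def n_samples(self, condition: Condition) -> int:
        if self.duration_s is None:
            dur = DEFAULT_DURATIONS.get(condition.label, 300.0)
        elif isinstance(self.duration_s, Mapping):
            dur = self.duration_s[condition.label]
        else:
            dur = float(self.duration_s)
        n = int(round(dur * self.fs))
        if n < 64:
            raise ValidationError("duration * fs must be at least 64 samples")
        return n


@dataclass
class Artifact:
    channel: int
    sample: int
    kind: str  # "spike" | "shift"
    magnitude: float  # signed, in OD units


@dataclass
class CohortTruth:
    """Ground truth of one synthetic cohort."""

    latent: dict[str, np.ndarray]  # condition label -> shared signal (sd 1)
    weights: np.ndarray  # per-long-channel mixing weight
    signal_channels: dict[str, list[str]]  # condition label -> channel ids
    hb_clean: dict[tuple[str, str], HemoglobinSeries]  # (participant, label) -> realized hb
    hb_noiseless: dict[tuple[str, str], HemoglobinSeries]  # shared component only
    artifacts: dict[tuple[str, str], list[Artifact]] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    params: CohortParams
    montage: Montage
    recordings: list[RawRecording]
    truth: CohortTruth

    def recording(self, participant_id: str, condition: Condition) -> RawRecording:
        for rec in self.recordings:
            if rec.participant_id == participant_id and rec.condition == condition:
                return rec
        raise KeyError((participant_id, condition))

    def participants(self) -> list[str]:
        seen: list[str] = []
        for rec in self.recordings:
            if rec.participant_id not in seen:
                seen.append(rec.participant_id)
        return seen

    def hemoglobin(self, participant_id: str, condition: Condition) -> HemoglobinSeries:
        """Realized (noisy, pre-optics) long-channel hemoglobin ground truth."""
        return self.truth.hb_clean[(participant_id, condition.label)]


@dataclass
class SuspenseRatings:
    """Subjective suspense sampled on a 1-10 scale every ~2 s."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("rating times must be strictly increasing")
        if self.values.min() < 1.0 - 1e-9 or self.values.max() > 10.0 + 1e-9:
            raise ValidationError("ratings must lie within [1, 10]")


# --------------------------------------------------------------------------
# Building blocks
# --------------------------------------------------------------------------


def noise_sd_for_target_isc(target_isc: float, n_participants: int) -> float:
    """Channel-noise sd giving a requested mean signal-channel ISC.

    For a unit-weight channel with unit shared-signal sd and total nuisance
    variance V (channel noise, after scalp removal), the expected
    leave-one-out correlation is r = 1 / sqrt((1 + V)(1 + V/(n-1))):
    the second factor is the residual noise in the average of the n-1
    remaining participants.  Solving for V gives the noise sd that realises
    ``target_isc`` at a given cohort size.
    """
    if not 0 < target_isc < 1:
        raise ValidationError("target ISC must lie in (0, 1)")
    a = 1.0 / (n_participants - 1)
    c = 1.0 - 1.0 / target_isc**2
    v = (-(1 + a) + np.sqrt((1 + a) ** 2 - 4 * a * c)) / (2 * a)
    return float(np.sqrt(v))


def default_montage(
    n_long: int, n_short: int, wavelengths: Sequence[float] = (760.0, 850.0)
) -> Montage:
    """A synthetic montage: unique-pair long channels at 3 cm, shorts at 0.8 cm."""
    chans = []
    for i in range(n_long):
        chans.append(
            ChannelDef(f"S{i + 1:03d}-D{i + 1:03d}", f"S{i + 1:03d}", f"D{i + 1:03d}",
                       rho=3.0, is_short=False)
        )
    for i in range(n_short):
        chans.append(
            ChannelDef(f"SS{i + 1:02d}-DS{i + 1:02d}", f"SS{i + 1:02d}", f"DS{i + 1:02d}",
                       rho=0.8, is_short=True)
        )
    return Montage(tuple(chans), tuple(wavelengths))


def band_limited_noise(
    n: int, fs: float, rng: np.random.Generator,
    low: float = 0.02, high: float = 0.15, order: int = 3,
) -> np.ndarray:
    """Unit-sd Gaussian process confined to the analysis band.

    White noise filtered with the same zero-phase Butterworth design the
    preprocessing uses, then re-standardized.  The default band sits in the
    interior of the 0.005-0.20 Hz analysis band, where the analysis filter's
    gain is ~1, so generated components pass through preprocessing
    essentially unchanged.
    """
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    if sd == 0:
        return x
    return (x - x.mean()) / sd


def _forward_intensity(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    montage: Montage,
    age: float,
    ch_indices: Sequence[int],
) -> np.ndarray:
    """Map micromolar concentration changes to light intensities (I0 = 1).

    I(t) = exp(-(eps_HbO * dHbO + eps_HbR * dHbR) * DPF * rho) per wavelength,
    the exact inverse of the preprocessing MBLL step.
    """
    wavelengths = montage.wavelengths
    E = HOMER_EXTINCTION.matrix(wavelengths)  # (n_wl, 2)
    dpf = np.array([compute_dpf(age, wl) for wl in wavelengths])
    n_t = hbo_um.shape[1]
    out = np.empty((len(ch_indices), len(wavelengths), n_t))
    conc = np.stack([hbo_um, hbr_um], axis=1) * 1e-6  # (n_ch, 2, n_t), mol/L
    for k, idx in enumerate(ch_indices):
        rho = montage.channels[idx].rho
        od = np.einsum("wj,jt->wt", E, conc[k]) * dpf[:, None] * rho
        out[k] = np.exp(-od)
    return out


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


def generate_cohort(params: CohortParams, seed: int) -> SyntheticCohort:
    """Draw one full synthetic cohort (all participants x all conditions)."""
    rng = np.random.default_rng(seed)
    p = params
    montage = default_montage(p.n_long_channels, p.n_short_channels, p.wavelengths)
    long_ids = [c.channel_id for c in montage.long_channels]
    short_ids = [c.channel_id for c in montage.short_channels]

    sig_intact = list(
        p.signal_channels_intact
        if p.signal_channels_intact is not None
        else long_ids[: max(1, round(0.4 * len(long_ids)))]
    )
    sig_scrambled = list(
        p.signal_channels_scrambled
        if p.signal_channels_scrambled is not None
        else long_ids[: max(1, round(0.1 * len(long_ids)))]
    )
    for cid in sig_intact + sig_scrambled:
        if cid not in long_ids:
            raise ValidationError(f"signal channel {cid!r} not a long channel")

    if p.ages is not None:
        if len(p.ages) != p.n_participants:
            raise ValidationError("ages must list one value per participant")
        ages = np.asarray(p.ages, dtype=float)
    else:
        ages = np.clip(rng.normal(23.3, 3.1, size=p.n_participants), 19.0, 31.0)

    weights = rng.uniform(0.5, 1.5, size=len(long_ids))
    long_pos = {cid: i for i, cid in enumerate(long_ids)}

    conditions = p.conditions()
    latent: dict[str, np.ndarray] = {}
    sig_sets: dict[str, list[str]] = {}
    for cond in conditions:
        n_t = p.n_samples(cond)
        latent[cond.label] = band_limited_noise(n_t, p.fs, rng) * p.shared_signal_sd
        sig_sets[cond.label] = sig_intact if cond.intact else sig_scrambled

    participants = [f"P{i + 1:02d}" for i in range(p.n_participants)]
    recordings: list[RawRecording] = []
    hb_clean: dict[tuple[str, str], HemoglobinSeries] = {}
    hb_noiseless: dict[tuple[str, str], HemoglobinSeries] = {}
    artifacts: dict[tuple[str, str], list[Artifact]] = {}

    n_long = len(long_ids)
    n_short = len(short_ids)
    for pi, pid in enumerate(participants):
        for cond in conditions:
            lab = cond.label
            n_t = latent[lab].size
            s = latent[lab]
            in_set = np.array([cid in sig_sets[lab] for cid in long_ids])
            w = weights * in_set

            scalp = band_limited_noise(n_t, p.fs, rng) * p.scalp_sd
            noise_o = np.stack([band_limited_noise(n_t, p.fs, rng) for _ in range(n_long)])
            noise_r = np.stack([band_limited_noise(n_t, p.fs, rng) for _ in range(n_long)])

            shared = w[:, None] * s[None, :]
            hbo = shared + scalp[None, :] + p.noise_sd * noise_o
            hbr = p.hbr_ratio * (shared + scalp[None, :]) \
                + abs(p.hbr_ratio) * p.noise_sd * noise_r

            hb_clean[(pid, lab)] = HemoglobinSeries(
                hbo=hbo, hbr=hbr, fs=p.fs, channel_ids=list(long_ids)
            )
            hb_noiseless[(pid, lab)] = HemoglobinSeries(
                hbo=shared, hbr=p.hbr_ratio * shared, fs=p.fs, channel_ids=list(long_ids)
            )

            # short channels: scalp physiology only, plus light channel noise
            if n_short:
                sn_o = np.stack([band_limited_noise(n_t, p.fs, rng) for _ in range(n_short)])
                sn_r = np.stack([band_limited_noise(n_t, p.fs, rng) for _ in range(n_short)])
                s_hbo = scalp[None, :] + 0.2 * p.noise_sd * sn_o
                s_hbr = p.hbr_ratio * scalp[None, :] + 0.2 * abs(p.hbr_ratio) * p.noise_sd * sn_r
            else:
                s_hbo = np.empty((0, n_t))
                s_hbr = np.empty((0, n_t))

            full_hbo = np.empty((montage.n_channels, n_t))
            full_hbr = np.empty((montage.n_channels, n_t))
            li = [montage.index_of(cid) for cid in long_ids]
            si = [montage.index_of(cid) for cid in short_ids]
            full_hbo[li], full_hbr[li] = hbo, hbr
            if n_short:
                full_hbo[si], full_hbr[si] = s_hbo, s_hbr

            intensity = _forward_intensity(
                full_hbo, full_hbr, montage, ages[pi], list(range(montage.n_channels))
            )

            if p.cardiac_amp > 0:
                t = np.arange(n_t) / p.fs
                phase = rng.uniform(0, 2 * np.pi)
                card = np.sin(2 * np.pi * p.cardiac_freq * t + phase)
                amp = np.full(montage.n_channels, p.cardiac_amp)
                amp[si] *= 3.0  # scalp pulsatility dominates short separations
                intensity *= 1.0 + amp[:, None, None] * card[None, None, :]

            if p.measurement_noise > 0:
                intensity *= np.exp(
                    p.measurement_noise
                    * rng.standard_normal(intensity.shape)
                )

            rec = RawRecording(
                participant_id=pid,
                age=float(ages[pi]),
                condition=cond,
                fs=p.fs,
                intensity=intensity,
                montage=montage,
            )
            arts: list[Artifact] = []
            if p.motion_rate > 0:
                rec, arts = inject_motion_artifacts(
                    rec, p.motion_rate, p.motion_amplitude,
                    seed=int(rng.integers(2**31 - 1)),
                )
            artifacts[(pid, lab)] = arts
            recordings.append(rec)

    truth = CohortTruth(
        latent=latent,
        weights=weights,
        signal_channels=sig_sets,
        hb_clean=hb_clean,
        hb_noiseless=hb_noiseless,
        artifacts=artifacts,
    )
    return SyntheticCohort(params=p, montage=montage, recordings=recordings, truth=truth)


# --------------------------------------------------------------------------
# Suspense ratings
# --------------------------------------------------------------------------


def generate_suspense_ratings(
    truth: CohortTruth,
    condition: Condition | str,
    target_corr: float,
    seed: int,
    interval_s: float = 2.0,
    fs: float = 3.9063,
) -> SuspenseRatings:
    """Ratings correlated with the latent narrative signal of a condition.

    The latent signal is sampled every ``interval_s`` seconds, mixed with an
    orthogonalized noise component so the realized correlation equals
    ``target_corr`` exactly (up to the affine rescaling), and mapped into
    the 1-10 rating range.
    """
    lab = condition.label if isinstance(condition, Condition) else condition
    if lab not in truth.latent:
        raise KeyError(f"no latent signal for condition {lab!r}")
    if not -1.0 <= target_corr <= 1.0:
        raise ValidationError("|target_corr| must be <= 1")
    rng = np.random.default_rng(seed)
    s = truth.latent[lab]
    step = max(1, int(round(interval_s * fs)))
    idx = np.arange(0, s.size, step)
    z = s[idx]
    z = (z - z.mean()) / z.std()

    if abs(target_corr) == 1.0:
        y = np.sign(target_corr) * z
    else:
        e = rng.standard_normal(z.size)
        e = e - (e @ z) / (z @ z) * z  # orthogonalize
        e = (e - e.mean()) / e.std()
        e = e - (e @ z) / (z @ z) * z  # re-orthogonalize after centering
        e /= np.sqrt((e @ e) / e.size)
        y = target_corr * z + np.sqrt(1 - target_corr**2) * e

    lo, hi = y.min(), y.max()
    if hi > lo:
        vals = 1.0 + 9.0 * (y - lo) / (hi - lo)
    else:
        vals = np.full(y.size, 5.5)
    return SuspenseRatings(times=idx / fs, values=vals)


# --------------------------------------------------------------------------
# Motion artifacts
# --------------------------------------------------------------------------


def inject_motion_artifacts(
    recording: RawRecording, rate: float, amplitude: float, seed: int
) -> tuple[RawRecording, list[Artifact]]:
    """Insert spike and baseline-shift artifacts at Poisson-drawn times.

    Artifacts are added in optical-density space (where motion appears
    additively) and mapped back to intensity, so untouched samples are
    bit-identical to the input.  ``amplitude`` is expressed in multiples of
    each channel's OD standard deviation; spikes are single-sample
    excursions, shifts are persisting steps.
    """
    if rate < 0:
        raise ValidationError("artifact rate must be >= 0")
    if rate == 0:
        return recording, []
    rng = np.random.default_rng(seed)
    n_t = recording.n_samples
    n_events = rng.poisson(rate * recording.duration_s / 60.0)
    if n_events == 0:
        return recording, []

    I = recording.intensity
    ref = I.mean(axis=2, keepdims=True)
    od = -np.log(I / ref)
    arts: list[Artifact] = []
    for _ in range(n_events):
        ch = int(rng.integers(recording.montage.n_channels))
        t0 = int(rng.integers(n_t))
        kind = "spike" if rng.random() < 0.5 else "shift"
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for wl in range(od.shape[1]):
            sd = od[ch, wl].std()
            mag = sign * amplitude * (sd if sd > 0 else 1e-3)
            if kind == "spike":
                od[ch, wl, t0] += mag
            else:
                od[ch, wl, t0:] += mag
        arts.append(Artifact(channel=ch, sample=t0, kind=kind, magnitude=sign * amplitude))

    intensity = I.copy()
    touched = sorted({a.channel for a in arts})
    intensity[touched] = (ref * np.exp(-od))[touched]
    new = RawRecording(
        participant_id=recording.participant_id,
        age=recording.age,
        condition=recording.condition,
        fs=recording.fs,
        intensity=intensity,
        montage=recording.montage,
    )
    return new, arts
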