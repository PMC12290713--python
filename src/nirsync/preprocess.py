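"""Preprocessing: raw light intensity -> standardized hemoglobin series.

The chain follows the conventional continuous-wave fNIRS pipeline:

1. intensity -> optical-density change, ``dOD = -ln(I / mean(I))``;
2. hybrid motion correction (spline de-trending of high-variance segments,
   then per-level wavelet coefficient rejection);
3. modified Beer-Lambert inversion to oxy-/deoxy-hemoglobin concentration
   changes, with an age- and wavelength-dependent differential pathlength
   factor (DPF);
4. zero-phase Butterworth band-pass (default 0.005-0.20 Hz);
5. scalp-physiology removal by regressing principal components of all
   good-quality short channels out of every long channel;
6. per-channel standardization (zero mean, unit variance).

Concentrations are expressed in micromolar; source-detector distances in cm;
extinction coefficients in cm^-1/(mol/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import interpolate, signal

from .core_io import (
    AnalysisConfig,
    ExtinctionTable,
    HOMER_EXTINCTION,
    Montage,
    RawRecording,
    ValidationError,
)

__all__ = [
    "OpticalDensitySeries",
    "HemoglobinSeries",
    "DPFModel",
    "GENERAL_DPF",
    "ParticipantExcluded",
    "intensity_to_od",
    "correct_motion_hybrid",
    "compute_dpf",
    "od_to_hemoglobin",
    "bandpass_filter",
    "assess_short_channel_quality",
    "short_channel_regression",
    "standardize",
    "run_preprocessing",
]


class ParticipantExcluded(Exception):
    """Raised when a recording cannot be preprocessed (no usable short channels)."""


@dataclass
class OpticalDensitySeries:
    """Optical-density change, channel x wavelength x time."""

    od: np.ndarray
    fs: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if not np.all(np.isfinite(self.od)):
            raise ValidationError("optical density contains non-finite values")


@dataclass
class HemoglobinSeries:
    """Concentration-change series (micromolar), channel x time, per chromophore."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_ids: list[str]
    standardized: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValidationError("hbo and hbr must share a shape")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValidationError("hemoglobin series contain non-finite values")
        if self.standardized:
            for arr in (self.hbo, self.hbr):
                if arr.shape[1] > 1:
                    if np.abs(arr.mean(axis=1)).max() > 1e-8:
                        raise ValidationError("standardized series must have zero mean")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]


# --------------------------------------------------------------------------
# Optical density
# --------------------------------------------------------------------------


def intensity_to_od(recording: RawRecording) -> OpticalDensitySeries:
    """Convert light intensity to optical-density change.

    Uses the series mean as the reference intensity (HOMER convention):
    ``dOD(t) = -ln(I(t) / <I>_t)``, so every dOD series has zero mean of
    ``exp(-dOD)`` weighted appropriately and, for small fluctuations, near
    zero mean itself.
    """
    I = recording.intensity
    if not np.all(I > 0):
        raise ValidationError("intensity must be strictly positive")
    ref = I.mean(axis=2, keepdims=True)
    od = -np.log(I / ref)
    return OpticalDensitySeries(od=od, fs=recording.fs, provenance=["intensity_to_od"])


# --------------------------------------------------------------------------
# Hybrid motion correction (spline stage + wavelet stage)
# --------------------------------------------------------------------------


def _moving_std(x: np.ndarray, w: int) -> np.ndarray:
    """Centered sliding-window standard deviation via cumulative sums."""
    n = x.size
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    c1 = np.cumsum(np.insert(xp, 0, 0.0))
    c2 = np.cumsum(np.insert(xp**2, 0, 0.0))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    return np.sqrt(var)[:n]


def _spline_correct_1d(x: np.ndarray, fs: float, window_s: float, thresh: float) -> np.ndarray:
    """Detect artifact segments and remove their spline trend.

    Detection works on the first-differenced series, where spikes and
    baseline steps appear as isolated outliers while the smooth hemodynamic
    signal stays small.  The channel baseline is a winsorized standard
    deviation of the differences (values clipped at 10 MAD-sd before the sd
    is taken), which ignores the artifacts themselves but, unlike a plain
    MAD, is not fooled by slow amplitude modulation of narrowband signals.
    Samples whose |dx| exceeds ``thresh`` times that baseline are flagged
    and dilated; within each flagged segment a smoothing spline fit is
    subtracted and the segment level re-anchored to the preceding clean
    sample so baseline shifts do not persist.
    """
    n = x.size
    w = max(3, int(round(window_s * fs)))
    if w > n:
        raise ValueError("motion-detection window longer than the series")
    dc = np.diff(x)
    dc = dc - np.median(dc)
    mad_sd = 1.4826 * np.median(np.abs(dc))
    if mad_sd <= 0:
        return x.copy()
    baseline = np.clip(dc, -10 * mad_sd, 10 * mad_sd).std()
    if baseline <= 0:
        return x.copy()
    mask = np.zeros(n, dtype=bool)
    hit = np.where(np.abs(dc) > thresh * baseline)[0]
    mask[hit] = True
    mask[np.minimum(hit + 1, n - 1)] = True
    if not mask.any():
        return x.copy()

    y = x.copy()
    # group flagged samples into contiguous segments (with 1-window padding)
    idx = np.where(mask)[0]
    segments: list[tuple[int, int]] = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev > w:
            segments.append((start, prev))
            start = i
        prev = i
    segments.append((start, prev))

    for s0, s1 in segments:
        a = max(0, s0 - w // 2)
        b = min(n, s1 + 1 + w // 2)
        seg = y[a:b]
        t = np.arange(seg.size, dtype=float)
        if seg.size >= 4:
            # smoothing spline tracks the artifact trajectory
            spl = interpolate.UnivariateSpline(t, seg, k=3, s=seg.size * np.var(seg) * 0.01)
            trend = spl(t)
        else:
            trend = np.full(seg.size, seg.mean())
        anchor = y[a - 1] if a > 0 else (y[b] if b < n else seg.mean())
        y[a:b] = seg - trend + anchor
    return y


def _wavelet_correct_1d(x: np.ndarray, wavelet: str, levels: int, iqr_mult: float) -> np.ndarray:
    """Zero detail coefficients that are outliers within their level."""
    n = x.size
    levels = min(levels, pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len))
    if levels < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric")
    margin = pywt.Wavelet(wavelet).dec_len - 1  # boundary-affected coefficients
    out = [coeffs[0]]
    for c in coeffs[1:]:
        q1, med, q3 = np.percentile(c, [25, 50, 75])
        iqr = q3 - q1
        if iqr <= 0 or c.size <= 2 * margin:
            out.append(c)
            continue
        keep = np.abs(c - med) <= iqr_mult * iqr
        keep[:margin] = True  # padding artifacts, not motion
        keep[-margin:] = True
        out.append(np.where(keep, c, 0.0))
    rec = pywt.waverec(out, wavelet, mode="symmetric")
    return rec[:n]


def correct_motion_hybrid(
    od: OpticalDensitySeries,
    window_s: float = 1.0,
    threshold: float = 8.0,
    wavelet: str = "db2",
    levels: int = 4,
    iqr_mult: float = 3.0,
) -> OpticalDensitySeries:
    """Two-stage motion correction: spline de-trending, then wavelet rejection.

    Stage 1 targets baseline shifts and large slow excursions; stage 2
    suppresses residual spikes, whose energy concentrates in outlying detail
    coefficients.  Dimensions are unchanged.
    """
    nt = od.od.shape[2]
    w = int(round(window_s * od.fs))
    if w > nt:
        raise ValueError("motion-detection window longer than the series")
    out = np.empty_like(od.od)
    for i in range(od.od.shape[0]):
        for j in range(od.od.shape[1]):
            y = _spline_correct_1d(od.od[i, j], od.fs, window_s, threshold)
            out[i, j] = _wavelet_correct_1d(y, wavelet, levels, iqr_mult)
    return OpticalDensitySeries(
        od=out,
        fs=od.fs,
        provenance=od.provenance
        + [f"correct_motion_hybrid(window_s={window_s}, threshold={threshold}, "
           f"wavelet={wavelet}, levels={levels}, iqr={iqr_mult})"],
    )


# --------------------------------------------------------------------------
# Differential pathlength factor
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DPFModel:
    """Coefficients of the general age/wavelength DPF equation.

    DPF(lambda, A) = alpha + beta*A**gamma + delta*lambda**3
                     + epsilon*lambda**2 + zeta*lambda

    with A in years and lambda in nm.  The default coefficients are the
    published fit of the general equation across adult cohorts; for a
    23-year-old they give DPF ~ 6.1 at 760 nm falling to ~ 5.0 at 850 nm.
    """

    alpha: float = 223.3
    beta: float = 0.05624
    gamma: float = 0.8493
    delta: float = -5.723e-7
    epsilon: float = 0.001245
    zeta: float = -0.9025


GENERAL_DPF = DPFModel()


def compute_dpf(age: float, wavelength: float, model: DPFModel = GENERAL_DPF) -> float:
    """Differential pathlength factor for a participant age (years) and wavelength (nm)."""
    if not 0 < age < 120:
        raise ValueError(f"age {age} out of supported range (0, 120)")
    if not 600 < wavelength < 1000:
        raise ValueError(f"wavelength {wavelength} nm out of supported range (600, 1000)")
    m = model
    dpf = (
        m.alpha
        + m.beta * age**m.gamma
        + m.delta * wavelength**3
        + m.epsilon * wavelength**2
        + m.zeta * wavelength
    )
    if dpf <= 0:
        raise ValueError("DPF model produced a nonpositive value")
    return float(dpf)


# --------------------------------------------------------------------------
# Modified Beer-Lambert inversion
# --------------------------------------------------------------------------


def od_to_hemoglobin(
    od: OpticalDensitySeries,
    montage: Montage,
    extinction: ExtinctionTable = HOMER_EXTINCTION,
    dpf_per_wavelength: list[float] | np.ndarray | None = None,
    age: float | None = None,
) -> HemoglobinSeries:
    """Invert the modified Beer-Lambert law per channel and time point.

    Solves, for each channel with distance rho,

        dOD_lambda / (DPF_lambda * rho) = eps_HbO,lambda * dHbO
                                          + eps_HbR,lambda * dHbR

    exactly for two wavelengths and in the least-squares sense for more.
    Either ``dpf_per_wavelength`` or ``age`` (from which DPFs are computed)
    must be given.  Returns concentrations in micromolar.
    """
    wavelengths = montage.wavelengths
    if len(wavelengths) < 2:
        raise ValidationError("need at least two wavelengths")
    if dpf_per_wavelength is None:
        if age is None:
            raise ValueError("provide dpf_per_wavelength or age")
        dpf_per_wavelength = [compute_dpf(age, wl) for wl in wavelengths]
    dpf = np.asarray(dpf_per_wavelength, dtype=float)
    if dpf.size != len(wavelengths):
        raise ValidationError("one DPF per wavelength required")

    E = extinction.matrix(wavelengths)  # (n_wl, 2)
    cond = np.linalg.cond(E)
    if cond > 1e6:
        raise np.linalg.LinAlgError(
            f"extinction matrix ill-conditioned (cond={cond:.3g}) for wavelengths "
            f"{wavelengths}"
        )
    pinv = np.linalg.pinv(E)  # (2, n_wl); exact inverse when n_wl == 2

    n_ch, n_wl, n_t = od.od.shape
    rho = np.array([c.rho for c in montage.channels])
    # scaled OD: (n_ch, n_wl, n_t) / (dpf[None,:,None] * rho[:,None,None])
    y = od.od / (dpf[None, :, None] * rho[:, None, None])
    conc = np.einsum("kw,cwt->ckt", pinv, y)  # (n_ch, 2, n_t), mol/L
    hbo = conc[:, 0, :] * 1e6
    hbr = conc[:, 1, :] * 1e6
    return HemoglobinSeries(
        hbo=hbo,
        hbr=hbr,
        fs=od.fs,
        channel_ids=montage.channel_ids,
        provenance=od.provenance + [f"od_to_hemoglobin(dpf={list(np.round(dpf, 4))})"],
    )


# --------------------------------------------------------------------------
# Band-pass filter
# --------------------------------------------------------------------------


def bandpass_filter(
    hb: HemoglobinSeries, low: float = 0.005, high: float = 0.20, order: int = 3
) -> HemoglobinSeries:
    """Zero-phase Butterworth band-pass applied to both chromophores."""
    nyq = hb.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=hb.fs, output="sos")
    hbo = signal.sosfiltfilt(sos, hb.hbo, axis=1)
    hbr = signal.sosfiltfilt(sos, hb.hbr, axis=1)
    return HemoglobinSeries(
        hbo=hbo,
        hbr=hbr,
        fs=hb.fs,
        channel_ids=hb.channel_ids,
        provenance=hb.provenance + [f"bandpass({low}-{high} Hz, order {order}, zero-phase)"],
    )


# --------------------------------------------------------------------------
# Short-channel quality and regression
# --------------------------------------------------------------------------


def assess_short_channel_quality(
    recording: RawRecording,
    band: tuple[float, float] = (0.5, 2.0),
    prominence_mult: float = 3.0,
) -> dict[str, bool]:
    """Flag short channels whose raw intensity shows a cardiac spectral peak.

    A short channel measuring real scalp perfusion carries the heartbeat
    (~1 Hz); its absence indicates poor optode coupling.  A channel is good
    iff, for every wavelength, the Welch power spectrum has a local maximum
    in ``band`` whose prominence exceeds ``prominence_mult`` times the
    median spectral power inside the band.  (Welch averaging keeps the
    noise floor smooth enough that broadband noise does not fake a peak.)
    """
    shorts = recording.montage.short_channels
    if not shorts:
        raise ValidationError("recording has no short channels")
    lo, hi = band
    result: dict[str, bool] = {}
    for ch in shorts:
        i = recording.montage.index_of(ch.channel_id)
        ok = True
        for j in range(len(recording.montage.wavelengths)):
            x = recording.intensity[i, j, :]
            f, p = signal.welch(
                x - x.mean(), fs=recording.fs, nperseg=min(256, x.size)
            )
            sel = (f >= lo) & (f <= hi)
            if sel.sum() < 3:
                ok = False
                break
            pband = p[sel]
            floor = np.median(pband)
            peaks, props = signal.find_peaks(pband, prominence=prominence_mult * floor)
            if peaks.size == 0:
                ok = False
                break
        result[ch.channel_id] = ok
    return result


def short_channel_regression(
    hb_long: HemoglobinSeries, hb_short_good: HemoglobinSeries
) -> HemoglobinSeries:
    """Regress short-channel principal components out of every long channel.

    All good short-channel HbO and HbR series are stacked and reduced to
    principal components via SVD (avoiding collinearity between adjacent
    short channels); the full component set plus an intercept is regressed
    out of each long-channel series by ordinary least squares.  One shared
    component set serves both chromophores.
    """
    if hb_short_good.n_channels < 1:
        raise ValidationError("need at least one good short channel")
    X = np.vstack([hb_short_good.hbo, hb_short_good.hbr]).T  # (T, 2*n_short)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise np.linalg.LinAlgError("short-channel set has zero variance")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-12
    pcs = U[:, keep] * s[keep]  # principal component scores

    design = np.column_stack([np.ones(pcs.shape[0]), pcs])
    # OLS residuals for both chromophores at once
    def _residual(Y: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
        return (Y.T - design @ beta).T

    return HemoglobinSeries(
        hbo=_residual(hb_long.hbo),
        hbr=_residual(hb_long.hbr),
        fs=hb_long.fs,
        channel_ids=hb_long.channel_ids,
        provenance=hb_long.provenance
        + [f"short_channel_regression(n_components={int(keep.sum())})"],
    )


def standardize(hb: HemoglobinSeries) -> HemoglobinSeries:
    """Zero-mean, unit-variance per channel series (idempotent)."""

    def _z(a: np.ndarray) -> np.ndarray:
        mu = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return (a - mu) / sd

    return HemoglobinSeries(
        hbo=_z(hb.hbo),
        hbr=_z(hb.hbr),
        fs=hb.fs,
        channel_ids=hb.channel_ids,
        standardized=True,
        provenance=hb.provenance + ["standardize"],
    )


# --------------------------------------------------------------------------
# Full chain
# --------------------------------------------------------------------------


def run_preprocessing(
    recording: RawRecording,
    config: AnalysisConfig | None = None,
    motion_correction: bool = True,
) -> HemoglobinSeries:
    """Full preprocessing chain for one recording; returns long channels only.

    Raises :class:`ParticipantExcluded` when the montage has short channels
    but none passes the cardiac quality check — such a recording cannot be
    cleaned of scalp physiology and the participant should be dropped.
    If the montage has no short channels at all, the regression step is
    skipped (provenance records this).
    """
    cfg = config or AnalysisConfig()
    od = intensity_to_od(recording)
    if motion_correction:
        od = correct_motion_hybrid(
            od,
            window_s=cfg.motion_window_s,
            threshold=cfg.motion_threshold,
            wavelet=cfg.wavelet,
            levels=cfg.wavelet_levels,
            iqr_mult=cfg.wavelet_iqr,
        )
    hb = od_to_hemoglobin(od, recording.montage, age=recording.age)
    hb = bandpass_filter(hb, cfg.filter_low, cfg.filter_high, cfg.filter_order)

    mon = recording.montage
    long_idx = [mon.index_of(c.channel_id) for c in mon.long_channels]
    hb_long = HemoglobinSeries(
        hbo=hb.hbo[long_idx],
        hbr=hb.hbr[long_idx],
        fs=hb.fs,
        channel_ids=[c.channel_id for c in mon.long_channels],
        provenance=hb.provenance + ["select_long_channels"],
    )

    if mon.short_channels:
        quality = assess_short_channel_quality(
            recording, band=cfg.cardiac_band, prominence_mult=cfg.cardiac_prominence
        )
        good = [cid for cid, ok in quality.items() if ok]
        if not good:
            raise ParticipantExcluded(
                f"participant {recording.participant_id}: no good-quality short channels"
            )
        short_idx = [mon.index_of(cid) for cid in good]
        hb_short = HemoglobinSeries(
            hbo=hb.hbo[short_idx],
            hbr=hb.hbr[short_idx],
            fs=hb.fs,
            channel_ids=good,
        )
        hb_long = short_channel_regression(hb_long, hb_short)
    else:
        hb_long.provenance.append("short_channel_regression skipped (no short channels)")

    return standardize(hb_long)
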