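"""Domain types, montage handling, and file I/O for fNIRS cohort analysis.

The package works with continuous-wave fNIRS recordings: raw light
intensities per channel and wavelength, a montage describing source-detector
geometry, and derived hemoglobin-concentration time series.  Two on-disk
layouts are supported:

* a minimal subset of the SNIRF standard (HDF5-based), covering exactly the
  fields this pipeline consumes, and
* a plain-text *fixture* format — one directory per recording holding a
  ``meta.json``, a ``montage.json`` and one ``intensity_<wavelength>.csv``
  per wavelength — convenient for version-controlled test data.

Wavelengths are normalised to ascending order at load time and channels are
ordered lexicographically by (source_id, detector_id); every downstream
matrix inherits that ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Condition",
    "ChannelDef",
    "Montage",
    "RawRecording",
    "ExtinctionTable",
    "HOMER_EXTINCTION",
    "AnalysisConfig",
    "FormatError",
    "ValidationError",
    "load_recording",
    "save_recording",
    "load_cohort",
    "save_cohort",
    "save_results",
]


class FormatError(ValueError):
    """A file is missing structure the reader requires."""


class ValidationError(ValueError):
    """Data violate a domain invariant (e.g. nonpositive light intensity)."""


# --------------------------------------------------------------------------
# Conditions
# --------------------------------------------------------------------------

INTACT = "Intact"
SCRAMBLED = "Scrambled"


@dataclass(frozen=True, order=True)
class Condition:
    """One experimental condition: a stimulus in Intact or Scrambled form.

    Scrambled controls retain the low-level audiovisual features of the
    stimulus but destroy its narrative structure; the analysis contrasts
    synchrony between the two variants of each stimulus.
    """

    stimulus: str
    variant: str  # INTACT or SCRAMBLED

    def __post_init__(self) -> None:
        if self.variant not in (INTACT, SCRAMBLED):
            raise ValidationError(f"unknown condition variant {self.variant!r}")

    @property
    def intact(self) -> bool:
        return self.variant == INTACT

    @property
    def counterpart(self) -> "Condition":
        other = SCRAMBLED if self.intact else INTACT
        return Condition(self.stimulus, other)

    @property
    def label(self) -> str:
        return f"{self.stimulus}_{self.variant}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        stimulus, _, variant = label.rpartition("_")
        if not stimulus:
            raise FormatError(f"cannot parse condition label {label!r}")
        return cls(stimulus, variant)


# --------------------------------------------------------------------------
# Montage
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelDef:
    """One source-detector pair.

    ``rho`` is the Euclidean source-detector distance in cm.  Channels at
    ~3 cm ("long") sample the cortex; channels at <= 1 cm ("short") sample
    only scalp and systemic physiology and are used as nuisance regressors.
    """

    channel_id: str
    source_id: str
    detector_id: str
    rho: float
    is_short: bool

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValidationError(f"channel {self.channel_id}: rho must be > 0")
        if self.is_short != (self.rho <= 1.0):
            raise ValidationError(
                f"channel {self.channel_id}: is_short flag inconsistent with "
                f"rho={self.rho} cm (short iff rho <= 1.0 cm)"
            )


@dataclass(frozen=True)
class Montage:
    """Channel geometry shared by every recording in a cohort.

    Channels are stored sorted lexicographically by (source_id, detector_id);
    all matrices produced downstream use this ordering.  Every channel shares
    one ascending wavelength list.
    """

    channels: tuple[ChannelDef, ...]
    wavelengths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.wavelengths) < 2:
            raise ValidationError("montage needs at least two wavelengths")
        object.__setattr__(
            self, "wavelengths", tuple(sorted(float(w) for w in self.wavelengths))
        )
        ordered = tuple(
            sorted(self.channels, key=lambda c: (c.source_id, c.detector_id))
        )
        object.__setattr__(self, "channels", ordered)
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("channel_ids must be unique")

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def long_channels(self) -> list[ChannelDef]:
        return [c for c in self.channels if not c.is_short]

    @property
    def short_channels(self) -> list[ChannelDef]:
        return [c for c in self.channels if c.is_short]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index_of(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return i
        raise KeyError(channel_id)

    def to_dict(self) -> dict:
        return {
            "wavelengths": list(self.wavelengths),
            "channels": [dataclasses.asdict(c) for c in self.channels],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Montage":
        try:
            chans = tuple(ChannelDef(**c) for c in d["channels"])
            wls = tuple(d["wavelengths"])
        except KeyError as exc:
            raise FormatError(f"montage description missing field {exc}") from exc
        return cls(chans, wls)


# --------------------------------------------------------------------------
# Raw recording
# --------------------------------------------------------------------------


@dataclass
class RawRecording:
    """Raw light intensities for one participant in one condition.

    ``intensity`` has shape (n_channels, n_wavelengths, n_samples), strictly
    positive (required for the log transform to optical density), with
    channel order matching ``montage.channels`` and wavelength order matching
    ``montage.wavelengths`` (ascending).
    """

    participant_id: str
    age: float
    condition: Condition
    fs: float
    intensity: np.ndarray
    montage: Montage

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be > 0")
        if self.intensity.ndim != 3:
            raise ValidationError("intensity must be channel x wavelength x time")
        nc, nw, nt = self.intensity.shape
        if nc != self.montage.n_channels or nw != len(self.montage.wavelengths):
            raise ValidationError(
                "intensity shape does not match montage "
                f"({nc} x {nw} vs {self.montage.n_channels} channels x "
                f"{len(self.montage.wavelengths)} wavelengths)"
            )
        if nt < 2:
            raise ValidationError("recording must contain at least 2 samples")
        bad = np.where(~np.all(self.intensity > 0, axis=(1, 2)))[0]
        if bad.size:
            names = [self.montage.channels[i].channel_id for i in bad[:5]]
            raise ValidationError(
                f"nonpositive light intensity in channel(s) {names}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# --------------------------------------------------------------------------
# Extinction coefficients
# --------------------------------------------------------------------------


class ExtinctionTable(dict):
    """Wavelength (nm) -> (eps_HbO, eps_HbR) in cm^-1 / (mol/L).

    The default table carries the HOMER ``GetExtinctions`` values for the
    five laser/LED wavelengths used by common NIRScout-class devices.
    """

    def __init__(self, entries: Mapping[float, tuple[float, float]]):
        super().__init__({float(k): (float(v[0]), float(v[1])) for k, v in entries.items()})
        for wl, (eo, er) in self.items():
            if eo <= 0 or er <= 0:
                raise ValidationError(f"extinction coefficients at {wl} nm must be > 0")

    def matrix(self, wavelengths: Sequence[float]) -> np.ndarray:
        """Stack rows [eps_HbO, eps_HbR] for the requested wavelengths."""
        rows = []
        for wl in wavelengths:
            if float(wl) not in self:
                raise ValidationError(f"no extinction coefficients for {wl} nm")
            rows.append(self[float(wl)])
        return np.array(rows, dtype=float)


#: HOMER GetExtinctions values, cm^-1/(mol/L), rows (eps_HbO, eps_HbR).
HOMER_EXTINCTION = ExtinctionTable(
    {
        760.0: (645.0, 1669.0),
        785.0: (787.0, 996.65),
        808.0: (903.0, 804.0),
        830.0: (1008.0, 778.0),
        850.0: (1097.0, 781.0),
    }
)


# --------------------------------------------------------------------------
# Analysis configuration
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable parameters for the full pipeline.

    Defaults follow the study conditions this pipeline targets: a
    0.005-0.20 Hz Butterworth band (order 3, applied forward-backward),
    1000 phase-scrambled surrogates, 1000 label permutations, alpha = 0.05.
    """

    filter_low: float = 0.005
    filter_high: float = 0.20
    filter_order: int = 3
    n_surrogates: int = 1000
    n_permutations: int = 1000
    alpha: float = 0.05
    fisher_clip: float = 1.0 - 1e-7
    # hybrid motion correction
    motion_window_s: float = 1.0
    motion_threshold: float = 8.0
    wavelet: str = "db2"
    wavelet_levels: int = 4
    wavelet_iqr: float = 3.0
    # short-channel quality
    cardiac_band: tuple[float, float] = (0.5, 2.0)
    cardiac_prominence: float = 3.0
    # decoding
    tuning_budget: int = 25
    permutation_tuning_budget: int | None = None
    classifiers: tuple[str, ...] = ()  # empty -> full registry
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.filter_low < self.filter_high:
            raise ValidationError("need 0 < filter_low < filter_high")
        if self.n_surrogates < 1 or self.n_permutations < 1:
            raise ValidationError("surrogate and permutation counts must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cardiac_band"] = list(self.cardiac_band)
        d["classifiers"] = list(self.classifiers)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "cardiac_band" in d:
            d["cardiac_band"] = tuple(d["cardiac_band"])
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def spawn_seed(self, stage: str) -> int:
        """Derive a per-stage integer seed from the master seed.

        One master seed spawns independent per-stage streams through a fixed
        hash offset, so stages can be re-run in isolation reproducibly.
        """
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


# --------------------------------------------------------------------------
# Fixture format I/O
# --------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def save_recording(rec: RawRecording, path: str | Path, format: str = "fixture") -> Path:
    """Write one recording; returns the directory or file written."""
    path = Path(path)
    if format == "fixture":
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "participant_id": rec.participant_id,
            "age": rec.age,
            "condition": {"stimulus": rec.condition.stimulus, "variant": rec.condition.variant},
            "fs": rec.fs,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        (path / "montage.json").write_text(json.dumps(rec.montage.to_dict(), indent=1))
        for j, wl in enumerate(rec.montage.wavelengths):
            df = pd.DataFrame(
                rec.intensity[:, j, :], index=rec.montage.channel_ids
            )
            df.index.name = "channel_id"
            df.to_csv(path / f"intensity_{wl:g}.csv", float_format=_FLOAT_FMT)
        return path
    if format == "snirf":
        _write_snirf(rec, path)
        return path
    raise ValueError(f"unknown format {format!r}")


def load_recording(path: str | Path, format: str | None = None) -> RawRecording:
    """Load a recording from the fixture directory layout or a SNIRF file."""
    path = Path(path)
    if format is None:
        format = "snirf" if path.is_file() else "fixture"
    if format == "snirf":
        return _read_snirf(path)
    if format != "fixture":
        raise ValueError(f"unknown format {format!r}")

    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"{path}: missing meta.json")
    meta = json.loads(meta_path.read_text())
    for key in ("participant_id", "fs", "condition", "age"):
        if key not in meta:
            raise FormatError(f"{path}: meta.json missing {key!r}")
    montage_path = path / "montage.json"
    if not montage_path.exists():
        raise FormatError(f"{path}: missing montage.json")
    montage = Montage.from_dict(json.loads(montage_path.read_text()))

    planes = []
    for wl in montage.wavelengths:
        f = path / f"intensity_{wl:g}.csv"
        if not f.exists():
            raise FormatError(f"{path}: missing intensity file for {wl} nm")
        df = pd.read_csv(f, index_col="channel_id", float_precision="round_trip")
        df = df.loc[montage.channel_ids]
        planes.append(df.to_numpy(dtype=float))
    intensity = np.stack(planes, axis=1)
    cond = meta["condition"]
    return RawRecording(
        participant_id=str(meta["participant_id"]),
        age=float(meta["age"]),
        condition=Condition(cond["stimulus"], cond["variant"]),
        fs=float(meta["fs"]),
        intensity=intensity,
        montage=montage,
    )


def save_cohort(recs: Sequence[RawRecording], path: str | Path) -> Path:
    path = Path(path)
    for rec in recs:
        save_recording(rec, path / f"{rec.participant_id}_{rec.condition.label}")
    return path


def load_cohort(path: str | Path) -> list[RawRecording]:
    """Load every fixture recording under ``path``; enforce one shared montage."""
    path = Path(path)
    recs = [load_recording(p) for p in sorted(path.iterdir()) if (p / "meta.json").exists()]
    if not recs:
        raise FormatError(f"no recordings found under {path}")
    ref = recs[0].montage
    for rec in recs[1:]:
        if rec.montage != ref:
            raise ValidationError(
                f"recording {rec.participant_id}/{rec.condition.label} disagrees "
                "with the cohort montage"
            )
    return recs


# --------------------------------------------------------------------------
# SNIRF subset
# --------------------------------------------------------------------------

# Only the fields this pipeline needs are read/written: one data block of
# continuous-wave intensities, probe geometry (for rho), wavelengths, and
# metaDataTags for participant id / age / condition.


def _write_snirf(rec: RawRecording, path: Path) -> None:
    import h5py

    mon = rec.montage
    sources = sorted({c.source_id for c in mon.channels})
    detectors = sorted({c.detector_id for c in mon.channels})
    s_idx = {s: i + 1 for i, s in enumerate(sources)}
    d_idx = {d: i + 1 for i, d in enumerate(detectors)}

    # Synthetic geometry reproducing each channel's rho: sources spaced on a
    # line, each detector at its channel's distance from its source.  A
    # detector shared between channels keeps the position of its first pair.
    s_pos = {s: np.array([20.0 * i, 0.0, 0.0]) for i, s in enumerate(sources)}
    d_pos: dict[str, np.ndarray] = {}
    for c in mon.channels:
        if c.detector_id not in d_pos:
            d_pos[c.detector_id] = s_pos[c.source_id] + np.array([c.rho, 0.0, 0.0])

    nt = rec.n_samples
    n_meas = mon.n_channels * len(mon.wavelengths)
    data = np.empty((nt, n_meas))
    with h5py.File(path, "w") as h5:
        h5.create_dataset("formatVersion", data="1.0")
        nirs = h5.create_group("nirs")
        tags = nirs.create_group("metaDataTags")
        tags.create_dataset("SubjectID", data=rec.participant_id)
        tags.create_dataset("LengthUnit", data="cm")
        tags.create_dataset("TimeUnit", data="s")
        tags.create_dataset("FrequencyUnit", data="Hz")
        tags.create_dataset("Age", data=float(rec.age))
        tags.create_dataset("Stimulus", data=rec.condition.stimulus)
        tags.create_dataset("StimulusVariant", data=rec.condition.variant)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(mon.wavelengths))
        probe.create_dataset("sourcePos3D", data=np.stack([s_pos[s] for s in sources]))
        probe.create_dataset("detectorPos3D", data=np.stack([d_pos[d] for d in detectors]))
        d1 = nirs.create_group("data1")
        k = 0
        for j in range(len(mon.wavelengths)):
            for i, c in enumerate(mon.channels):
                data[:, k] = rec.intensity[i, j, :]
                ml = d1.create_group(f"measurementList{k + 1}")
                ml.create_dataset("sourceIndex", data=s_idx[c.source_id])
                ml.create_dataset("detectorIndex", data=d_idx[c.detector_id])
                ml.create_dataset("wavelengthIndex", data=j + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(nt) / rec.fs)


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _read_snirf(path: Path) -> RawRecording:
    import h5py

    with h5py.File(path, "r") as h5:
        if "nirs" not in h5:
            raise FormatError(f"{path}: not a SNIRF file (no /nirs group)")
        nirs = h5["nirs"]
        if "probe" not in nirs or "wavelengths" not in nirs["probe"]:
            raise FormatError(f"{path}: missing probe wavelengths")
        wavelengths = np.asarray(nirs["probe"]["wavelengths"][()], dtype=float)
        s_pos = np.asarray(nirs["probe"]["sourcePos3D"][()], dtype=float)
        d_pos = np.asarray(nirs["probe"]["detectorPos3D"][()], dtype=float)
        d1 = nirs["data1"]
        time = np.asarray(d1["time"][()], dtype=float)
        if time.size < 2:
            raise FormatError(f"{path}: cannot infer sampling rate from time vector")
        fs = 1.0 / float(np.median(np.diff(time)))
        data = np.asarray(d1["dataTimeSeries"][()], dtype=float)

        meas = []
        k = 1
        while f"measurementList{k}" in d1:
            ml = d1[f"measurementList{k}"]
            meas.append(
                (int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()]),
                 int(ml["wavelengthIndex"][()]))
            )
            k += 1
        if not meas:
            raise FormatError(f"{path}: no measurement list")

        tags = nirs["metaDataTags"]
        participant = _read_str(tags["SubjectID"]) if "SubjectID" in tags else path.stem
        age = float(tags["Age"][()]) if "Age" in tags else float("nan")
        stim = _read_str(tags["Stimulus"]) if "Stimulus" in tags else "unknown"
        variant = _read_str(tags["StimulusVariant"]) if "StimulusVariant" in tags else INTACT

    pairs = sorted({(s, d) for s, d, _ in meas})
    order = np.argsort(wavelengths)
    wl_sorted = wavelengths[order]
    wl_rank = {int(orig) + 1: new for new, orig in enumerate(order)}

    chans = []
    for s, d in pairs:
        rho = float(np.linalg.norm(s_pos[s - 1] - d_pos[d - 1]))
        chans.append(
            ChannelDef(
                channel_id=f"S{s}-D{d}",
                source_id=f"S{s}",
                detector_id=f"D{d}",
                rho=rho,
                is_short=rho <= 1.0,
            )
        )
    montage = Montage(tuple(chans), tuple(wl_sorted))
    pair_index = {(c.source_id, c.detector_id): i for i, c in enumerate(montage.channels)}

    intensity = np.empty((montage.n_channels, wl_sorted.size, time.size))
    for col, (s, d, w) in enumerate(meas):
        i = pair_index[(f"S{s}", f"D{d}")]
        intensity[i, wl_rank[w], :] = data[:, col]

    return RawRecording(
        participant_id=participant,
        age=age,
        condition=Condition(stim, variant),
        fs=fs,
        intensity=intensity,
        montage=montage,
    )


# --------------------------------------------------------------------------
# Result persistence
# --------------------------------------------------------------------------


def save_results(results, path: str | Path, config: AnalysisConfig | None = None,
                 seed: int | None = None) -> dict:
    """Write stage outputs as CSV/JSON tables plus a manifest.

    Dispatches on the result type (ISC matrices, channel statistics,
    consistency/decoding results, plain DataFrames).  Returns the manifest,
    which records every file written together with the config hash and seed
    so a run can be reproduced exactly.
    """
    from . import isc_stats, reproducibility  # local import to avoid cycles

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _write_df(df: pd.DataFrame, name: str) -> None:
        f = path / name
        df.to_csv(f, index=False, float_format=_FLOAT_FMT)
        written.append(name)

    items = results if isinstance(results, (list, tuple)) else [results]
    for item in items:
        if isinstance(item, isc_stats.ISCMatrix):
            _write_df(item.to_frame(), f"isc_{item.condition.label}.csv")
        elif isinstance(item, isc_stats.ChannelStats):
            _write_df(item.to_frame(), f"stats_{item.contrast}.csv")
        elif isinstance(item, isc_stats.Mask):
            f = path / f"mask_{item.contrast}_loo{item.left_out_participant}.json"
            f.write_text(json.dumps(dataclasses.asdict(item), indent=1))
            written.append(f.name)
        elif isinstance(item, reproducibility.ConsistencyResult):
            _write_df(item.to_frame(), "consistency.csv")
        elif isinstance(item, reproducibility.DecodingResult):
            f = path / "decoding.json"
            f.write_text(json.dumps(item.to_dict(), indent=1))
            written.append(f.name)
        elif isinstance(item, pd.DataFrame):
            _write_df(item, "table.csv")
        else:
            raise TypeError(f"don't know how to save {type(item).__name__}")

    manifest = {
        "files": written,
        "config_hash": config.content_hash() if config else None,
        "seed": seed if seed is not None else (config.seed if config else None),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
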