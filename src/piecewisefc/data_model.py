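"""Domain containers, file I/O and preprocessing for epoched multi-subject EEG.

The central container is :class:`EpochedEEG`: one subject's stimulus-locked
epochs as a ``channels x samples x trials`` array with binary per-trial
condition labels (1 = target, 0 = non-target, the two conditions of an
oddball task).  A :class:`MultiSubjectDataset` is an ordered collection of
subjects sharing channel set, sampling rate and epoch geometry.

Continuous EDF(+) and BrainVision recordings are read through :mod:`mne`
and epoched around their annotations; the package's own on-disk container
is a small HDF5 layout (see :func:`write_epochs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy import signal

from .errors import FormatError, ParameterError, ValidationError

NONTARGET = 0
TARGET = 1

__all__ = [
    "NONTARGET",
    "TARGET",
    "BandSpec",
    "DEFAULT_BANDS",
    "EpochedEEG",
    "MultiSubjectDataset",
    "read_epochs",
    "write_epochs",
    "preprocess_filters",
    "baseline_correct",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with closed edges [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ParameterError(f"band edges must satisfy 0 < lo < hi, got {self}")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean membership of frequency bins; edges belong to the band."""
        freqs = np.asarray(freqs, dtype=float)
        return (freqs >= self.lo) & (freqs <= self.hi)


#: Canonical low-frequency EEG rhythms.  Shared edges (5, 8, 14 Hz) belong to
#: both adjacent bands (closed-interval membership).
DEFAULT_BANDS: Mapping[str, BandSpec] = {
    "delta": BandSpec("delta", 2.0, 5.0),
    "theta": BandSpec("theta", 5.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 14.0),
    "beta": BandSpec("beta", 14.0, 30.0),
}


def get_band(band: "BandSpec | str") -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return DEFAULT_BANDS[band]
    except KeyError:
        raise ParameterError(
            f"unknown band {band!r}; known: {sorted(DEFAULT_BANDS)}"
        ) from None


@dataclass
class EpochedEEG:
    """One subject's epoched EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples, n_trials)`` float array, microvolts.
    fs
        Sampling rate in Hz.
    labels
        ``(n_trials,)`` int array of condition codes, 0 = non-target,
        1 = target.
    channel_names
        Ordered, unique channel identifiers.
    t0
        Epoch start relative to stimulus onset, seconds (negative =
        prestimulus).
    subject_id
        Free-form identifier.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: tuple[str, ...]
    t0: float = 0.0
    subject_id: str = "subject"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be channels x samples x trials, got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if self.labels.shape != (self.data.shape[2],):
            raise ValidationError(
                f"label count {self.labels.shape} does not match trial count "
                f"{self.data.shape[2]}"
            )
        bad = set(np.unique(self.labels)) - {NONTARGET, TARGET}
        if bad:
            raise ValidationError(f"labels must be 0/1, found {sorted(bad)}")
        for cond in (NONTARGET, TARGET):
            if np.sum(self.labels == cond) < 2:
                raise ValidationError(
                    f"need at least 2 trials per condition, condition {cond} "
                    f"has {np.sum(self.labels == cond)}"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def trials_of(self, condition: int) -> np.ndarray:
        """Indices of trials with the given condition code."""
        return np.flatnonzero(self.labels == condition)

    def copy_with(self, **kw) -> "EpochedEEG":
        return replace(self, **kw)


@dataclass
class MultiSubjectDataset:
    """Ordered collection of subjects with shared channel set and geometry."""

    subjects: list[EpochedEEG] = field(default_factory=list)

    def __post_init__(self):
        if len(self.subjects) < 2:
            raise ValidationError("a multi-subject dataset needs M >= 2 subjects")
        ref = self.subjects[0]
        for s in self.subjects[1:]:
            if s.channel_names != ref.channel_names:
                raise ValidationError("subjects must share channel order")
            if s.fs != ref.fs or s.n_samples != ref.n_samples or s.t0 != ref.t0:
                raise ValidationError("subjects must share fs and epoch geometry")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_channels(self) -> int:
        return self.subjects[0].n_channels

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.subjects[0].channel_names

    @property
    def fs(self) -> float:
        return self.subjects[0].fs

    @property
    def times(self) -> np.ndarray:
        return self.subjects[0].times

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


# ---------------------------------------------------------------------------
# I/O

def write_epochs(epochs: EpochedEEG, path) -> None:
    """Write the internal HDF5 container.

    Layout: datasets ``/data`` (C x T x N float64), ``/labels`` (N int),
    ``/channel_names`` (string array); root attributes ``fs``, ``t0``,
    ``subject_id``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
        )
        f.attrs["fs"] = epochs.fs
        f.attrs["t0"] = epochs.t0
        f.attrs["subject_id"] = epochs.subject_id


def _read_hdf5(path) -> EpochedEEG:
    try:
        with h5py.File(path, "r") as f:
            for key in ("data", "labels", "channel_names"):
                if key not in f:
                    raise FormatError(f"{path}: missing dataset /{key}")
            for key in ("fs", "t0"):
                if key not in f.attrs:
                    raise FormatError(f"{path}: missing attribute {key}")
            return EpochedEEG(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                labels=f["labels"][()],
                channel_names=[
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in f["channel_names"][()]
                ],
                t0=float(f.attrs["t0"]),
                subject_id=str(f.attrs.get("subject_id", "subject")),
            )
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 file ({exc})") from exc


_DEFAULT_LABEL_MAP = {
    "target": TARGET,
    "tgt": TARGET,
    "nontarget": NONTARGET,
    "non-target": NONTARGET,
    "standard": NONTARGET,
}


def _read_continuous(path, format: str, tmin: float, tmax: float,
                     label_map: Mapping[str, int] | None,
                     subject_id: str | None) -> EpochedEEG:
    import mne

    mne.set_log_level("ERROR")
    try:
        if format == "EDF":
            raw = mne.io.read_raw_edf(path, preload=True)
        else:  # BrainVision
            raw = mne.io.read_raw_brainvision(path, preload=True)
    except Exception as exc:  # mne raises assorted types for bad files
        raise FormatError(f"{path}: cannot parse as {format} ({exc})") from exc

    fs = float(raw.info["sfreq"])
    lmap = dict(_DEFAULT_LABEL_MAP if label_map is None else label_map)
    onsets, labels = [], []
    for ann in raw.annotations:
        desc = str(ann["description"]).strip().lower()
        # BrainVision markers look like "Stimulus/target"
        key = desc.split("/")[-1]
        if key in lmap:
            onsets.append(float(ann["onset"]))
            labels.append(lmap[key])
    if not onsets:
        raise FormatError(
            f"{path}: no annotations matching the label map "
            f"{sorted(lmap)} found"
        )
    n_samp = int(round((tmax - tmin) * fs))
    if n_samp < 1:
        raise ParameterError(f"empty epoch window [{tmin}, {tmax})")
    sig = raw.get_data(units="uV")
    trials, kept_labels = [], []
    for onset, lab in zip(onsets, labels):
        start = int(round((onset + tmin) * fs))
        if start < 0 or start + n_samp > sig.shape[1]:
            continue  # event too close to the recording edge
        trials.append(sig[:, start:start + n_samp])
        kept_labels.append(lab)
    if not trials:
        raise FormatError(f"{path}: no event fits inside the recording")
    data = np.stack(trials, axis=-1)
    return EpochedEEG(
        data=data,
        fs=fs,
        labels=np.array(kept_labels),
        channel_names=list(raw.ch_names),
        t0=tmin,
        subject_id=subject_id or Path(path).stem,
    )


def read_epochs(path, format: str | None = None, *, tmin: float = -0.2,
                tmax: float = 0.8, label_map: Mapping[str, int] | None = None,
                subject_id: str | None = None) -> EpochedEEG:
    """Read one subject's epochs from disk.

    Parameters
    ----------
    path
        File path.  For BrainVision pass the ``.vhdr`` header file.
    format
        ``"HDF5"``, ``"EDF"`` or ``"BrainVision"``; inferred from the file
        extension when omitted (``.h5``/``.hdf5``, ``.edf``, ``.vhdr``).
    tmin, tmax
        Epoch extent in seconds relative to each annotated event; only used
        for continuous formats (the HDF5 container is already epoched).
        Defaults cover the oddball epoch [-200, +800] ms.
    label_map
        Mapping from annotation description (lower-case, the part after any
        ``/``) to condition code 0/1.  Defaults recognise "target",
        "nontarget", "non-target" and "standard".
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {".h5": "HDF5", ".hdf5": "HDF5", ".edf": "EDF",
                  ".vhdr": "BrainVision"}.get(ext)
        if format is None:
            raise ParameterError(f"cannot infer format from extension {ext!r}")
    format = {"hdf5": "HDF5", "internal-hdf5": "HDF5", "edf": "EDF",
              "brainvision": "BrainVision"}.get(format.lower(), format)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    if format == "HDF5":
        return _read_hdf5(path)
    if format in ("EDF", "BrainVision"):
        return _read_continuous(path, format, tmin, tmax, label_map, subject_id)
    raise ParameterError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Preprocessing

def _butter_sos(kind: str, freqs, fs: float, order: int = 4):
    return signal.butter(order, freqs, btype=kind, fs=fs, output="sos")


def preprocess_filters(x: EpochedEEG, hp: float = 1.0,
                       notch: Sequence[float] = (60.0, 120.0),
                       lp: float = 120.0) -> EpochedEEG:
    """Zero-phase Butterworth filter cascade applied per channel and trial.

    High-pass at ``hp`` Hz removes DC drift, band-stop notches of ±1 Hz
    around each entry of ``notch`` suppress power-line interference, and a
    low-pass at ``lp`` Hz removes content without neurophysiological
    interest.  All stages are 4th-order Butterworth run forward-backward
    (``sosfiltfilt``) so the phase used downstream is undistorted.
    """
    nyq = x.fs / 2.0
    if not (0 < hp < lp):
        raise ParameterError(f"need 0 < hp < lp, got hp={hp}, lp={lp}")
    if lp >= nyq:
        raise ParameterError(f"lp={lp} Hz must lie below Nyquist {nyq} Hz")
    for f0 in notch:
        if not (1.0 < f0 - 1.0 and f0 + 1.0 < nyq):
            raise ParameterError(f"notch at {f0} Hz outside (1, Nyquist-1)")

    stages = [_butter_sos("highpass", hp, x.fs), _butter_sos("lowpass", lp, x.fs)]
    for f0 in notch:
        stages.append(_butter_sos("bandstop", (f0 - 1.0, f0 + 1.0), x.fs))

    out = x.data
    for sos in stages:
        out = signal.sosfiltfilt(sos, out, axis=1)
    return x.copy_with(data=out)


def baseline_correct(x: EpochedEEG,
                     interval: tuple[float, float] = (-0.2, 0.0)) -> EpochedEEG:
    """Subtract each channel/trial's mean over the prestimulus interval.

    ``interval`` is half-open ``[start, end)`` in seconds relative to
    stimulus onset and must round to at least one sample inside the epoch.
    """
    start, end = interval
    times = x.times
    mask = (times >= start) & (times < end)
    if not mask.any():
        raise ParameterError(
            f"baseline interval [{start}, {end}) contains no samples "
            f"(epoch spans [{times[0]:.3f}, {times[-1]:.3f}])"
        )
    base = x.data[:, mask, :].mean(axis=1, keepdims=True)
    return x.copy_with(data=x.data - base)
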