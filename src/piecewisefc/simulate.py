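"""Synthetic multi-subject oddball EEG with planted phase-lagged couplings.

The generator emulates the structure of an auditory/visual oddball study:
M subjects, C channels, N epoched trials per subject with rare "target"
events (probability 0.2, first two trials of a run always non-target),
epochs spanning [-200, +800] ms around stimulus onset.

Couplings are planted as *narrow-band Gaussian noise* shared between the
two channels of a pair: an independent band-limited realisation per trial,
confined to a time window by a tapered envelope, with the second channel's
copy rotated in phase through the analytic signal.  Trial-to-trial phase
variability therefore comes for free — which is what makes trial-ensemble
phase-lag statistics (PLI/wPLI) non-degenerate — while the *relative* phase
between the two channels is held at the requested lag.  A zero lag
reproduces the signature of volume conduction (identical source seen by two
sensors), which wPLI is designed to ignore.

Ground truth records which (link, condition, window) triples carry a
planted coupling so that selection rules can be scored for sensitivity and
false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .data_model import NONTARGET, TARGET, EpochedEEG, MultiSubjectDataset
from .errors import ParameterError
from .links import link_pairs, n_links, pair_to_link

__all__ = [
    "PlantedCoupling",
    "SimulationParams",
    "GroundTruth",
    "simulate_dataset",
    "zero_lag_control",
]

_COND_CODES = {"target": (TARGET,), "non-target": (NONTARGET,),
               "nontarget": (NONTARGET,), "both": (NONTARGET, TARGET)}


@dataclass(frozen=True)
class PlantedCoupling:
    """A phase-lagged narrow-band coupling between one channel pair.

    ``phase_lag`` (radians) is the phase by which the second channel trails
    the first at ``band_center``; ``window`` is the half-open time interval
    (s, relative to stimulus onset) in which the coupling is active;
    ``condition`` restricts it to target trials, non-target trials or both.
    """

    pair: tuple[int, int]
    band_center: float
    phase_lag: float = np.pi / 2
    window: tuple[float, float] = (0.2, 0.5)
    condition: Literal["target", "non-target", "both"] = "target"

    def __post_init__(self):
        if self.pair[0] == self.pair[1]:
            raise ParameterError("coupled channels must be distinct")
        if self.condition not in _COND_CODES:
            raise ParameterError(f"unknown condition {self.condition!r}")
        if self.window[0] >= self.window[1]:
            raise ParameterError(f"empty coupling window {self.window}")


@dataclass
class SimulationParams:
    """Study-geometry and coupling parameters for the generator.

    Defaults mirror the oddball recording setup this generator emulates:
    17 subjects, 34 channels, 375 trials at target probability 0.2, 1 kHz
    sampling, epochs from -200 to +800 ms.  ``snr`` is the amplitude ratio
    of a planted oscillation to the unit-variance sensor noise;
    ``subject_jitter`` is the log-scale s.d. of a per-subject multiplier on
    coupling amplitude, emulating between-subject variability.
    """

    M: int = 17
    C: int = 34
    N: int = 375
    fs: float = 1000.0
    epoch: tuple[float, float] = (-0.2, 0.8)
    target_prob: float = 0.2
    couplings: Sequence[PlantedCoupling] = field(default_factory=list)
    noise_model: str = "white"  # "white", "ar1", "pink"
    ar1_rho: float = 0.95
    snr: float = 2.0
    mixing: np.ndarray | None = None
    subject_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.target_prob < 1):
            raise ParameterError("target_prob must be in (0, 1)")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
        if self.M < 2 or self.C < 2 or self.N < 4:
            raise ParameterError("need M >= 2, C >= 2, N >= 4")
        if self.epoch[0] >= self.epoch[1]:
            raise ParameterError("empty epoch")
        for cp in self.couplings:
            if cp.window[0] < self.epoch[0] or cp.window[1] > self.epoch[1]:
                raise ParameterError(
                    f"coupling window {cp.window} outside epoch {self.epoch}"
                )
            if not (0 <= cp.pair[0] < self.C and 0 <= cp.pair[1] < self.C):
                raise ParameterError(f"coupling pair {cp.pair} outside C={self.C}")
            if not (0 < cp.band_center < self.fs / 2):
                raise ParameterError("band_center must lie below Nyquist")
        if self.mixing is not None:
            mix = np.asarray(self.mixing, dtype=float)
            if mix.shape != (self.C, self.C):
                raise ParameterError(f"mixing must be {self.C}x{self.C}")
            if abs(np.linalg.det(mix)) < 1e-12:
                raise ParameterError("mixing matrix must be invertible")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch[1] - self.epoch[0]) * self.fs))

    @property
    def times(self) -> np.ndarray:
        return self.epoch[0] + np.arange(self.n_samples) / self.fs


@dataclass
class GroundTruth:
    """Which links carry planted couplings, for scoring selection rules."""

    n_channels: int
    couplings: tuple[PlantedCoupling, ...]

    def link_mask(self, condition: str | None = None) -> np.ndarray:
        """(V,) boolean mask of planted links, optionally per condition."""
        mask = np.zeros(n_links(self.n_channels), dtype=bool)
        for cp in self.couplings:
            if condition is not None and cp.condition not in (condition, "both"):
                continue
            mask[pair_to_link(*cp.pair, self.n_channels)] = True
        return mask

    def window_link_mask(self, intervals: Sequence[tuple[float, float]],
                         condition: str | None = None) -> np.ndarray:
        """(n_windows, V) mask: link planted and its coupling overlaps window."""
        V = n_links(self.n_channels)
        out = np.zeros((len(intervals), V), dtype=bool)
        for cp in self.couplings:
            if condition is not None and cp.condition not in (condition, "both"):
                continue
            v = pair_to_link(*cp.pair, self.n_channels)
            for i, (a, b) in enumerate(intervals):
                if cp.window[0] < b and cp.window[1] > a:
                    out[i, v] = True
        return out


def _draw_labels(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Bernoulli(p) labels, first two forced non-target, >= 2 per condition."""
    while True:
        labels = (rng.random(n) < p).astype(int)
        labels[:2] = NONTARGET
        if (labels == TARGET).sum() >= 2 and (labels == NONTARGET).sum() >= 2:
            return labels


def _noise(rng: np.random.Generator, model: str, rho: float,
           shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance noise along the last-but-one (time) axis."""
    w = rng.standard_normal(shape)
    if model == "white":
        return w
    if model == "ar1":
        # x_t = rho x_{t-1} + e_t, scaled to unit marginal variance
        x = sps.lfilter([1.0], [1.0, -rho], w, axis=-2)
        return x * np.sqrt(1.0 - rho ** 2)
    if model == "pink":
        n = shape[-2]
        spec = np.fft.rfft(w, axis=-2)
        f = np.fft.rfftfreq(n)
        scale = np.ones_like(f)
        scale[1:] = 1.0 / np.sqrt(f[1:])
        spec *= scale[(None,) * (len(shape) - 2) + (slice(None), None)]
        x = np.fft.irfft(spec, n=n, axis=-2)
        return x / x.std(axis=-2, keepdims=True)
    raise ParameterError(f"unknown noise model {model!r}")


def _narrowband(rng: np.random.Generator, n: int, fs: float, f0: float,
                half_bw: float = 1.0) -> np.ndarray:
    """One narrow-band Gaussian noise realisation as an analytic signal."""
    lo, hi = max(f0 - half_bw, 0.1), min(f0 + half_bw, fs / 2 - 1e-9)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    # pad so the filter transient does not bias the epoch
    pad = int(round(2 * fs / max(lo, 0.5)))
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
    return sps.hilbert(x)


def _envelope(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Tukey taper supported on the coupling window, zero elsewhere."""
    mask = (times >= window[0]) & (times < window[1])
    env = np.zeros_like(times)
    k = int(mask.sum())
    if k:
        env[mask] = sps.windows.tukey(k, alpha=0.25)
    return env


def simulate_dataset(params: SimulationParams
                     ) -> tuple[MultiSubjectDataset, GroundTruth]:
    """Generate a multi-subject two-condition dataset with known couplings.

    Each subject is independent noise plus, for every planted coupling and
    matching trial, a shared narrow-band oscillation: channel ``a`` receives
    the real part of the analytic realisation, channel ``b`` the real part
    rotated by ``-phase_lag``.  The oscillation is tapered to the coupling
    window, scaled so its RMS inside the window equals ``snr`` times the
    unit noise s.d., and further multiplied by the subject's log-normal
    amplitude jitter.  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    times = params.times
    n_samp = params.n_samples
    subjects = []
    for m in range(params.M):
        labels = _draw_labels(rng, params.N, params.target_prob)
        data = _noise(rng, params.noise_model, params.ar1_rho,
                      (params.C, n_samp, params.N))
        jitter = np.exp(params.subject_jitter * rng.standard_normal(
            len(params.couplings))) if params.couplings else np.empty(0)
        for k, cp in enumerate(params.couplings):
            env = _envelope(times, cp.window)
            support = env > 0
            if not support.any():
                raise ParameterError(
                    f"coupling window {cp.window} contains no samples"
                )
            conds = _COND_CODES[cp.condition]
            amp = params.snr * jitter[k]
            for trial in np.flatnonzero(np.isin(labels, conds)):
                z = _narrowband(rng, n_samp, params.fs, cp.band_center)
                z *= env
                rms = np.sqrt(np.mean(z[support].real ** 2))
                z *= amp / max(rms, 1e-30)
                a, b = cp.pair
                data[a, :, trial] += z.real
                data[b, :, trial] += (z * np.exp(-1j * cp.phase_lag)).real
        subjects.append(EpochedEEG(
            data=data, fs=params.fs, labels=labels,
            channel_names=[f"ch{c:02d}" for c in range(params.C)],
            t0=params.epoch[0], subject_id=f"sub{m:02d}",
        ))
    truth = GroundTruth(params.C, tuple(params.couplings))
    return MultiSubjectDataset(subjects), truth


def zero_lag_control(params: SimulationParams) -> MultiSubjectDataset:
    """Volume-conduction control: zero-lag shared signals and/or mixing.

    All planted couplings must have ``phase_lag = 0`` (both channels then
    receive the *identical* band-limited signal on top of independent
    noise); if ``params.mixing`` is given, the instantaneous mixing matrix
    is applied to every subject's data afterwards.  With an identity mixing
    matrix the output equals :func:`simulate_dataset` under the same seed.
    """
    for cp in params.couplings:
        if cp.phase_lag != 0.0:
            raise ParameterError(
                "zero_lag_control requires phase_lag = 0 for all couplings"
            )
    dataset, _ = simulate_dataset(params)
    if params.mixing is not None:
        mix = np.asarray(params.mixing, dtype=float)
        for sub in dataset:
            sub.data = np.einsum("ij,jtn->itn", mix, sub.data)
    return dataset
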