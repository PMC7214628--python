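"""Trial-ensemble phase-lag statistics from Morlet wavelet coefficients.

The subject-level pipeline is: complex Morlet continuous wavelet transform
per channel/frequency/sample/trial -> per-pair cross-spectrum
``W_c conj(W_c')`` -> phase-lag index (PLI) or weighted phase-lag index
(wPLI) across the trial ensemble -> arithmetic average over the frequency
bins of a rhythm band -> optional subtractive baseline normalisation.

PLI is the absolute mean sign of the cross-spectrum imaginary part across
trials: it measures how consistently one channel leads the other,
regardless of magnitude.  wPLI weights each trial's sign by the magnitude
of the imaginary part, down-weighting near-zero-lag contributions and so
suppressing the spurious instantaneous coupling produced by volume
conduction.  Both lie in [0, 1] by construction.

The wavelet transform is computed in the frequency domain: the spectrum is
multiplied by a one-sided Gaussian of centre ``f0`` and width
``sigma_f = f0 / cycles`` (the Fourier transform of a complex Morlet
wavelet of the given cycle count), which imposes no minimum epoch length.
The gain is unity at the centre frequency, so a pure sinusoid of amplitude
A yields coefficients of modulus A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sfft

from .data_model import BandSpec, EpochedEEG, get_band
from .errors import ParameterError
from .links import link_pairs

__all__ = [
    "WaveletCoefficients",
    "CrossSpectrum",
    "ConnectivitySeries",
    "morlet_cwt",
    "cross_spectrum",
    "pli",
    "wpli",
    "band_average",
    "baseline_normalize_fc",
    "subject_connectivity",
]


@dataclass
class WaveletCoefficients:
    """Complex Morlet coefficients, ``channels x freqs x samples x trials``."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    cycles: float

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not np.all(np.diff(self.freqs) > 0):
            raise ParameterError("frequency grid must be strictly increasing")

    def edge_valid(self) -> np.ndarray:
        """(freqs, samples) mask of samples farther than one wavelet
        e-folding time (sqrt(2) * sigma_t) from either epoch edge."""
        sigma_t = self.cycles / (2 * np.pi * self.freqs)
        efold = np.sqrt(2.0) * sigma_t
        t = self.times
        return ((t[None, :] - t[0]) > efold[:, None]) & \
               ((t[-1] - t[None, :]) > efold[:, None])


@dataclass
class CrossSpectrum:
    """Per-trial cross-spectra, ``links x freqs x samples x trials``.

    Link ``v`` corresponds to the unordered channel pair given by row ``v``
    of :func:`piecewisefc.links.link_pairs`; the value stored for (c, c')
    with c < c' is ``W_c conj(W_c')`` (the value for the swapped order is
    its complex conjugate and is not stored).
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_channels: int
    normalized: bool = False


@dataclass
class ConnectivitySeries:
    """Band-averaged, time-resolved link synchrony for one subject."""

    values: np.ndarray  # (links, samples), in [0, 1]
    times: np.ndarray
    band: BandSpec
    metric: str
    subject_id: str = "subject"
    condition: int | None = None

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ParameterError("values must be links x samples")


def morlet_cwt(x: EpochedEEG, freqs, cycles: float = 7.0) -> WaveletCoefficients:
    """Complex Morlet CWT of every channel and trial on a frequency grid.

    ``cycles`` sets the time/frequency trade-off: the wavelet's temporal
    envelope has s.d. ``cycles / (2 pi f)``.  Values below 3 make the
    "wavelet" too broadband to call a rhythm estimate.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if freqs.size == 0:
        raise ParameterError("empty frequency grid")
    if np.any(freqs <= 0) or np.any(freqs >= x.fs / 2):
        raise ParameterError(
            f"frequencies must lie in (0, {x.fs / 2}) Hz, got {freqs}"
        )
    if cycles < 3:
        raise ParameterError("cycles must be >= 3")
    order = np.argsort(freqs)
    freqs = freqs[order]

    n = x.n_samples
    # pad against circular wrap-around of the slowest wavelet
    sigma_t_max = cycles / (2 * np.pi * freqs.min())
    nfft = sfft.next_fast_len(n + int(np.ceil(10 * sigma_t_max * x.fs)))
    grid = np.fft.fftfreq(nfft, d=1.0 / x.fs)
    X = sfft.fft(x.data, nfft, axis=1)  # (C, nfft, N)

    out = np.empty((x.n_channels, freqs.size, n, x.n_trials), dtype=complex)
    for i, f0 in enumerate(freqs):
        sigma_f = f0 / cycles
        h = np.zeros(nfft)
        pos = grid > 0
        h[pos] = 2.0 * np.exp(-((grid[pos] - f0) ** 2) / (2 * sigma_f ** 2))
        out[:, i] = sfft.ifft(X * h[None, :, None], axis=1)[:, :n, :]
    return WaveletCoefficients(out, freqs, x.times, x.fs, cycles)


def cross_spectrum(W: WaveletCoefficients, normalize: bool = False,
                   trials: np.ndarray | None = None) -> CrossSpectrum:
    """Per-trial cross-spectrum for every unordered channel pair.

    With ``normalize=True`` each value is divided by the product of the
    coefficient magnitudes, reducing it to a pure phase factor; this
    collapses wPLI onto PLI and exists only as an explicit variant.
    ``trials`` optionally restricts the ensemble to a trial subset.
    """
    vals = W.values if trials is None else W.values[..., trials]
    C = vals.shape[0]
    if C < 2:
        raise ParameterError("need at least 2 channels")
    pairs = link_pairs(C)
    S = vals[pairs[:, 0]] * np.conj(vals[pairs[:, 1]])
    if normalize:
        mag = np.abs(S)
        S = np.divide(S, mag, out=np.zeros_like(S), where=mag > 0)
    return CrossSpectrum(S, W.freqs, W.times, C, normalized=normalize)


def _imag(S: "CrossSpectrum | np.ndarray") -> np.ndarray:
    vals = S.values if isinstance(S, CrossSpectrum) else np.asarray(S)
    if vals.shape[-1] < 2:
        warnings.warn("phase-lag statistics over a single trial are degenerate",
                      stacklevel=3)
    return np.imag(vals)


def pli(S: "CrossSpectrum | np.ndarray") -> np.ndarray:
    """Phase-lag index: |E_n{ sgn Im S }| over the trial axis (last)."""
    return np.abs(np.mean(np.sign(_imag(S)), axis=-1))


def wpli(S: "CrossSpectrum | np.ndarray", weight: str = "imag") -> np.ndarray:
    """Weighted phase-lag index: |E_n{Im S}| / E_n{|Im S|}.

    Where every trial's imaginary part is exactly zero (perfect zero-lag
    degeneracy) the denominator vanishes and the result is defined as 0.

    ``weight="magnitude"`` uses the full cross-spectrum modulus as the
    weight (``|E{|S| sgn Im S}| / E{|S|}``) instead of ``|Im S|``.  On a
    unit-normalised cross-spectrum that weight is constant, so this
    variant collapses exactly onto PLI — which is why the default operates
    on the unnormalised cross-spectrum with imaginary-part weighting.
    """
    vals = S.values if isinstance(S, CrossSpectrum) else np.asarray(S)
    im = _imag(S)
    if weight == "imag":
        w = np.abs(im)
    elif weight == "magnitude":
        w = np.abs(vals)
    else:
        raise ParameterError(f"unknown weight {weight!r}")
    num = np.abs(np.mean(w * np.sign(im), axis=-1))
    den = np.mean(w, axis=-1)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def band_average(y: np.ndarray, freqs: np.ndarray,
                 band: "BandSpec | str") -> np.ndarray:
    """Mean over the frequency bins inside [band.lo, band.hi] (closed).

    ``y`` is ``links x freqs x samples``; the result is ``links x samples``.
    """
    band = get_band(band)
    sel = band.contains(np.asarray(freqs, dtype=float))
    if not sel.any():
        raise ParameterError(
            f"no frequency bin inside band {band.name} [{band.lo}, {band.hi}]"
        )
    return np.asarray(y)[:, sel, :].mean(axis=1)


def baseline_normalize_fc(y: ConnectivitySeries,
                          baseline: tuple[float, float] = (-0.2, 0.0),
                          mode: str = "subtract_clip") -> ConnectivitySeries:
    """Subtract each link's baseline-interval mean and clip to [0, 1].

    ``mode="none"`` returns the series unchanged (explicit no-op).
    """
    if mode == "none":
        return y
    if mode != "subtract_clip":
        raise ParameterError(f"unknown normalisation mode {mode!r}")
    start, end = baseline
    mask = (y.times >= start) & (y.times < end)
    if not mask.any():
        raise ParameterError(f"baseline [{start}, {end}) contains no samples")
    base = y.values[:, mask].mean(axis=1, keepdims=True)
    return replace(y, values=np.clip(y.values - base, 0.0, 1.0))


def label_shuffle_surrogates(x: EpochedEEG, pair: tuple[int, int],
                             band: "BandSpec | str",
                             window: tuple[float, float],
                             metric: str = "wpli", n_surrogates: int = 200,
                             cycles: float = 7.0, condition: int = 1,
                             rng: "np.random.Generator | int" = 0) -> dict:
    """Condition-locked synchrony of one pair against label-shuffled nulls.

    The observed statistic is the band- and window-averaged PLI/wPLI over
    the trials of ``condition``; each surrogate recomputes it over an
    equally sized trial set drawn by permuting the labels.  A genuinely
    phase-lagged condition-specific coupling pushes the observed value
    above the surrogate distribution; a zero-lag (volume-conduction-like)
    coupling does not, because the cross-spectrum imaginary part carries
    no consistent sign.

    Returns observed value, surrogate array, their 95th percentile and the
    exceedance flag.
    """
    from .data_model import get_band as _get_band

    band = _get_band(band)
    gen = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    a, b = pair
    sub = x.copy_with(data=x.data[[a, b]],
                      channel_names=(x.channel_names[a], x.channel_names[b]))
    W = morlet_cwt(sub, band_freq_grid(band), cycles)
    im = np.imag(W.values[0] * np.conj(W.values[1]))  # (F, T, N)
    tmask = (x.times >= window[0]) & (x.times < window[1])
    if not tmask.any():
        raise ParameterError(f"window {window} contains no samples")
    im = im[:, tmask, :]

    def stat(sel: np.ndarray) -> float:
        """sel: boolean (N,) trial subset -> band/window-averaged metric."""
        vals = im[..., sel]
        if metric.lower() == "wpli":
            num = np.abs(vals.mean(axis=-1))
            den = np.abs(vals).mean(axis=-1)
            y = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        else:
            y = np.abs(np.sign(vals).mean(axis=-1))
        return float(y.mean())

    observed_sel = x.labels == condition
    observed = stat(observed_sel)
    surrogates = np.empty(n_surrogates)
    for s in range(n_surrogates):
        surrogates[s] = stat(gen.permutation(observed_sel))
    p95 = float(np.percentile(surrogates, 95))
    return {"observed": observed, "surrogates": surrogates,
            "percentile95": p95, "exceeds": bool(observed > p95)}


def _metric_fn(metric: str):
    try:
        return {"pli": pli, "wpli": wpli}[metric.lower()]
    except KeyError:
        raise ParameterError(f"unknown metric {metric!r}") from None


def band_freq_grid(band: "BandSpec | str", spacing: float = 1.0) -> np.ndarray:
    """Integer-spaced frequency grid covering a band (closed edges)."""
    band = get_band(band)
    grid = np.arange(np.ceil(band.lo / spacing) * spacing,
                     band.hi + spacing / 2, spacing)
    return grid


def subject_connectivity(x: EpochedEEG, band: "BandSpec | str",
                         metric: str = "wpli", *, cycles: float = 7.0,
                         freqs: np.ndarray | None = None,
                         split_by_label: bool = True,
                         match_trials: bool = True,
                         rng: "np.random.Generator | int | None" = 0,
                         normalize_cross: bool = False,
                         baseline: tuple[float, float] | None = None,
                         ) -> "dict[int, ConnectivitySeries] | ConnectivitySeries":
    """One subject's band-averaged connectivity series, per condition.

    With ``split_by_label`` the trial ensemble is split by condition before
    the phase-lag statistic is computed, so each condition's synchrony is
    estimated from its own trials.  Because PLI/wPLI are positively biased
    at small trial counts and the bias depends on the count, the larger
    condition is by default subsampled (``match_trials``) to the size of
    the smaller one, keeping the two estimates comparable; the subsample is
    drawn from ``rng`` for reproducibility.

    Returns ``{condition_code: ConnectivitySeries}`` when splitting, else a
    single pooled series.
    """
    band = get_band(band)
    if freqs is None:
        freqs = band_freq_grid(band)
    W = morlet_cwt(x, freqs, cycles)
    fn = _metric_fn(metric)

    def series(trials, condition):
        S = cross_spectrum(W, normalize=normalize_cross, trials=trials)
        cs = ConnectivitySeries(
            values=band_average(fn(S), W.freqs, band), times=x.times,
            band=band, metric=metric.lower(), subject_id=x.subject_id,
            condition=condition,
        )
        if baseline is not None:
            cs = baseline_normalize_fc(cs, baseline)
        return cs

    if not split_by_label:
        return series(None, None)

    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    groups = {c: x.trials_of(c) for c in sorted(set(x.labels.tolist()))}
    if match_trials and len(groups) > 1:
        k = min(len(idx) for idx in groups.values())
        groups = {c: np.sort(gen.choice(idx, size=k, replace=False))
                  for c, idx in groups.items()}
    return {c: series(idx, c) for c, idx in groups.items()}
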