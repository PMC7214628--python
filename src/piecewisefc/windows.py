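"""Quasi-stationary window schemes and per-window connectivity reduction.

Time-resolved link synchrony fluctuates; under the assumption that the
underlying network is stationary within short intervals, the epoch is
split into ordered, non-overlapping, contiguous windows and each link's
synchrony is reduced to its within-window expectation.  Windows come in
three kinds: ``fixed`` (equal length tau, remainder absorbed by the last
window), ``variable`` (delimited by externally supplied change points,
e.g. from the classifier-curve segmentation) and ``whole`` (a single
window spanning the extent — the stationary baseline).

All intervals are half-open ``[start, end)`` in seconds, so every sample
belongs to exactly one window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectivity import ConnectivitySeries
from .data_model import BandSpec
from .errors import ParameterError

__all__ = [
    "WindowScheme",
    "WindowedConnectivity",
    "make_fixed_windows",
    "make_variable_windows",
    "whole_window",
    "window_expectation",
    "stack_windowed",
]

_EPS = 1e-9


@dataclass(frozen=True)
class WindowScheme:
    """Ordered, contiguous, non-overlapping intervals covering an extent."""

    intervals: tuple[tuple[float, float], ...]
    kind: str = "fixed"  # fixed | variable | whole

    def __post_init__(self):
        if len(self.intervals) < 1:
            raise ParameterError("a window scheme needs at least one window")
        for (a, b) in self.intervals:
            if b <= a:
                raise ParameterError(f"empty window [{a}, {b})")
        for (_, b), (a2, _) in zip(self.intervals, self.intervals[1:]):
            if abs(b - a2) > _EPS:
                raise ParameterError("windows must be contiguous and ordered")

    @property
    def n_windows(self) -> int:
        return len(self.intervals)

    @property
    def extent(self) -> tuple[float, float]:
        return (self.intervals[0][0], self.intervals[-1][1])

    def sample_assignment(self, times: np.ndarray) -> np.ndarray:
        """Window index per sample; -1 for samples outside the extent."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, -1, dtype=int)
        for i, (a, b) in enumerate(self.intervals):
            last = i == len(self.intervals) - 1
            inside = (times >= a - _EPS) & (
                (times <= b + _EPS) if last else (times < b - _EPS)
            )
            out[inside & (out == -1)] = i
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"kind": self.kind,
                       "intervals": [list(iv) for iv in self.intervals]}, f,
                      indent=2)

    @classmethod
    def from_json(cls, path) -> "WindowScheme":
        with open(path) as f:
            obj = json.load(f)
        return cls(tuple(tuple(iv) for iv in obj["intervals"]),
                   obj.get("kind", "variable"))


def make_fixed_windows(extent: tuple[float, float], tau: float) -> WindowScheme:
    """Equal windows of length ``tau``; the remainder (if any) is absorbed
    into the final window so no sample is dropped."""
    start, end = extent
    length = end - start
    if tau <= 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    if tau > length + _EPS:
        raise ParameterError(f"tau={tau} exceeds extent length {length}")
    n = int(np.floor(length / tau + _EPS))
    edges = [start + i * tau for i in range(n)] + [end]
    return WindowScheme(tuple((edges[i], edges[i + 1]) for i in range(n)),
                        kind="fixed" if n > 1 else "whole")


def make_variable_windows(change_points: Sequence[float],
                          extent: tuple[float, float]) -> WindowScheme:
    """Windows delimited by the extent edges and the given change points."""
    start, end = extent
    cps = sorted(float(c) for c in change_points)
    if len(set(cps)) != len(cps):
        raise ParameterError("change points must be distinct")
    for c in cps:
        if not (start < c < end):
            raise ParameterError(f"change point {c} outside extent {extent}")
    edges = [start] + cps + [end]
    kind = "variable" if cps else "whole"
    return WindowScheme(tuple((edges[i], edges[i + 1])
                              for i in range(len(edges) - 1)), kind=kind)


def whole_window(extent: tuple[float, float]) -> WindowScheme:
    """Single window over the full extent (stationary baseline, tau = T)."""
    return WindowScheme((tuple(extent),), kind="whole")


@dataclass
class WindowedConnectivity:
    """Per-window representative connectivity across subjects.

    ``values`` is ``(subjects, windows, links)`` when unlabelled or
    ``(subjects, windows, links, conditions)`` when split by label, with
    the condition axis ordered by ``conditions`` (e.g. ``(0, 1)`` =
    non-target, target).
    """

    values: np.ndarray
    scheme: WindowScheme
    band: BandSpec | None = None
    conditions: tuple[int, ...] | None = None
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self):
        expect = 3 if self.conditions is None else 4
        if self.values.ndim != expect:
            raise ParameterError(
                f"values must have {expect} axes, got {self.values.ndim}"
            )
        if self.values.shape[1] != self.scheme.n_windows:
            raise ParameterError("window axis does not match the scheme")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def n_links(self) -> int:
        return self.values.shape[2]

    def condition_values(self, condition: int) -> np.ndarray:
        """(subjects, windows, links) slice for one condition code."""
        if self.conditions is None:
            raise ParameterError("this windowed connectivity is unlabelled")
        return self.values[..., self.conditions.index(condition)]

    def pooled(self) -> np.ndarray:
        """(subjects, windows, links); mean over conditions if labelled."""
        if self.conditions is None:
            return self.values
        return self.values.mean(axis=-1)


def window_expectation(series: ConnectivitySeries,
                       scheme: WindowScheme) -> np.ndarray:
    """Per-window mean of a link x samples series -> ``(windows, links)``.

    Every window must contain at least one sample of ``series.times``.
    """
    assign = scheme.sample_assignment(series.times)
    out = np.empty((scheme.n_windows, series.values.shape[0]))
    for i in range(scheme.n_windows):
        sel = assign == i
        if not sel.any():
            raise ParameterError(
                f"window {scheme.intervals[i]} contains no samples"
            )
        out[i] = series.values[:, sel].mean(axis=1)
    return out


def stack_windowed(per_subject: Sequence["dict[int, ConnectivitySeries] | ConnectivitySeries"],
                   scheme: WindowScheme) -> WindowedConnectivity:
    """Assemble per-subject (optionally per-condition) series into one
    :class:`WindowedConnectivity` array."""
    first = per_subject[0]
    if isinstance(first, dict):
        conds = tuple(sorted(first.keys()))
        vals = np.stack([
            np.stack([window_expectation(sub[c], scheme) for c in conds],
                     axis=-1)
            for sub in per_subject
        ])
        band = first[conds[0]].band
        ids = tuple(sub[conds[0]].subject_id for sub in per_subject)
        return WindowedConnectivity(vals, scheme, band, conds, ids)
    vals = np.stack([window_expectation(sub, scheme) for sub in per_subject])
    return WindowedConnectivity(vals, scheme, first.band, None,
                                tuple(s.subject_id for s in per_subject))
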