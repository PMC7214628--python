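"""Enumeration of unordered channel pairs ("links").

A graph over ``C`` channels has ``V = C*(C-1)/2`` undirected links.  Links
are enumerated lexicographically: (0,1), (0,2), ..., (0,C-1), (1,2), ...
This fixed order is shared by every module that indexes link-wise arrays.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError


def n_links(n_channels: int) -> int:
    """Number of unordered channel pairs V = C(C-1)/2."""
    if n_channels < 2:
        raise ParameterError(f"need at least 2 channels, got {n_channels}")
    return n_channels * (n_channels - 1) // 2


def link_pairs(n_channels: int) -> np.ndarray:
    """(V, 2) int array of channel index pairs (a < b), lexicographic."""
    a, b = np.triu_indices(n_channels, k=1)
    return np.column_stack([a, b])


def pair_to_link(a: int, b: int, n_channels: int) -> int:
    """Index of the unordered pair (a, b) in the lexicographic enumeration."""
    if a == b:
        raise ParameterError("self-pairs are not links")
    if not (0 <= a < n_channels and 0 <= b < n_channels):
        raise ParameterError(f"channel out of range for C={n_channels}")
    if a > b:
        a, b = b, a
    # links before row a: sum_{r<a} (C-1-r); offset within row: b - a - 1
    return a * (2 * n_channels - a - 1) // 2 + (b - a - 1)


def incidence_matrix(n_channels: int) -> np.ndarray:
    """(C, V) binary matrix; entry (c, v) = 1 iff channel c is an endpoint of v."""
    pairs = link_pairs(n_channels)
    inc = np.zeros((n_channels, len(pairs)), dtype=float)
    inc[pairs[:, 0], np.arange(len(pairs))] = 1.0
    inc[pairs[:, 1], np.arange(len(pairs))] = 1.0
    return inc
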