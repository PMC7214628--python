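"""Relevance-masked group-level brain graphs and their summaries.

Once a binary relevance vector ``kappa`` over the V = C(C-1)/2 links has
been selected, the group-level graph at time t carries, on every retained
link, the connectivity summed over subjects.  Node strength is the
weighted sum of a channel's retained incident links; "unfolding" maps the
link-level strengths onto the channel space.  Network density is the
fraction of possible links retained.  The leave-subjects-out consistency
analysis re-runs the supervised selection on random subject subsets and
books which links appear or disappear relative to the full-set graph.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .links import incidence_matrix, link_pairs, n_links
from .relevance import RelevanceMask, confidence_summary, psth
from .windows import WindowedConnectivity

__all__ = [
    "node_strength_links",
    "unfold_to_channels",
    "network_density",
    "channel_relevance_counts",
    "consistency_under_subtraction",
    "adjacency_matrix",
    "write_adjacency",
    "write_node_strength",
    "edge_list",
]


def _mask_array(kappa) -> np.ndarray:
    if isinstance(kappa, RelevanceMask):
        return kappa.values
    return np.asarray(kappa, dtype=bool)


def node_strength_links(y_subjects, kappa, normalize: bool = False
                        ) -> np.ndarray:
    """Link-level strength ``gamma(v, t) = kappa(v) * sum_m y_m(v, t)``.

    ``y_subjects`` is an ``(M, V, T)`` array or a sequence of per-subject
    ``(V, T)`` arrays / ConnectivitySeries.  ``normalize`` divides by M
    (mean instead of sum over subjects; scale only).
    """
    if not isinstance(y_subjects, np.ndarray):
        y_subjects = np.stack([
            s.values if hasattr(s, "values") else np.asarray(s)
            for s in y_subjects
        ])
    kappa = _mask_array(kappa)
    if kappa.ndim != 1 or kappa.shape[0] != y_subjects.shape[1]:
        raise ParameterError(
            f"mask length {kappa.shape} does not match link axis "
            f"{y_subjects.shape[1]}"
        )
    total = y_subjects.sum(axis=0)
    if normalize:
        total = total / y_subjects.shape[0]
    return kappa[:, None] * total


def unfold_to_channels(gamma_links: np.ndarray, n_channels: int) -> np.ndarray:
    """Channel-level strength: sum of a channel's incident link strengths.

    Satisfies the handshake identity
    ``sum_c gamma(c, t) = 2 sum_v gamma(v, t)``.
    """
    gamma_links = np.asarray(gamma_links)
    if gamma_links.shape[0] != n_links(n_channels):
        raise ParameterError(
            f"{gamma_links.shape[0]} links inconsistent with C={n_channels}"
        )
    return incidence_matrix(n_channels) @ gamma_links


def network_density(kappa) -> "float | np.ndarray":
    """Selected links over all possible links, D = |kappa| / V.

    For a stack of masks (windows or subjects on the leading axis) the
    density is returned per row.
    """
    kappa = _mask_array(kappa)
    dens = kappa.mean(axis=-1)
    return float(dens) if np.ndim(dens) == 0 else dens


def channel_relevance_counts(kappa, n_channels: int) -> np.ndarray:
    """How many selected links touch each channel (per mask row).

    This is the per-channel "significant node" count used for topographic
    export: input ``(V,)`` or ``(rows, V)``, output ``(C,)`` or
    ``(rows, C)`` integer counts.
    """
    kappa = _mask_array(kappa).astype(float)
    counts = (incidence_matrix(n_channels) @ kappa.T).T
    return counts.astype(int)


def adjacency_matrix(values: np.ndarray, n_channels: int) -> np.ndarray:
    """Symmetric (C, C) matrix from link-indexed ``values`` (V,)."""
    values = np.asarray(values, dtype=float)
    pairs = link_pairs(n_channels)
    adj = np.zeros((n_channels, n_channels))
    adj[pairs[:, 0], pairs[:, 1]] = values
    adj[pairs[:, 1], pairs[:, 0]] = values
    return adj


def write_adjacency(path, values: np.ndarray, channel_names: Sequence[str]
                    ) -> None:
    """Whitespace-delimited symmetric adjacency with a channel-name header."""
    adj = adjacency_matrix(values, len(channel_names))
    with open(path, "w") as f:
        f.write(" ".join(channel_names) + "\n")
        for row in adj:
            f.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def write_node_strength(path, gamma_channels: np.ndarray, times: np.ndarray,
                        channel_names: Sequence[str]) -> None:
    """Long-format TSV: time, channel, gamma."""
    C, T = gamma_channels.shape
    df = pd.DataFrame({
        "time": np.repeat(np.asarray(times), C),
        "channel": np.tile(list(channel_names), T),
        "gamma": gamma_channels.T.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def edge_list(full_mask, other_mask, weights: np.ndarray,
              channel_names: Sequence[str]) -> pd.DataFrame:
    """Connectogram bookkeeping relative to a reference graph.

    Status per link present in either mask: ``stable`` (in both),
    ``appeared`` (only in the new mask), ``disappeared`` (only in the
    reference).
    """
    full = _mask_array(full_mask)
    other = _mask_array(other_mask)
    pairs = link_pairs(len(channel_names))
    rows = []
    for v in np.flatnonzero(full | other):
        status = ("stable" if full[v] and other[v]
                  else "appeared" if other[v] else "disappeared")
        rows.append({
            "ch_a": channel_names[pairs[v, 0]],
            "ch_b": channel_names[pairs[v, 1]],
            "weight": float(weights[v]),
            "status": status,
        })
    return pd.DataFrame(rows, columns=["ch_a", "ch_b", "weight", "status"])


def consistency_under_subtraction(wc: WindowedConnectivity,
                                  alpha: float = 0.05, leave_out: int = 1,
                                  permutations: int = 10,
                                  rng: "np.random.Generator | int" = 0,
                                  family: str = "per_window") -> dict:
    """Leave-subjects-out stability of the supervised group-level graph.

    Re-runs the full supervised selection (across-subject and
    across-window tests plus their combination) on ``permutations`` random
    subsets of ``M - leave_out`` subjects and compares each subset's
    combined relevance vector with the full-set one, reporting densities,
    confidence summaries and the appearing/disappearing link sets.
    """
    M = wc.n_subjects
    if leave_out < 0 or leave_out >= M:
        raise ParameterError(f"leave_out must lie in [0, {M - 1}]")
    if M - leave_out < 4:
        raise ParameterError("need at least 4 retained subjects")
    gen = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)

    full = psth(wc, alpha, family=family)
    full_mask = full["combined"].values
    scenarios = []
    n_perm = 1 if leave_out == 0 else permutations
    retained = np.zeros(wc.n_links)
    for _ in range(n_perm):
        keep = (np.arange(M) if leave_out == 0 else
                np.sort(gen.choice(M, size=M - leave_out, replace=False)))
        sub_wc = WindowedConnectivity(
            wc.values[keep], wc.scheme, wc.band, wc.conditions,
            tuple(wc.subject_ids[i] for i in keep) if wc.subject_ids else (),
        )
        res = psth(sub_wc, alpha, family=family)
        mask = res["combined"].values
        retained += (mask & full_mask)
        scenarios.append({
            "subjects": keep.tolist(),
            "mask": mask,
            "density": network_density(mask),
            "appeared": np.flatnonzero(mask & ~full_mask).tolist(),
            "disappeared": np.flatnonzero(full_mask & ~mask).tolist(),
            "confidence": confidence_summary(res["tests_windows"],
                                             res["combined"]),
        })
    denom = max(int(full_mask.sum()), 1)
    return {
        "full_mask": full_mask,
        "full_density": network_density(full_mask),
        "full_confidence": confidence_summary(full["tests_windows"],
                                              full["combined"]),
        "leave_out": leave_out,
        "scenarios": scenarios,
        "link_retention": retained / n_perm,
        "mean_retention_of_full_links": float(
            (retained / n_perm)[full_mask].mean()) if full_mask.any() else 1.0,
        "_denom_full_links": denom,
    }
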