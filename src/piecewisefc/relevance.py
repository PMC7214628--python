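"""Link-selection rules for piecewise group-level connectivity.

Two families of rules turn windowed connectivity into binary link
relevance masks:

* the **unsupervised amplitude rule** (piecewise: *pUTh*; stationary:
  *UTh*) keeps, per window, every link whose across-subject mean
  connectivity reaches a fraction ``q`` of the strongest link's mean;

* the **supervised statistical rule** (*pSTh* / *STh*) tests, per link,
  whether target and non-target connectivity differ — across subjects
  within each window, and across windows within each subject — with a
  two-sided Mann-Whitney U test followed by Benjamini-Hochberg FDR
  correction across links.

The per-window masks (one per window) and per-subject masks (one per
subject) are then combined into a single group-level relevance vector:
OR over windows AND OR over subjects, so a link must show a label effect
in at least one window *and* in at least one subject's window dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import NONTARGET, TARGET
from .errors import ParameterError, ValidationError
from .links import link_pairs
from .windows import WindowedConnectivity

__all__ = [
    "RelevanceMask",
    "mannwhitney_p",
    "fdr_bh",
    "puth",
    "psth_across_subjects",
    "psth_across_windows",
    "combine_relevance",
    "psth",
    "confidence_summary",
    "export_link_table",
]

#: exact enumeration is used up to this combined sample size (no ties)
_EXACT_LIMIT = 16


@dataclass
class RelevanceMask:
    """Binary link relevance with its provenance.

    ``values`` is ``(V,)`` for a combined mask, ``(n_windows, V)`` for
    per-window masks or ``(n_subjects, V)`` for per-subject masks; ``axis``
    names which.  ``threshold`` is the governing alpha (supervised) or
    amplitude cut-off q (unsupervised).
    """

    values: np.ndarray
    axis: str  # "window" | "subject" | "combined"
    rule: str  # "psth" | "puth"
    threshold: float
    band: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)

    def any_link(self) -> np.ndarray:
        """OR over the leading axis -> (V,)."""
        return self.values if self.values.ndim == 1 else self.values.any(axis=0)


def mannwhitney_p(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample ``a``, p).

    The exact null enumeration is used when the combined sample size is at
    most 16 and there are no ties; otherwise the normal approximation with
    midrank tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs at least 2 observations")
    combined = np.concatenate([a, b])
    ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= _EXACT_LIMIT and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fdr_bh(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level ``alpha``.

    A p-value equal to its step-up threshold is rejected (<= convention).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject


def _windowed_values(wc) -> np.ndarray:
    if isinstance(wc, WindowedConnectivity):
        return wc.pooled()
    return np.asarray(wc, dtype=float)


def puth(wc, q: float = 0.7) -> RelevanceMask:
    """Unsupervised amplitude thresholding, per window.

    For each window ``i`` the across-subject mean connectivity is computed
    per link; links whose mean reaches ``q`` times the maximum mean over
    links are selected.  ``q`` is a cut-off in [0, 1] (heuristically 0.7;
    sensible sweep range 0.4-0.9): larger q keeps fewer links.
    """
    if not (0.0 <= q <= 1.0):
        raise ParameterError(f"q must lie in [0, 1], got {q}")
    vals = _windowed_values(wc)  # (M, N_w, V)
    group_mean = vals.mean(axis=0)  # (N_w, V)
    thresh = q * group_mean.max(axis=1, keepdims=True)
    mask = group_mean >= thresh
    band = wc.band if isinstance(wc, WindowedConnectivity) else None
    return RelevanceMask(mask, axis="window", rule="puth", threshold=q,
                         band=band)


def _mw_table(a_vals: np.ndarray, b_vals: np.ndarray, alpha: float,
              family: str, unit: str) -> tuple[np.ndarray, pd.DataFrame]:
    """Mann-Whitney + BH-FDR over a (groups, V) layout.

    ``a_vals``/``b_vals``: (n_groups, n_units, V) where the test runs over
    the unit axis within each (group, link) cell; FDR families are links
    within a group (``family='per_group'``) or all cells (``'global'``).
    """
    n_groups, _, V = a_vals.shape
    U = np.empty((n_groups, V))
    p = np.empty((n_groups, V))
    for g in range(n_groups):
        for v in range(V):
            U[g, v], p[g, v] = mannwhitney_p(a_vals[g, :, v], b_vals[g, :, v])
    if family == "global":
        reject = fdr_bh(p.ravel(), alpha).reshape(p.shape)
        qv = _bh_qvalues(p.ravel()).reshape(p.shape)
    else:
        reject = np.stack([fdr_bh(p[g], alpha) for g in range(n_groups)])
        qv = np.stack([_bh_qvalues(p[g]) for g in range(n_groups)])
    tests = pd.DataFrame({
        unit: np.repeat(np.arange(n_groups), V),
        "link": np.tile(np.arange(V), n_groups),
        "U": U.ravel(),
        "p": p.ravel(),
        "q_value": qv.ravel(),
        "n_target": a_vals.shape[1],
        "n_nontarget": b_vals.shape[1],
        "kappa": reject.ravel().astype(int),
    })
    return reject, tests


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    _, qv, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
    return np.minimum(qv, 1.0)


def psth_across_subjects(wc: WindowedConnectivity, alpha: float = 0.05,
                         family: str = "per_window"
                         ) -> tuple[RelevanceMask, pd.DataFrame]:
    """Supervised rule across subjects: one mask per window.

    For each (window, link), target and non-target windowed connectivity
    values are compared across the M subjects (two samples of size M);
    BH-FDR runs across the V links within each window (``family``
    ``"per_window"``, the default) or over all windows at once
    (``"global"``).
    """
    if wc.conditions is None:
        raise ValidationError("labelled windowed connectivity required")
    if wc.n_subjects < 4:
        raise ParameterError("across-subject testing needs M >= 4")
    tgt = wc.condition_values(TARGET)      # (M, N_w, V)
    non = wc.condition_values(NONTARGET)
    fam = "per_group" if family == "per_window" else family
    reject, tests = _mw_table(tgt.transpose(1, 0, 2), non.transpose(1, 0, 2),
                              alpha, fam, unit="window")
    mask = RelevanceMask(reject, axis="window", rule="psth", threshold=alpha,
                         band=wc.band)
    return mask, tests


def psth_across_windows(wc: WindowedConnectivity, alpha: float = 0.05,
                        family: str = "per_subject"
                        ) -> tuple[RelevanceMask, pd.DataFrame]:
    """Supervised rule across windows: one mask per subject.

    For each (subject, link), the target and non-target window series
    (length N_tau) are compared; at least 3 windows are required for the
    test to have any power.  Windows are treated as exchangeable units
    even though neighbouring windows are serially correlated — the FDR
    correction is the acknowledged mitigation, not a cure.
    """
    if wc.conditions is None:
        raise ValidationError("labelled windowed connectivity required")
    if wc.n_windows < 3:
        raise ParameterError("across-window testing needs at least 3 windows")
    tgt = wc.condition_values(TARGET)      # (M, N_w, V)
    non = wc.condition_values(NONTARGET)
    fam = "per_group" if family == "per_subject" else family
    reject, tests = _mw_table(tgt, non, alpha, fam, unit="subject")
    mask = RelevanceMask(reject, axis="subject", rule="psth", threshold=alpha,
                         band=wc.band)
    return mask, tests


def combine_relevance(window_masks, subject_masks) -> RelevanceMask:
    """Group-level combination: (OR over windows) AND (OR over subjects)."""
    wm = window_masks.values if isinstance(window_masks, RelevanceMask) \
        else np.asarray(window_masks, dtype=bool)
    sm = subject_masks.values if isinstance(subject_masks, RelevanceMask) \
        else np.asarray(subject_masks, dtype=bool)
    wm = np.atleast_2d(wm)
    sm = np.atleast_2d(sm)
    if wm.shape[1] != sm.shape[1]:
        raise ParameterError(
            f"link dimensions differ: {wm.shape[1]} vs {sm.shape[1]}"
        )
    combined = wm.any(axis=0) & sm.any(axis=0)
    thr = window_masks.threshold if isinstance(window_masks, RelevanceMask) else np.nan
    band = window_masks.band if isinstance(window_masks, RelevanceMask) else None
    return RelevanceMask(combined, axis="combined", rule="psth",
                         threshold=thr, band=band)


def psth(wc: WindowedConnectivity, alpha: float = 0.05,
         family: str = "per_window") -> dict:
    """Full supervised piecewise pipeline on one band's windowed values.

    Returns a dict with the per-window masks, per-subject masks, their
    test tables and the combined group-level relevance vector.
    """
    window_masks, tests_w = psth_across_subjects(wc, alpha, family=family)
    subject_masks, tests_s = psth_across_windows(wc, alpha)
    combined = combine_relevance(window_masks, subject_masks)
    return {
        "window_masks": window_masks,
        "subject_masks": subject_masks,
        "combined": combined,
        "tests_windows": tests_w,
        "tests_subjects": tests_s,
    }


def confidence_summary(tests: pd.DataFrame,
                       mask: RelevanceMask | None = None) -> dict:
    """Minimum / median / maximum p over (selected) links.

    With no mask, or an empty selection, the summary covers all tested
    links, mirroring how a confidence sweep reports windows where nothing
    survives.
    """
    p = tests["p"].to_numpy()
    if mask is not None:
        sel_links = np.flatnonzero(mask.any_link())
        sel = tests["link"].isin(sel_links).to_numpy()
        if sel.any():
            p = p[sel]
    return {"min_p": float(np.min(p)), "median_p": float(np.median(p)),
            "max_p": float(np.max(p)), "n_tests": int(p.size)}


def export_link_table(path, wc: WindowedConnectivity, tests: pd.DataFrame,
                      channel_names) -> pd.DataFrame:
    """Write the per-(window, link) TSV summary table.

    Columns: band, window_start, window_end, ch_a, ch_b, group mean per
    condition, U, p, q_value, kappa.
    """
    pairs = link_pairs(len(channel_names))
    tab = tests.copy()
    iv = np.array(wc.scheme.intervals)
    tab["band"] = wc.band.name if wc.band is not None else ""
    tab["window_start"] = iv[tab["window"], 0]
    tab["window_end"] = iv[tab["window"], 1]
    tab["ch_a"] = [channel_names[pairs[v, 0]] for v in tab["link"]]
    tab["ch_b"] = [channel_names[pairs[v, 1]] for v in tab["link"]]
    gm_t = wc.condition_values(TARGET).mean(axis=0)
    gm_n = wc.condition_values(NONTARGET).mean(axis=0)
    tab["group_mean_target"] = gm_t[tab["window"], tab["link"]]
    tab["group_mean_nontarget"] = gm_n[tab["window"], tab["link"]]
    cols = ["band", "window_start", "window_end", "ch_a", "ch_b",
            "group_mean_target", "group_mean_nontarget", "U", "p",
            "q_value", "kappa"]
    tab[cols].to_csv(path, sep="\t", index=False)
    return tab[cols]
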