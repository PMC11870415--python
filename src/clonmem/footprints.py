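"""Memory-footprint calls and TF-family co-binding statistics.

A *memory footprint* is a 10-bp-binned TF binding site whose (quantile-
transformed) footprint score changes by at least 0.2 between a condition and
its control — a gain for memory formation, a loss for inhibitor response.
Co-binding of a partner family with the reference family (AP-1) is
quantified at the peak level: peaks are cross-tabulated as carrying memory
sites of both families, the first only, the second only, or neither, and the
log2 odds ratio of that 2x2 table is reported, followed by a 10th-90th
percentile normalization of positive and negative log-ORs separately onto
[0, 1] and [-1, 0].
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

__all__ = ["call_memory_sites", "cobinding_matrix", "normalize_cobinding",
           "nearest_reference_distance", "footprint_performance_curve"]


def call_memory_sites(sites: pd.DataFrame, condition: str, control: str,
                      threshold: float = 0.2,
                      direction: str = "gain") -> pd.Series:
    """Boolean memory call per site: score change >= threshold (gain) or
    <= -threshold (loss); the threshold is inclusive ("minimum change")."""
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    delta = sites[f"score_{condition}"] - sites[f"score_{control}"]
    return delta >= threshold if direction == "gain" else delta <= -threshold


def cobinding_matrix(sites: pd.DataFrame, memory: pd.Series,
                     reference: str = "AP1", families=None,
                     peak_universe=None) -> pd.DataFrame:
    """Peak-level co-binding log2 odds ratios for every family pair.

    For each unordered pair, peaks are labeled both / first-only /
    second-only / neither by memory-site content and the odds ratio
    ``both * neither / (first_only * second_only)`` is log2-transformed
    (Haldane +0.5 correction applied to every cell when any cell is zero).
    ``peak_universe`` is the full set of analyzed peaks entering the
    "neither" cell; it defaults to the peaks present in ``sites``, but
    callers holding the complete peak list should pass it — restricting the
    universe to site-bearing peaks biases the odds ratio.  Returns a tidy
    DataFrame (family_a, family_b, log2_or, plus the table cells); rows
    exist for both orders of each pair and the matrix is exactly symmetric.
    """
    if families is None:
        families = sorted(sites["family"].unique())
    peaks = (sites["peak_id"].unique() if peak_universe is None
             else np.asarray(peak_universe))
    n_peaks = len(peaks)
    has_memory = {
        fam: set(sites.loc[memory & (sites["family"] == fam), "peak_id"])
        for fam in families}

    rows = []
    for fa, fb in itertools.combinations(families, 2):
        a, b = has_memory[fa], has_memory[fb]
        both = len(a & b)
        only_a = len(a - b)
        only_b = len(b - a)
        neither = n_peaks - both - only_a - only_b
        cells = np.array([both, only_a, only_b, neither], dtype=float)
        if np.any(cells == 0):
            cells = cells + 0.5
        log2_or = float(np.log2(cells[0] * cells[3] / (cells[1] * cells[2])))
        for x, y in ((fa, fb), (fb, fa)):
            rows.append({"family_a": x, "family_b": y, "log2_or": log2_or,
                         "both": both, "first_only": only_a if x == fa else only_b,
                         "second_only": only_b if x == fa else only_a,
                         "neither": neither, "reference": reference})
    return pd.DataFrame(rows)


def normalize_cobinding(log2_ors: np.ndarray | pd.Series,
                        pool: np.ndarray | pd.Series | None = None) -> np.ndarray:
    """10th-90th percentile normalization of log2 odds ratios.

    Positive values map linearly onto [0, 1] between the 10th and 90th
    percentiles of the *positive* pool values (clipped); negative values map
    analogously onto [-1, 0].  ``pool`` is the set over which percentiles
    are taken (all pairs across all timepoints of one experiment); it
    defaults to the input itself.  Percentiles use linear interpolation.
    A degenerate range (q10 == q90) maps its sign's values to 0 with a
    warning.
    """
    v = np.asarray(log2_ors, dtype=float)
    p = v if pool is None else np.asarray(pool, dtype=float)
    out = np.zeros_like(v)
    for sign in (1, -1):
        pv = p[p * sign > 0] * sign
        mask = v * sign > 0
        if not mask.any():
            continue
        if pv.size == 0:
            warnings.warn("no pool values of the required sign; mapped to 0")
            continue
        q10, q90 = np.percentile(pv, [10, 90])
        if q90 == q10:
            warnings.warn("degenerate percentile range; values mapped to 0")
            continue
        out[mask] = sign * np.clip((v[mask] * sign - q10) / (q90 - q10), 0, 1)
    return out


def nearest_reference_distance(sites: pd.DataFrame, memory: pd.Series,
                               reference: str = "AP1", bin_size: int = 10,
                               adjacent_bp: float = 20.0) -> pd.DataFrame:
    """Distance from each non-reference memory site to the nearest
    reference-family memory site in the same peak.

    Site positions are bin midpoints (``bin_start + bin_size / 2``).  Sites
    in peaks without a reference memory site are excluded.  The returned
    frame carries site_id, peak_id, family, distance and an ``adjacent``
    flag (distance < ``adjacent_bp``).
    """
    mem = sites[memory].copy()
    mem["midpoint"] = mem["bin_start"] + bin_size / 2.0
    ref = mem[mem["family"] == reference]
    ref_by_peak = ref.groupby("peak_id")["midpoint"].apply(np.asarray)
    others = mem[mem["family"] != reference]
    rows = []
    for _, site in others.iterrows():
        if site["peak_id"] not in ref_by_peak.index:
            continue
        d = float(np.min(np.abs(ref_by_peak[site["peak_id"]]
                                - site["midpoint"])))
        rows.append({"site_id": site["site_id"], "peak_id": site["peak_id"],
                     "family": site["family"], "distance": d,
                     "adjacent": d < adjacent_bp})
    return pd.DataFrame(rows, columns=["site_id", "peak_id", "family",
                                       "distance", "adjacent"])


def collapse_peak_deltas(sites: pd.DataFrame, condition: str, control: str,
                         reference: str = "AP1") -> pd.Series:
    """One footprint-score change per peak for the reference family:
    the change of largest magnitude among the peak's reference sites
    (overlapping motif sites collapsed)."""
    ref = sites[sites["family"] == reference].copy()
    ref["delta"] = ref[f"score_{condition}"] - ref[f"score_{control}"]
    idx = ref.groupby("peak_id")["delta"].apply(
        lambda s: s.iloc[np.argmax(np.abs(s.to_numpy()))])
    return idx


def footprint_performance_curve(peak_deltas: pd.Series, labels: pd.Series,
                                thresholds=None) -> pd.DataFrame:
    """Sensitivity/specificity/accuracy of |delta| >= t for predicting
    differential peaks, over a threshold grid.

    ``peak_deltas`` holds one collapsed reference-family score change per
    peak and ``labels`` the 0/1 differential call from the orthogonal assay
    (e.g. CUT&Tag t-test p < 0.05), aligned by peak id.
    """
    d = np.abs(np.asarray(peak_deltas.loc[labels.index], dtype=float))
    y = np.asarray(labels, dtype=bool)
    if not y.any():
        raise ValueError("no positive labels: sensitivity undefined")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 0.525, 0.025), 3)
    rows = []
    for t in thresholds:
        pred = d >= t
        tp = int((pred & y).sum())
        fn = int((~pred & y).sum())
        tn = int((~pred & ~y).sum())
        fp = int((pred & ~y).sum())
        rows.append({
            "threshold": float(t),
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
            "accuracy": (tp + tn) / y.size,
        })
    return pd.DataFrame(rows)
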