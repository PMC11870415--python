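"""Clonal-variance permutation test for heritability of per-cell scores.

For each feature, the within-clone standard deviation of the single-cell
scores is computed across the cells of every clone; the *observed clonal
variance* is the square of the median of those SDs across clones.  Cell-to-
clone assignments are then randomly permuted (a true permutation over the
clone-assigned cells, preserving clone sizes) and the statistic recomputed;
with null mean :math:`\\mu_0` and null SD :math:`\\sigma_0` over the
permutations,

.. math::  Z = (V_{obs} - \\mu_0) / \\sigma_0, \\qquad
           p = 2\\,\\Phi(-|Z|)

and BH-adjusted FDRs are reported across features.  Heritable features have
within-clone variance *below* the null, i.e. negative Z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = ["clonal_variance_test", "ClonalVarianceTest",
           "clone_summaries", "compare_clone_distributions",
           "correlate_clone_features"]


def _clone_indicator(labels: np.ndarray):
    clones, inv = np.unique(labels, return_inverse=True)
    C = sparse.csr_matrix((np.ones(labels.size), (inv, np.arange(labels.size))),
                          shape=(clones.size, labels.size))
    sizes = np.asarray(C.sum(axis=1)).ravel()
    return C, clones, sizes


def _clonal_variance(C, sizes, values: np.ndarray) -> np.ndarray:
    """Median-over-clones within-clone SD, squared; vectorized over columns."""
    s1 = C @ values
    s2 = C @ (values ** 2)
    n = sizes[:, None]
    var = (s2 - s1 ** 2 / n) / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    return np.median(sd, axis=0) ** 2


def clonal_variance_test(scores, clone_labels, n_perm: int = 1000,
                         seed: int = 0) -> pd.DataFrame:
    """Per-feature clonal-variance permutation test.

    ``scores`` is cells x features (DataFrame or array) restricted to
    clone-assigned cells; ``clone_labels`` gives each cell's clone.  Returns
    a DataFrame with observed_clonal_variance, null moments, Z, p_value and
    BH FDR per feature; features constant across all cells are flagged
    (``constant``) and excluded from the FDR.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    features = (list(scores.columns) if isinstance(scores, pd.DataFrame)
                else [f"feature_{j}" for j in range(np.shape(scores)[1])])
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(clone_labels)
    if X.shape[0] != labels.size:
        raise ValueError("scores and clone_labels disagree on cell count")
    C, clones, sizes = _clone_indicator(labels)
    if np.any(sizes < 2):
        raise ValueError("every clone needs at least 2 cells")

    observed = _clonal_variance(C, sizes, X)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, X.shape[1]))
    for b in range(n_perm):
        null[b] = _clonal_variance(C, sizes, X[rng.permutation(X.shape[0])])
    mu0 = null.mean(axis=0)
    sd0 = null.std(axis=0, ddof=1)

    constant = X.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - mu0) / sd0
    z[constant] = np.nan
    p = 2.0 * stats.norm.sf(np.abs(z))

    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame({
        "feature_id": features,
        "observed_clonal_variance": observed,
        "mean_shuffled_clonal_variance": mu0,
        "stdev_shuffled_clonal_variance": sd0,
        "Z": z, "p_value": p, "FDR": fdr, "constant": constant,
    }).set_index("feature_id")


class ClonalVarianceTest(BaseEstimator):
    """Estimator wrapper around :func:`clonal_variance_test`.

    ``fit(scores, clone_labels)`` stores the per-feature result table in
    ``results_`` and the permutation null in ``n_permutations`` draws.
    """

    def __init__(self, n_permutations: int = 1000, random_state: int = 0):
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, scores, clone_labels):
        self.results_ = clonal_variance_test(
            scores, clone_labels, n_perm=self.n_permutations,
            seed=self.random_state)
        return self

    def heritable_features(self, fdr: float = 0.05) -> list[str]:
        r = self.results_
        return r.index[(r["FDR"] < fdr) & (r["Z"] < 0)].tolist()


def clone_summaries(scores: pd.DataFrame, clone_labels,
                    clone_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-clone median and SD of every feature's scores (long format),
    joined with clone-level metadata (sample, condition) when given."""
    labels = pd.Series(np.asarray(clone_labels), name="clone")
    sc = scores.reset_index(drop=True)
    med = sc.groupby(labels).median()
    sd = sc.groupby(labels).std(ddof=1)
    size = sc.groupby(labels).size().rename("size")
    out = (med.stack().rename("median").to_frame()
           .join(sd.stack().rename("sd")))
    out.index.names = ["clone", "feature"]
    out = out.reset_index().merge(size, left_on="clone", right_index=True)
    if clone_meta is not None:
        out = out.merge(clone_meta, on="clone", how="left")
    return out


def compare_clone_distributions(summaries: pd.DataFrame, feature: str,
                                exposed: str, control: str,
                                condition_col: str = "condition",
                                high_threshold: float = 1.25) -> dict:
    """Compare clone-level score distributions between two conditions.

    ``summaries`` is the long table from :func:`clone_summaries` with a
    condition column.  Returns the KS p-value on the within-clone SDs, the
    exposed-minus-control difference of median-of-medians and of
    median-of-SDs, and the per-arm fraction of clones whose median score
    exceeds ``high_threshold`` (the "high-AP-1 clone" definition).
    """
    df = summaries[summaries["feature"] == feature]
    arm_a = df[df[condition_col] == exposed]
    arm_b = df[df[condition_col] == control]
    if len(arm_a) < 3 or len(arm_b) < 3:
        raise ValueError("need at least 3 clones per arm")
    ks = stats.ks_2samp(arm_a["sd"], arm_b["sd"])
    return {
        "ks_p_sd": float(ks.pvalue),
        "ks_stat_sd": float(ks.statistic),
        "delta_median": float(arm_a["median"].median()
                              - arm_b["median"].median()),
        "delta_sd": float(arm_a["sd"].median() - arm_b["sd"].median()),
        "high_fraction": {
            exposed: float((arm_a["median"] > high_threshold).mean()),
            control: float((arm_b["median"] > high_threshold).mean()),
        },
    }


def correlate_clone_features(clone_motif_means: pd.DataFrame,
                             clone_program_means: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation over clones of mean motif scores vs mean program
    scores (motif families x programs).  Zero-variance vectors yield NaN."""
    a = clone_motif_means.sort_index()
    b = clone_program_means.sort_index()
    if not a.index.equals(b.index):
        raise ValueError("clone sets differ between the two tables")
    if len(a) < 3:
        raise ValueError("need at least 3 clones")
    out = np.empty((a.shape[1], b.shape[1]))
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ac = av - av.mean(axis=0)
        bc = bv - bv.mean(axis=0)
        num = ac.T @ bc
        den = np.outer(np.sqrt((ac ** 2).sum(axis=0)),
                       np.sqrt((bc ** 2).sum(axis=0)))
        out = num / den
    out[~np.isfinite(out)] = np.nan
    return pd.DataFrame(out, index=a.columns, columns=b.columns)
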