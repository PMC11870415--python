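"""Background-normalized deviation scores for motif families and gene programs.

The statistic follows the chromVAR construction.  For a feature set (motif
family or gene program) with weights :math:`w` over features, the raw
deviation of cell :math:`i` is

.. math::

    Y_i = \\frac{\\sum_f w_f x_{if} - \\sum_f w_f e_{if}}
               {\\sum_f w_f e_{if}},
    \\qquad e_{if} = \\mathrm{depth}_i \\cdot
                     \\frac{\\mathrm{total}_f}{\\mathrm{grand\\ total}}

and the reported score z-scores :math:`Y_i` against the same statistic
recomputed on background feature sets matched on mean abundance (features are
ranked by mean count, split into equal-size bins, and each annotated feature
is swapped for a random bin-mate in each of the background replicates;
default 250 replicates, 20 bins).  Under the expectation model the score has
mean ~0 per cell, controlling for sequencing depth and feature abundance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpectedCounts", "expected_counts", "sample_background_sets",
    "deviation_scores", "DeviationScorer", "bag_motif_families",
    "condition_summary", "activated_fraction", "downsampled_ks",
    "select_program_genes",
]


class ExpectedCounts:
    """Lazy rank-one expectation matrix e[i, f] = depth_i * total_f / grand."""

    def __init__(self, counts):
        counts = sparse.csr_matrix(counts)
        self.depths = np.asarray(counts.sum(axis=1)).ravel().astype(float)
        self.feature_totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
        self.grand_total = float(self.feature_totals.sum())
        if self.grand_total == 0:
            raise ValueError("count matrix is empty (grand total 0)")

    def dot(self, w: np.ndarray) -> np.ndarray:
        """Per-cell expected weighted counts  E @ w  (length n_cells)."""
        return self.depths * (self.feature_totals @ w) / self.grand_total

    def dense(self) -> np.ndarray:
        return np.outer(self.depths, self.feature_totals) / self.grand_total


def expected_counts(counts) -> ExpectedCounts:
    """chromVAR-style expectation accessor for a cell x feature count matrix."""
    return ExpectedCounts(counts)


def sample_background_sets(counts, annotated_features: np.ndarray | None = None,
                           n_bins: int = 20, n_background: int = 250,
                           seed: int | np.random.Generator = 0,
                           bin_assignments: np.ndarray | None = None) -> np.ndarray:
    """Abundance-matched background features.

    Features are ranked by mean count and split into ``n_bins`` equal-size
    bins (or ``bin_assignments`` is used directly, for callers matching on a
    different variable such as GC content).  For every feature in
    ``annotated_features`` (default: all), ``n_background`` features are
    drawn from its bin excluding the feature itself — without replacement
    when the bin is large enough, with replacement otherwise.

    Returns an integer array of shape (n_features, n_background) with row f
    holding the background features of feature f (rows not requested are -1).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counts = sparse.csr_matrix(counts)
    n_features = counts.shape[1]
    if bin_assignments is None:
        means = np.asarray(counts.mean(axis=0)).ravel()
        order = np.argsort(means, kind="stable")
        bin_assignments = np.empty(n_features, dtype=int)
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            bin_assignments[chunk] = b
    if annotated_features is None:
        annotated_features = np.arange(n_features)

    bins = {b: np.flatnonzero(bin_assignments == b)
            for b in np.unique(bin_assignments)}
    out = np.full((n_features, n_background), -1, dtype=np.int64)
    for f in annotated_features:
        mates = bins[bin_assignments[f]]
        mates = mates[mates != f]
        if mates.size == 0:
            raise ValueError(f"feature {f} alone in its bin: no background")
        replace = mates.size < n_background
        out[f] = rng.choice(mates, size=n_background, replace=replace)
    return out


def _family_matrix(annotation, n_features: int) -> sparse.csc_matrix:
    """Coerce the annotation to a (features x families) sparse weight matrix."""
    if sparse.issparse(annotation):
        m = annotation.tocsc()
    else:
        m = sparse.csc_matrix(np.asarray(annotation, dtype=float))
    if m.shape[0] != n_features:
        raise ValueError("annotation rows must equal the feature count")
    return m


def deviation_scores(counts, annotation, backgrounds: np.ndarray,
                     expectation: ExpectedCounts | None = None,
                     family_names=None) -> pd.DataFrame:
    """Cell x family background-normalized deviation scores.

    ``annotation`` is features x families (boolean membership for motifs,
    probability weights for gene programs); ``backgrounds`` is the array
    produced by :func:`sample_background_sets`.  A family whose background
    deviations are constant yields score 0 where the raw deviation equals the
    background mean and missing (NaN, with a warning) otherwise.
    """
    X = sparse.csr_matrix(counts).astype(float)
    n_cells, n_features = X.shape
    if expectation is None:
        expectation = ExpectedCounts(X)
    A = _family_matrix(annotation, n_features)
    n_families = A.shape[1]
    n_bg = backgrounds.shape[1]
    if family_names is None:
        family_names = [f"family_{a}" for a in range(n_families)]

    scores = np.empty((n_cells, n_families))
    for a in range(n_families):
        w = np.asarray(A[:, a].todense()).ravel()
        members = np.flatnonzero(w)
        if members.size == 0:
            raise ValueError(f"family {family_names[a]} annotates no feature")
        ew = expectation.dot(w)
        if np.any(ew == 0):
            raise ValueError("zero expected counts for a cell; remove "
                             "all-zero cells before scoring")
        y = (X @ w - ew) / ew

        yb = np.empty((n_bg, n_cells))
        for b in range(n_bg):
            wb = np.zeros(n_features)
            np.add.at(wb, backgrounds[members, b], w[members])
            ewb = expectation.dot(wb)
            yb[b] = (X @ wb - ewb) / ewb
        mu = yb.mean(axis=0)
        sd = yb.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (y - mu) / sd
        degenerate = sd == 0
        if degenerate.any():
            z[degenerate & (y == mu)] = 0.0
            bad = degenerate & (y != mu)
            if bad.any():
                warnings.warn(
                    f"family {family_names[a]}: {int(bad.sum())} cells have "
                    "constant background deviations; scores set missing")
                z[bad] = np.nan
        scores[:, a] = z
    return pd.DataFrame(scores, columns=list(family_names))


class DeviationScorer(BaseEstimator, TransformerMixin):
    """Transformer computing chromVAR-style deviation scores.

    ``fit`` learns the expectation model and samples the abundance-matched
    background sets from the training counts; ``transform`` scores a count
    matrix with the same features.  With the defaults (250 backgrounds,
    20 abundance bins) this matches the published scoring of motif families
    over peaks and of LDA gene programs over genes.

    Parameters
    ----------
    annotation : (features x families) membership/weight matrix
    n_background, n_bins : background replicate count and abundance bins
    bin_assignments : optional externally supplied feature bins (e.g. GC x
        accessibility bins for peaks)
    random_state : seed for background sampling
    family_names : column labels of the returned score frame
    """

    def __init__(self, annotation=None, n_background: int = 250,
                 n_bins: int = 20, bin_assignments=None,
                 random_state: int = 0, family_names=None):
        self.annotation = annotation
        self.n_background = n_background
        self.n_bins = n_bins
        self.bin_assignments = bin_assignments
        self.random_state = random_state
        self.family_names = family_names

    def fit(self, X, y=None):
        if self.annotation is None:
            raise ValueError("annotation is required")
        X = sparse.csr_matrix(X)
        self.expectation_ = ExpectedCounts(X)
        A = _family_matrix(self.annotation, X.shape[1])
        annotated = np.unique(A.nonzero()[0])
        self.backgrounds_ = sample_background_sets(
            X, annotated, n_bins=self.n_bins, n_background=self.n_background,
            seed=np.random.default_rng(self.random_state),
            bin_assignments=self.bin_assignments)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = sparse.csr_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return deviation_scores(X, self.annotation, self.backgrounds_,
                                expectation=ExpectedCounts(X),
                                family_names=self.family_names)


def bag_motif_families(qvalues: pd.DataFrame, variability: pd.Series,
                       q_cutoff: float = 0.05) -> dict[str, str]:
    """Greedy bagging of motifs into families by similarity q-values.

    Motifs are visited in descending variability; an unmerged motif becomes a
    leader and every still-unmerged motif with q < ``q_cutoff`` to it joins
    its family.  Returns motif -> leader.
    """
    order = variability.sort_values(ascending=False, kind="stable").index
    leader_of: dict[str, str] = {}
    for m in order:
        if m in leader_of:
            continue
        leader_of[m] = m
        q = qvalues.loc[m]
        for other in order:
            if other not in leader_of and q[other] < q_cutoff:
                leader_of[other] = m
    return leader_of


def condition_summary(scores: pd.DataFrame, cell_meta: pd.DataFrame,
                      control: str, cell_type: str | None = None,
                      n_top: int = 50, min_cells: int = 200) -> pd.DataFrame:
    """Per-family condition summary: sample means, change vs control, t-tests.

    ``cell_meta`` (aligned to the rows of ``scores``) carries columns
    ``sample``, ``condition`` and optionally ``cell_type``.  Scores are
    averaged over the target cells of each sample; change is the sample mean
    minus the mean of control-sample means; a two-sample t-test compares each
    condition's sample means to control and BH-adjusts across the ``n_top``
    most variable families (by per-cell score variance).  Samples with fewer
    than ``min_cells`` target cells are excluded.
    """
    meta = cell_meta.reset_index(drop=True)
    sc = scores.reset_index(drop=True)
    if cell_type is not None:
        keep = meta["cell_type"] == cell_type
        meta, sc = meta[keep], sc[keep]

    grouped = sc.groupby([meta["sample"], meta["condition"]])
    sample_means = grouped.mean()
    n_cells = grouped.size()
    sample_means = sample_means[n_cells >= min_cells]
    if sample_means.empty:
        raise ValueError("no sample retains enough target cells")

    ctrl_means = sample_means.xs(control, level="condition", drop_level=True)
    variable = sc.var(axis=0).sort_values(ascending=False, kind="stable")
    top = set(variable.index[:n_top])

    rows = []
    for family in scores.columns:
        ctrl_avg = ctrl_means[family].mean()
        for (sample, condition), mean in sample_means[family].items():
            rows.append({"family": family, "sample": sample,
                         "condition": condition, "mean_score": mean,
                         "change": mean - ctrl_avg,
                         "n_cells": int(n_cells[(sample, condition)])})
    out = pd.DataFrame(rows)

    # condition-level t-tests on sample means vs control
    tests = []
    for family in scores.columns:
        for condition in out["condition"].unique():
            if condition == control:
                continue
            a = sample_means.xs(condition, level="condition")[family]
            b = ctrl_means[family]
            if len(a) >= 2 and len(b) >= 2:
                p = stats.ttest_ind(a, b).pvalue
            else:
                p = np.nan
            tests.append({"family": family, "condition": condition,
                          "p_value": p})
    tests = pd.DataFrame(tests)
    in_top = tests["family"].isin(top) & tests["p_value"].notna()
    tests["fdr"] = np.nan
    if in_top.any():
        tests.loc[in_top, "fdr"] = multipletests(
            tests.loc[in_top, "p_value"], method="fdr_bh")[1]
    return out.merge(tests, on=["family", "condition"], how="left")


def activated_fraction(scores: pd.Series, samples: pd.Series,
                       threshold: float = 1.5) -> pd.Series:
    """Per-sample fraction of cells with score strictly greater than
    ``threshold`` (the "activated cell" definition)."""
    active = pd.Series(np.asarray(scores) > threshold, index=samples.index)
    return active.groupby(samples.to_numpy()).mean()


def downsampled_ks(scores: pd.Series, conditions: pd.Series, a: str, b: str,
                   n: int = 500, seed: int = 0):
    """Two-sample KS test between conditions after downsampling each to ``n``
    cells.  Returns (statistic, p_value, flagged) — flagged is True when a
    condition had fewer than ``n`` cells and was used in full."""
    rng = np.random.default_rng(seed)
    vals = np.asarray(scores, dtype=float)
    cond = np.asarray(conditions)
    flagged = False
    arms = []
    for label in (a, b):
        v = vals[cond == label]
        if v.size > n:
            v = rng.choice(v, size=n, replace=False)
        elif v.size < n:
            flagged = True
        arms.append(v)
    res = stats.ks_2samp(arms[0], arms[1])
    return res.statistic, res.pvalue, flagged


def select_program_genes(topic_weights: pd.Series, k: int = 150) -> list[str]:
    """Top-``k`` genes of a program by contribution weight, ties broken by
    gene id (lexicographic)."""
    df = topic_weights.rename("w").rename_axis("gene").reset_index()
    df = df.sort_values(["w", "gene"], ascending=[False, True], kind="stable")
    return df["gene"].head(k).tolist()
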