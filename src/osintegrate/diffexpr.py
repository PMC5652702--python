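"""Negative-binomial exact-test differential expression between two phenotype groups.

The decision rule is deliberately conservative: a gene is called significant
only when the tests run under the *common* dispersion estimate and under the
per-gene *tagwise* dispersion estimate both survive Benjamini-Hochberg
adjustment at ``alpha``.  When that dual rule yields zero genes the whole run
falls back to unadjusted p-values (recorded in ``DEResult.mode_used``); the
fallback is all-or-nothing per run, never per gene.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DispersionEstimate",
    "DEResult",
    "normalize_libsizes",
    "estimate_dispersion",
    "exact_test",
    "exact_nb_pvalue",
    "call_de",
    "bh_adjust",
    "transcriptome_correlation",
]

# dispersions below this are numerically indistinguishable from Poisson
_POISSON_EPS = 1e-6


@dataclasses.dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample phenotype labels.

    Parameters
    ----------
    counts:
        DataFrame, genes as rows, samples as columns, non-negative integers.
    groups:
        Series mapping sample -> group label.  Exactly the samples of
        ``counts`` must be labelled; one or two distinct labels are allowed
        (two are required for testing).
    lib_sizes:
        Optional Series of per-sample library sizes; defaults to column sums.
    """

    counts: pd.DataFrame
    groups: pd.Series
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("negative counts are not allowed")
        if not np.isfinite(counts.values).all():
            raise ValueError("counts must be finite")
        missing = set(counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.groups = self.groups.loc[counts.columns]
        if self.lib_sizes is None:
            self.lib_sizes = counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.loc[counts.columns].astype(float)
            if (self.lib_sizes <= 0).any():
                raise ValueError("library sizes must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def group_samples(self, label: str) -> list:
        return list(self.groups.index[self.groups == label])

    def group_labels(self) -> list:
        """Distinct labels, test group ('aggressive' when present) first."""
        labels = sorted(set(self.groups))
        if "aggressive" in labels:
            labels.remove("aggressive")
            labels.insert(0, "aggressive")
        return labels


@dataclasses.dataclass
class DispersionEstimate:
    """Common and per-gene (tagwise) NB dispersion, variance = mu + phi * mu^2."""

    common: float
    tagwise: pd.Series
    shrinkage_weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.common) or self.common < 0:
            raise ValueError("common dispersion must be finite and >= 0")
        if (~np.isfinite(self.tagwise.values)).any() or (self.tagwise.values < 0).any():
            raise ValueError("tagwise dispersions must be finite and >= 0")


@dataclasses.dataclass
class DEResult:
    """Per-gene differential-expression calls.

    ``table`` columns: log2_fold_change, p_common, p_tagwise, fdr_common,
    fdr_tagwise, significant.  ``mode_used`` is ``dual_fdr`` or
    ``unadjusted_fallback`` and applies to every gene of the run.
    """

    table: pd.DataFrame
    mode_used: str
    alpha: float

    @property
    def significant_genes(self) -> set:
        return set(self.table.index[self.table["significant"]])


# ---------------------------------------------------------------------------
# normalization


def normalize_libsizes(m: CountMatrix) -> pd.Series:
    """Effective library sizes via median-of-ratios scale factors.

    Each sample's factor is the median ratio of its counts to the
    geometric-mean pseudo-reference across samples (genes expressed in every
    sample only), normalized so factors have geometric mean 1.  The effective
    library size is the factor times the geometric mean of the raw column
    sums, so a sample with doubled counts gets a doubled effective size.
    """
    counts = m.counts.values.astype(float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix cannot be normalized")
    colsums = counts.sum(axis=0)
    if counts.shape[1] == 1:
        return pd.Series(colsums, index=m.samples)
    expressed = (counts > 0).all(axis=1)
    if expressed.any():
        logref = np.log(counts[expressed]).mean(axis=1)
        factors = np.exp(
            np.median(np.log(counts[expressed]) - logref[:, None], axis=0)
        )
    else:
        factors = colsums / np.exp(np.mean(np.log(np.where(colsums > 0, colsums, 1))))
    factors = factors / np.exp(np.mean(np.log(factors)))
    scale = np.exp(np.mean(np.log(colsums[colsums > 0])))
    return pd.Series(factors * scale, index=m.samples)


def _pseudo_counts(m: CountMatrix) -> tuple[np.ndarray, dict]:
    """Counts rescaled (and rounded) to a single effective library size.

    This is a rounding approximation of the quantile adjustment that makes
    the conditional NB likelihood / exact test applicable.
    """
    eff = normalize_libsizes(m)
    target = np.exp(np.mean(np.log(eff.values)))
    pseudo = np.rint(m.counts.values * (target / eff.values)[None, :]).astype(np.int64)
    labels = m.group_labels()
    cols = {lab: [m.samples.get_loc(s) for s in m.group_samples(lab)] for lab in labels}
    return pseudo, cols


# ---------------------------------------------------------------------------
# dispersion estimation


def _cond_loglik(pseudo: np.ndarray, group_cols: Sequence[Sequence[int]], phi: float) -> np.ndarray:
    """Per-gene conditional NB log-likelihood given group totals (phi terms only)."""
    if phi < _POISSON_EPS:
        phi = _POISSON_EPS
    r = 1.0 / phi
    ll = np.zeros(pseudo.shape[0])
    for cols in group_cols:
        if len(cols) < 2:
            continue  # a single-sample group carries no dispersion information
        y = pseudo[:, cols]
        n = y.shape[1]
        z = y.sum(axis=1)
        ll += gammaln(y + r).sum(axis=1) - n * gammaln(r) + gammaln(n * r) - gammaln(z + n * r)
        # terms constant in phi (factorials of y and z) are dropped
    return ll


_PHI_GRID = np.concatenate([[1e-6], np.logspace(-4, 1, 81)])


def estimate_dispersion(m: CountMatrix, shrinkage_weight: float = 10.0) -> DispersionEstimate:
    """Estimate common and tagwise NB dispersions by conditional likelihood.

    The common value maximizes the conditional log-likelihood summed over
    genes (counts quantile-adjusted to equal effective library sizes).  Each
    tagwise value maximizes the gene's own conditional likelihood plus
    ``shrinkage_weight`` pseudo-genes carrying the average per-gene
    likelihood, shrinking noisy per-gene estimates toward the common value.
    """
    pseudo, cols = _pseudo_counts(m)
    group_cols = list(cols.values())
    if all(len(c) < 2 for c in group_cols):
        raise ValueError(
            "dispersion is not estimable without replicates in at least one "
            "group; supply a fixed dispersion value instead"
        )
    ll_grid = np.empty((pseudo.shape[0], len(_PHI_GRID)))
    for j, phi in enumerate(_PHI_GRID):
        ll_grid[:, j] = _cond_loglik(pseudo, group_cols, phi)

    total = ll_grid.sum(axis=0)
    j_best = int(np.argmax(total))
    lo = _PHI_GRID[max(j_best - 1, 0)]
    hi = _PHI_GRID[min(j_best + 1, len(_PHI_GRID) - 1)]
    if lo == hi:
        common = float(lo)
    else:
        res = minimize_scalar(
            lambda lg: -_cond_loglik(pseudo, group_cols, 10.0 ** lg).sum(),
            bounds=(np.log10(lo), np.log10(hi)),
            method="bounded",
        )
        common = float(10.0 ** res.x)
    if common <= _PHI_GRID[0] * (1 + 1e-6):
        common = float(_PHI_GRID[0])

    mean_ll = ll_grid.mean(axis=0)
    weighted = ll_grid + shrinkage_weight * mean_ll[None, :]
    tag = _PHI_GRID[np.argmax(weighted, axis=1)]
    if not np.isfinite(shrinkage_weight):
        tag = np.full(pseudo.shape[0], common)
    return DispersionEstimate(
        common=common,
        tagwise=pd.Series(tag.astype(float), index=m.genes),
        shrinkage_weight=float(shrinkage_weight),
    )


# ---------------------------------------------------------------------------
# exact test


def exact_nb_pvalue(z1: int, z2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact NB p-value for a split (z1 | z2) of a gene total.

    Conditions on the total z1 + z2 under equal per-sample means and equal
    library sizes: the split follows a negative hypergeometric law with
    shapes n1/phi and n2/phi (binomial(z, n1/(n1+n2)) in the Poisson limit).
    The two-sided p sums the probabilities of all splits no more likely than
    the observed one (minimum-likelihood method), capped at 1.
    """
    z = z1 + z2
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if phi < _POISSON_EPS:
        # Poisson limit: binomial split
        logp = (
            gammaln(z + 1)
            - gammaln(k + 1)
            - gammaln(z - k + 1)
            + k * np.log(n1 / (n1 + n2))
            + (z - k) * np.log(n2 / (n1 + n2))
        )
    else:
        r = 1.0 / phi
        a, b = n1 * r, n2 * r
        logp = (
            gammaln(k + a)
            - gammaln(k + 1)
            - gammaln(a)
            + gammaln(z - k + b)
            - gammaln(z - k + 1)
            - gammaln(b)
            - (gammaln(z + a + b) - gammaln(z + 1) - gammaln(a + b))
        )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[z1]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def exact_test(
    m: CountMatrix,
    d: DispersionEstimate | float,
    which: str = "common",
) -> pd.DataFrame:
    """Per-gene exact NB test between the two groups of ``m``.

    Parameters
    ----------
    d:
        A :class:`DispersionEstimate` or a fixed scalar dispersion.
    which:
        ``"common"`` or ``"tagwise"``; ignored when ``d`` is a scalar.

    Returns
    -------
    DataFrame indexed by gene with columns ``p`` and ``log2_fold_change``
    (first group label — 'aggressive' when present — over the other, computed
    from normalized group means with pseudo-count 0.5).
    """
    labels = m.group_labels()
    if len(labels) != 2:
        raise ValueError(f"exact test requires exactly two groups, got {labels}")
    pseudo, cols = _pseudo_counts(m)
    c1, c2 = cols[labels[0]], cols[labels[1]]
    n1, n2 = len(c1), len(c2)
    if isinstance(d, DispersionEstimate):
        if which == "common":
            phis = np.full(pseudo.shape[0], d.common)
        elif which == "tagwise":
            phis = d.tagwise.loc[m.genes].values
        else:
            raise ValueError("which must be 'common' or 'tagwise'")
    else:
        if not np.isfinite(d) or d < 0:
            raise ValueError("fixed dispersion must be finite and >= 0")
        phis = np.full(pseudo.shape[0], float(d))

    z1 = pseudo[:, c1].sum(axis=1)
    z2 = pseudo[:, c2].sum(axis=1)
    pvals = np.ones(pseudo.shape[0])
    for i in range(pseudo.shape[0]):
        pvals[i] = exact_nb_pvalue(int(z1[i]), int(z2[i]), n1, n2, phis[i])

    m1 = z1 / n1
    m2 = z2 / n2
    lfc = np.log2(m1 + 0.5) - np.log2(m2 + 0.5)
    lfc[(z1 == 0) & (z2 == 0)] = 0.0
    return pd.DataFrame({"p": pvals, "log2_fold_change": lfc}, index=m.genes)


# ---------------------------------------------------------------------------
# significance calling


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, ties by original order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    r_common: pd.DataFrame,
    r_tagwise: pd.DataFrame,
    alpha: float = 0.05,
) -> DEResult:
    """Combine common- and tagwise-dispersion tests into significance calls.

    Significant genes must pass BH-adjusted p < ``alpha`` under *both*
    dispersion analyses.  If no gene passes, the run switches to the
    unadjusted fallback (both raw p < ``alpha``), recorded in ``mode_used``.
    """
    if not r_common.index.equals(r_tagwise.index):
        raise ValueError("common and tagwise results cover different gene sets")
    fdr_c = bh_adjust(r_common["p"].values)
    fdr_t = bh_adjust(r_tagwise["p"].values)
    sig = (fdr_c < alpha) & (fdr_t < alpha)
    mode = "dual_fdr"
    if not sig.any():
        sig = (r_common["p"].values < alpha) & (r_tagwise["p"].values < alpha)
        mode = "unadjusted_fallback"
    table = pd.DataFrame(
        {
            "log2_fold_change": r_common["log2_fold_change"].values,
            "p_common": r_common["p"].values,
            "p_tagwise": r_tagwise["p"].values,
            "fdr_common": fdr_c,
            "fdr_tagwise": fdr_t,
            "significant": sig,
        },
        index=r_common.index,
    )
    table.index.name = "gene"
    return DEResult(table=table, mode_used=mode, alpha=alpha)


# ---------------------------------------------------------------------------
# transcriptome correlation


def transcriptome_correlation(a, b, transform: bool = True) -> float:
    """Pearson correlation of two expression vectors on log2(CPM + 1).

    Set ``transform=False`` when the vectors are already on the comparison
    scale.  Raises on zero-variance input (r undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length and gene order")
    if transform:
        a = np.log2(a / a.sum() * 1e6 + 1)
        b = np.log2(b / b.sum() * 1e6 + 1)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance vector")
    return float(pearsonr(a, b)[0])
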