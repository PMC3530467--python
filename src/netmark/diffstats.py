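"""Per-gene two-group differential statistics and cross-analyte diagnostics.

The core statistic is the moderated difference of group means

    d_i = (mean_pos_i - mean_neg_i) / (se_i + s0)

where ``se_i`` is the pooled standard error of the mean difference and ``s0``
a fudge factor that stabilises genes with tiny variance (here the median of
the per-gene standard errors).  False-discovery q-values come from group-label
permutations: for a threshold t, the estimated FDR is the median permuted
count of |d| >= t divided by the observed count, and a gene's q-value is the
smallest FDR over thresholds at or below its own |d|.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import NEGATIVE, POSITIVE, OmicsMatrix

logger = logging.getLogger(__name__)

#: smallest representable q-value; the edge-weight transform takes log10(q)
Q_FLOOR = 1e-16


def _pos_mask(matrix: OmicsMatrix) -> np.ndarray:
    mask = np.array([matrix.labels.get(s) == POSITIVE for s in matrix.samples])
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {int(mask.sum())} positive, "
            f"{int((~mask).sum())} negative)"
        )
    return mask


def _d_statistics(X: np.ndarray, pos_mask: np.ndarray, s0: float | None = None):
    """Vectorised d-statistics for every row; returns (d, se, s0)."""
    n1 = int(pos_mask.sum())
    n2 = int((~pos_mask).sum())
    xp = X[:, pos_mask]
    xn = X[:, ~pos_mask]
    diff = xp.mean(axis=1) - xn.mean(axis=1)
    ssq = ((xp - xp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xn - xn.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    pooled_var = ssq / (n1 + n2 - 2)
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    if s0 is None:
        s0 = float(np.median(se))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / (se + s0)
    d[np.isnan(d)] = 0.0  # zero-variance, zero-difference rows
    return d, se, s0


def sam_statistic(matrix: OmicsMatrix, gene: str) -> float:
    """Moderated d-statistic of one gene; its sign gives the direction of
    change (positive = higher in the positive group)."""
    if gene not in matrix.values.index:
        raise KeyError(gene)
    X = matrix.values.to_numpy(float)
    d, _, _ = _d_statistics(X, _pos_mask(matrix))
    return float(d[matrix.values.index.get_loc(gene)])


def sam_statistics(matrix: OmicsMatrix) -> pd.Series:
    """d-statistics for every gene (one vectorised pass)."""
    d, _, _ = _d_statistics(matrix.values.to_numpy(float), _pos_mask(matrix))
    return pd.Series(d, index=matrix.values.index, name="d")


def _label_permutations(n: int, n_pos: int, n_perm: int, rng: np.random.Generator):
    """Positive-group index masks: exhaustive when the design is small enough,
    otherwise random draws."""
    total = math.comb(n, n_pos)
    if total <= n_perm:
        if total < n_perm:
            logger.warning(
                "only %d distinct label permutations exist (< %d requested); using all",
                total, n_perm,
            )
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n_pos)):
            masks[i, list(combo)] = True
        return masks
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.permutation(n)[:n_pos]] = True
    return masks


def sam_qvalues(
    matrix: OmicsMatrix,
    n_perm: int = 200,
    seed: int = 0,
    q_floor: float = Q_FLOOR,
) -> pd.DataFrame:
    """Permutation q-values for every gene.

    Returns a DataFrame indexed by gene with columns ``d`` and ``q``; q lies in
    (q_floor, 1] and is non-increasing in |d| within the run.  Deterministic
    given the seed.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    rng = np.random.default_rng(seed)
    # canonical sample order: permutation masks attach to sample identities,
    # so a consistent reordering of the input columns cannot change q
    matrix = matrix.restrict_samples(sorted(matrix.samples))
    X = matrix.values.to_numpy(float)
    pos_mask = _pos_mask(matrix)
    d, _, s0 = _d_statistics(X, pos_mask)
    absd = np.abs(d)

    masks = _label_permutations(X.shape[1], int(pos_mask.sum()), n_perm, rng)
    n_used = masks.shape[0]
    # permuted |d| values, one sorted array per permutation
    perm_sorted = np.empty((n_used, X.shape[0]))
    for i in range(n_used):
        dp, _, _ = _d_statistics(X, masks[i], s0=s0)
        perm_sorted[i] = np.sort(np.abs(dp))

    order = np.argsort(-absd, kind="stable")
    thresholds = absd[order]  # descending
    obs_count = np.arange(1, len(thresholds) + 1, dtype=float)
    # per permutation: how many permuted |d| are >= each threshold
    counts = np.stack(
        [perm_sorted.shape[1] - np.searchsorted(perm_sorted[i], thresholds, side="left")
         for i in range(n_used)]
    )
    med = np.median(counts, axis=0)
    fdr = np.clip(med / obs_count, 0.0, 1.0)
    # q at rank k = min FDR over thresholds at or below |d|_(k): suffix minimum
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    # equal |d| must share one q-value: take the group's smallest
    first_of_tie = np.searchsorted(-thresholds, -thresholds, side="left")
    q_sorted = q_sorted[first_of_tie]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    q = np.clip(q, q_floor, 1.0)
    return pd.DataFrame({"d": d, "q": q}, index=matrix.values.index)


def welch_bh_qvalues(matrix: OmicsMatrix, **_: object) -> pd.DataFrame:
    """Sensitivity-analysis alternative: Welch t-test with Benjamini–Hochberg
    q-values, same output contract as :func:`sam_qvalues`."""
    from statsmodels.stats.multitest import multipletests

    pos = matrix.group_samples(POSITIVE)
    neg = matrix.group_samples(NEGATIVE)
    t, p = stats.ttest_ind(
        matrix.values[pos], matrix.values[neg], axis=1, equal_var=False
    )
    t = np.nan_to_num(t)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    q = np.clip(q, Q_FLOOR, 1.0)
    return pd.DataFrame({"d": t, "q": q}, index=matrix.values.index)


@dataclass
class CorrelationResult:
    per_gene: pd.Series  # Pearson r per gene
    flagged: list[str]  # genes with a constant profile (r recorded as 0)
    median: float


def expression_methylation_correlation(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    genes: list[str] | None = None,
) -> CorrelationResult:
    """Per-gene Pearson correlation between a gene's expression and promoter
    methylation profiles across the same samples, plus the median."""
    if expr.samples != meth.samples:
        raise ValueError("matrices must share samples in identical order")
    genes = list(genes) if genes is not None else sorted(
        set(expr.genes) & set(meth.genes)
    )
    missing = [g for g in genes if g not in expr.values.index or g not in meth.values.index]
    if missing:
        raise KeyError(f"gene(s) absent from one analyte: {missing[:5]}")
    E = expr.values.loc[genes].to_numpy(float)
    M = meth.values.loc[genes].to_numpy(float)
    Ec = E - E.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    se = np.sqrt((Ec**2).sum(axis=1))
    sm = np.sqrt((Mc**2).sum(axis=1))
    const = (se == 0) | (sm == 0)
    denom = np.where(const, 1.0, se * sm)
    r = (Ec * Mc).sum(axis=1) / denom
    r[const] = 0.0
    per_gene = pd.Series(r, index=genes, name="pearson_r")
    flagged = [g for g, c in zip(genes, const) if c]
    if flagged:
        logger.warning("%d gene(s) with constant profile; correlation set to 0", len(flagged))
    return CorrelationResult(per_gene=per_gene, flagged=flagged, median=float(np.median(r)))


def _rowwise_ranks(values: pd.DataFrame) -> np.ndarray:
    return stats.rankdata(values.to_numpy(float), axis=1)


def connected_pair_correlation_test(
    meth: OmicsMatrix,
    net,
    n_random_pairs: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Compare methylation-profile similarity of interacting vs random gene
    pairs.

    Spearman rank correlations are computed for every network edge and for
    ``n_random_pairs`` uniformly drawn non-identical gene pairs (default: as
    many as there are edges).  A one-tailed two-sample Kolmogorov–Smirnov test
    asks whether connected-pair correlations are stochastically larger.
    Returns (connected_corrs, random_corrs, p_value).
    """
    edges = [e for e in net.edges]
    if not edges:
        raise ValueError("network has no edges")
    nodes = sorted(net.nodes)
    missing = [g for g in nodes if g not in meth.values.index]
    if missing:
        raise KeyError(f"network gene(s) absent from matrix: {missing[:5]}")
    if n_random_pairs is None:
        n_random_pairs = len(edges)
    rng = np.random.default_rng(seed)

    ranks = _rowwise_ranks(meth.values.loc[nodes])
    idx = {g: i for i, g in enumerate(nodes)}
    Rc = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((Rc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    Rn = Rc / norm[:, None]

    def pair_corr(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return (Rn[i] * Rn[j]).sum(axis=1)

    ei = np.array([idx[a] for a, _ in edges])
    ej = np.array([idx[b] for _, b in edges])
    connected = pair_corr(ei, ej)

    ri = rng.integers(0, len(nodes), size=n_random_pairs)
    rj = rng.integers(0, len(nodes) - 1, size=n_random_pairs)
    rj[rj >= ri] += 1  # uniform over ordered non-identical pairs
    random_pairs = pair_corr(ri, rj)

    # 'less' = CDF(connected) below CDF(random) = connected stochastically larger
    ks = stats.ks_2samp(connected, random_pairs, alternative="less")
    return connected, random_pairs, float(ks.pvalue)
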