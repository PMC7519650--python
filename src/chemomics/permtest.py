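"""Burden-controlled permutation association between gene mutation status and
per-sample mutation-context counts.

A binary genes x samples mutation-status matrix is repeatedly randomized with
the Curveball algorithm (Strona et al.), which preserves every row sum (gene
mutation frequency) and column sum (per-sample mutation burden) exactly.  For
every gene an observed Wilcoxon rank-sum p-value (mutant vs wild-type context
counts) is compared against the p-values recomputed on each permuted matrix;
the final p-value is the fraction of permuted p-values at least as extreme.
Because the randomization fixes both margins, the test controls for the
strong confounding between per-sample mutation burden and any per-sample
mutation count.

Inside the permutation loop, observed and permuted p-values are both computed
with the same midrank normal approximation (tie-corrected, continuity-
corrected), so they live on an identical scale; the standalone
:func:`gene_observed_stat` additionally offers exact enumeration for small
tie-free groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats


# ---------------------------------------------------------------------------
# Curveball randomization


@njit(cache=True)
def _curveball_trades(mat, n_trades, seed):  # pragma: no cover - numba kernel
    n_rows, n_cols = mat.shape
    np.random.seed(seed)
    buf = np.empty(n_cols, np.int64)
    for _ in range(n_trades):
        i = np.random.randint(0, n_rows)
        j = np.random.randint(0, n_rows)
        if i == j:
            continue
        k = 0
        ones_i = 0
        for c in range(n_cols):
            a = mat[i, c]
            b = mat[j, c]
            if a != b:
                buf[k] = c
                k += 1
                if a == 1:
                    ones_i += 1
        if k < 2 or ones_i == 0 or ones_i == k:
            continue
        for x in range(k - 1, 0, -1):
            y = np.random.randint(0, x + 1)
            tmp = buf[x]
            buf[x] = buf[y]
            buf[y] = tmp
        for x in range(k):
            c = buf[x]
            if x < ones_i:
                mat[i, c] = 1
                mat[j, c] = 0
            else:
                mat[i, c] = 0
                mat[j, c] = 1
    return mat


def curve_ball_randomize(matrix, n_trades: int | None = None, rng=None):
    """Margin-preserving randomization of a binary matrix (Curveball).

    Repeatedly picks two random rows and redistributes their discordant
    columns at random while keeping each row's count of ones — a "trade".
    Row and column sums are preserved exactly on every draw.

    Parameters
    ----------
    matrix : 2-D binary array or DataFrame (genes x samples).
    n_trades : number of trades; defaults to ``5 * (number of 1-entries)``,
        a mixing heuristic.
    rng : ``numpy.random.Generator`` (fresh default_rng if omitted).

    Returns a new matrix of the same type; the input is not modified.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    arr = matrix.values if is_df else np.asarray(matrix)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("matrix must be binary")
    if rng is None:
        rng = np.random.default_rng()
    ones = int(arr.sum())
    if n_trades is None:
        n_trades = max(1, 5 * ones)
    if n_trades < 1:
        raise ValueError("n_trades must be >= 1")
    out = arr.astype(np.int8).copy()
    _curveball_trades(out, int(n_trades), int(rng.integers(2**31)))
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


# ---------------------------------------------------------------------------
# Rank-sum machinery


def _rank_setup(counts: np.ndarray):
    """Midranks of the counts and the tie-correction term (both permutation-
    invariant: group membership changes, values never do)."""
    ranks = stats.rankdata(counts)
    n = len(counts)
    _, tie_sizes = np.unique(counts, return_counts=True)
    tie_term = ((tie_sizes**3 - tie_sizes).sum()) / (n * (n - 1)) if n > 1 else 0.0
    return ranks, tie_term


def _asymptotic_p(W, n1, n, tie_term):
    """Two-sided rank-sum p from mutant rank sums ``W`` (vectorized).

    Midrank normal approximation with tie correction and 0.5 continuity
    correction.  Degenerate cases (all values tied, or empty group) give 1.
    """
    W = np.asarray(W, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(W - mu) - 0.5) / np.sqrt(var)
    z = np.where(var > 0, np.maximum(z, 0.0), 0.0)
    p = 2.0 * stats.norm.sf(z)
    return np.minimum(p, 1.0)


def gene_observed_stat(status_row, counts, *, method: str = "auto"):
    """Observed association for one gene: (two-sided rank-sum p, median diff).

    ``median_diff`` is ``median(counts | mutant) - median(counts | wild-type)``.
    ``method="auto"`` uses exact enumeration when both groups have <= 25
    samples and the counts are tie-free, otherwise the tie-corrected normal
    approximation; ``"exact"``/``"asymptotic"`` force a choice.
    """
    status = np.asarray(status_row, dtype=bool)
    counts = np.asarray(counts, dtype=float)
    mut, wt = counts[status], counts[~status]
    if len(mut) == 0 or len(wt) == 0:
        raise ValueError("need at least one mutant and one wild-type sample")
    median_diff = float(np.median(mut) - np.median(wt))
    ranks, tie_term = _rank_setup(counts)
    has_ties = len(np.unique(counts)) < len(counts)
    if method == "auto":
        method = "exact" if (max(len(mut), len(wt)) <= 25 and not has_ties) else "asymptotic"
    if method == "exact":
        res = stats.mannwhitneyu(mut, wt, alternative="two-sided", method="exact")
        return float(res.pvalue), median_diff
    if method == "asymptotic":
        W = ranks[status].sum()
        p = _asymptotic_p(np.array([W]), np.array([len(mut)]), len(counts), tie_term)[0]
        return float(p), median_diff
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# The burden-controlled permutation test


def burden_permutation_test(
    matrix: pd.DataFrame,
    counts,
    n_perm: int = 100_000,
    min_freq: float = 0.05,
    rng=None,
    *,
    mode: str = "smoothed",
    null_scope: str = "per_gene",
    n_trades: int | None = None,
) -> pd.DataFrame:
    """Permutation association of per-gene mutation status with context counts.

    Parameters
    ----------
    matrix : binary DataFrame, rows = genes, columns = samples; 1 iff the
        sample carries a qualifying mutation in the gene.
    counts : per-sample context counts aligned with the matrix columns
        (Series aligned by index, or positional array).
    n_perm : number of Curveball-permuted matrices (study default 100,000).
    min_freq : genes mutated in a fraction of samples strictly above this
        are analyzed (default 0.05).
    mode : ``"smoothed"`` (default) gives ``p_final = (1 + #{p_perm <=
        p_obs}) / (n_perm + 1)``, never exactly 0; ``"literal"`` gives the
        plain fraction of ``p_perm`` strictly below ``p_obs``.
    null_scope : ``"per_gene"`` compares each gene's p_obs with that gene's
        own permuted p-values; ``"pooled"`` compares against all genes'
        permuted p-values pooled.

    Returns a DataFrame (one row per analyzed gene) with ``n_mutant``,
    ``p_obs``, ``median_diff``, ``p_final`` and ``n_perm`` — the volcano-plot
    coordinates are (``median_diff``, ``p_final``).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("smoothed", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    if null_scope not in ("per_gene", "pooled"):
        raise ValueError(f"unknown null_scope {null_scope!r}")

    arr = matrix.values.astype(np.int8)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("matrix must be binary")
    if isinstance(counts, pd.Series):
        counts = counts.reindex(matrix.columns).values
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = arr.shape
    if len(counts) != n_samples:
        raise ValueError("counts not aligned with matrix columns")

    freq = arr.sum(axis=1) / n_samples
    keep = (freq > min_freq) & (arr.sum(axis=1) < n_samples)
    if not keep.any():
        raise ValueError(f"no genes mutated in more than {min_freq:.0%} of samples")
    genes = matrix.index[keep]
    sub = arr[keep]

    ranks, tie_term = _rank_setup(counts)
    n1 = sub.sum(axis=1)
    p_obs = _asymptotic_p(sub @ ranks, n1, n_samples, tie_term)
    median_diff = np.array(
        [np.median(counts[row == 1]) - np.median(counts[row == 0]) for row in sub]
    )

    if n_trades is None:
        n_trades = max(1, 5 * int(arr.sum()))
    hits = np.zeros(len(genes), dtype=np.int64)
    pooled_hits = np.zeros(len(genes), dtype=np.int64)
    work = arr.copy()
    for _ in range(n_perm):
        work[...] = arr
        _curveball_trades(work, int(n_trades), int(rng.integers(2**31)))
        psub = work[keep]
        p_perm = _asymptotic_p(psub @ ranks, psub.sum(axis=1), n_samples, tie_term)
        if mode == "smoothed":
            hits += p_perm <= p_obs
            if null_scope == "pooled":
                pooled_hits += (p_perm[None, :] <= p_obs[:, None]).sum(axis=1)
        else:
            hits += p_perm < p_obs
            if null_scope == "pooled":
                pooled_hits += (p_perm[None, :] < p_obs[:, None]).sum(axis=1)

    if null_scope == "pooled":
        denom = n_perm * len(genes)
        p_final = (
            (1 + pooled_hits) / (denom + 1) if mode == "smoothed" else pooled_hits / denom
        )
    else:
        p_final = (1 + hits) / (n_perm + 1) if mode == "smoothed" else hits / n_perm

    return pd.DataFrame(
        {
            "gene": genes,
            "n_mutant": n1,
            "p_obs": p_obs,
            "median_diff": median_diff,
            "p_final": p_final,
            "n_perm": n_perm,
        }
    ).set_index("gene")
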