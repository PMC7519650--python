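"""RNA-based immune scoring.

Each immune cell type is scored per sample as the mean normalized (log-scale)
expression of its predefined gene list; the overall immune score (IS) is the
sum of the cell-type scores.  An analogous mean score summarizes the
antigen-presenting machinery (APM).  Scores are dichotomized at the cohort
median ("above median" is literal: ties at the median go to low).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "chemomics") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def _resolve_genes(matrix: pd.DataFrame, genes, set_name: str, min_resolve_frac: float):
    """Case-insensitive match of set genes to matrix columns; error if too few resolve."""
    lookup = {str(c).upper(): c for c in matrix.columns}
    present = [lookup[g.upper()] for g in genes if g.upper() in lookup]
    missing = [g for g in genes if g.upper() not in lookup]
    if not present:
        raise ValueError(f"gene set {set_name!r}: no genes present in the expression matrix")
    if len(present) < min_resolve_frac * len(genes):
        raise ValueError(
            f"gene set {set_name!r}: only {len(present)}/{len(genes)} genes resolve "
            f"(below the {min_resolve_frac:.0%} floor); missing e.g. {missing[:5]}"
        )
    if missing:
        warnings.warn(f"gene set {set_name!r}: {len(missing)} genes not in matrix: {missing[:10]}")
    return present


def gene_set_score(
    matrix: pd.DataFrame, genes, *, set_name: str = "set", min_resolve_frac: float = 0.5
) -> pd.Series:
    """Per-sample mean expression over the set genes present in the matrix.

    ``matrix`` is samples x genes, normalized log-scale expression.
    """
    present = _resolve_genes(matrix, list(genes), set_name, min_resolve_frac)
    return matrix[present].mean(axis=1)


def immune_score(
    matrix: pd.DataFrame, collection: dict[str, list[str]], *, min_resolve_frac: float = 0.5
) -> pd.Series:
    """Overall immune score: the sum of all cell-type gene-set scores."""
    if not collection:
        raise ValueError("empty gene-set collection")
    scores = [
        gene_set_score(matrix, genes, set_name=name, min_resolve_frac=min_resolve_frac)
        for name, genes in collection.items()
    ]
    return sum(scores[1:], start=scores[0]).rename("immune_score")


def apm_score(matrix: pd.DataFrame, apm_genes, *, min_resolve_frac: float = 0.5) -> pd.Series:
    """Mean expression of the antigen-presenting-machinery gene set."""
    return gene_set_score(
        matrix, apm_genes, set_name="APM", min_resolve_frac=min_resolve_frac
    ).rename("apm_score")


def dichotomize(values: pd.Series, *, labels=("high", "low")) -> pd.Series:
    """Median split: strictly above the median -> high, ties at median -> low.

    All-identical input labels everything low and warns.
    """
    values = pd.Series(values).astype(float)
    finite = values.dropna()
    if len(finite) < 2:
        raise ValueError("need at least two finite values to dichotomize")
    med = finite.median()
    if finite.nunique() == 1:
        warnings.warn("all values identical; every sample labeled low")
    hi, lo = labels
    out = pd.Series(np.where(values > med, hi, lo), index=values.index)
    out[values.isna()] = np.nan
    return out


def immune_hot(matrix: pd.DataFrame, collection: dict[str, list[str]]) -> pd.Series:
    """Boolean per-sample flag: immune score strictly above the cohort median."""
    return dichotomize(immune_score(matrix, collection)) == "high"
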