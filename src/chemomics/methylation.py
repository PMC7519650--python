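"""Tumor-associated CpG selection, consensus clustering, and region summaries.

Beta values (methylated fraction, in [0, 1]) arrive probes x samples with a
probe annotation (chromosome, gene, region class).  Tumor-associated
hypermethylated sites are autosomal probes unmethylated in normal bladder
tissue and in leukocytes but methylated in at least ``min_tumors`` tumors;
the hypomethylated selection mirrors this in ``1 - beta``.  Samples are then
grouped by Monti-style consensus clustering over the selected probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

PROMOTER_CLASSES = ("TSS1500", "TSS200", "5'UTR")
BODY_CLASS = "Body"


def _mean_beta(ref) -> pd.Series:
    """Row-mean betas from a probes x samples frame, or pass a Series through."""
    if isinstance(ref, pd.DataFrame):
        return ref.mean(axis=1)
    return pd.Series(ref)


@dataclass(frozen=True)
class CpGSelection:
    probes: list[str]
    direction: str  # "hyper" or "hypo"
    n_requested: int


def select_tumor_cpgs(
    tumor: pd.DataFrame,
    normal_ref,
    leuko_ref,
    annotation: pd.DataFrame,
    direction: str = "hyper",
    n: int = 5000,
    *,
    low_thr: float = 0.2,
    high_thr: float = 0.3,
    min_tumors: int = 4,
) -> CpGSelection:
    """Select tumor-associated hyper- or hypomethylated autosomal CpG sites.

    hyper: reference (normal bladder and leukocyte) mean beta < ``low_thr``
    and beta > ``high_thr`` in at least ``min_tumors`` tumor samples.
    hypo: the same predicates applied to ``1 - beta``.  Eligible probes are
    ranked by the number of qualifying tumors, then by tumor beta variance,
    and the top ``n`` are returned (all survivors, with a warning, if fewer
    than ``n`` qualify).

    ``annotation`` is indexed by probe with at least ``chrom`` (autosomes
    are everything that is not X/Y/MT) and ``gene``/``region_class`` columns.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    common = tumor.index.intersection(annotation.index)
    t = tumor.loc[common]
    nb = _mean_beta(normal_ref).reindex(common)
    lk = _mean_beta(leuko_ref).reindex(common)
    if direction == "hypo":
        t, nb, lk = 1.0 - t, 1.0 - nb, 1.0 - lk

    chrom = annotation.loc[common, "chrom"].astype(str).str.removeprefix("chr")
    autosomal = ~chrom.isin(["X", "Y", "MT", "M"])
    ref_low = (nb < low_thr) & (lk < low_thr)
    n_meth = (t > high_thr).sum(axis=1)
    eligible = autosomal & ref_low & (n_meth >= min_tumors)

    surv = t[eligible]
    if surv.empty:
        raise ValueError("no probes satisfy the selection predicates")
    order = pd.DataFrame(
        {"n_meth": n_meth[eligible], "var": surv.var(axis=1)}
    ).sort_values(["n_meth", "var"], ascending=False)
    if len(order) < n:
        import warnings

        warnings.warn(f"only {len(order)} probes qualify (requested {n}); returning all")
    return CpGSelection(probes=list(order.index[:n]), direction=direction, n_requested=n)


@dataclass
class ConsensusResult:
    """Consensus-clustering output: labels at the chosen k, plus diagnostics."""

    k: int
    labels: pd.Series
    consensus: dict[int, pd.DataFrame] = field(repr=False)
    ambiguity: dict[int, float] = field(default_factory=dict)  # PAC per k


def consensus_cluster(
    data: pd.DataFrame,
    k_range=(2, 3, 4, 5, 6),
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    rng=None,
    *,
    k: int | None = None,
    linkage_method: str = "ward",
) -> ConsensusResult:
    """Monti-style consensus clustering of samples.

    ``data`` is samples x features (e.g. samples x selected CpG betas).  For
    each resample a fraction of samples is drawn without replacement and
    hierarchically clustered (Ward linkage, Euclidean distance); co-cluster
    frequencies among co-sampled pairs form the consensus matrix per k.
    Final labels come from hierarchical clustering of ``1 - consensus``.
    Unless ``k`` is fixed, it is chosen to minimize the proportion of
    ambiguous consensus entries (PAC, entries strictly between 0.1 and
    0.9) — the flattest consensus CDF between the 0/1 shoulders.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_samples = len(data)
    if n_samples < 2:
        raise ValueError("need at least two samples")
    ks = [k] if k is not None else [kk for kk in k_range if 2 <= kk <= n_samples - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    X = np.asarray(data, dtype=float)
    m = max(2, int(round(subsample_frac * n_samples)))

    together = {kk: np.zeros((n_samples, n_samples)) for kk in ks}
    sampled = np.zeros((n_samples, n_samples))
    for _ in range(n_resamples):
        idx = rng.choice(n_samples, size=m, replace=False)
        sampled[np.ix_(idx, idx)] += 1
        Z = linkage(X[idx], method=linkage_method)
        for kk in ks:
            lab = fcluster(Z, t=min(kk, m), criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            together[kk][np.ix_(idx, idx)] += same

    consensus, pac = {}, {}
    with np.errstate(invalid="ignore"):
        for kk in ks:
            C = np.where(sampled > 0, together[kk] / np.maximum(sampled, 1), 0.0)
            np.fill_diagonal(C, 1.0)
            C = (C + C.T) / 2.0
            consensus[kk] = pd.DataFrame(C, index=data.index, columns=data.index)
            off = C[np.triu_indices(n_samples, 1)]
            pac[kk] = float(((off > 0.1) & (off < 0.9)).mean()) if len(off) else 0.0

    chosen = ks[0] if k is not None else min(ks, key=lambda kk: (pac[kk], kk))
    D = 1.0 - consensus[chosen].values
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = pd.Series(
        fcluster(Z, t=chosen, criterion="maxclust"), index=data.index, name="cluster"
    )
    return ConsensusResult(k=chosen, labels=labels, consensus=consensus, ambiguity=pac)


def region_methylation(
    beta: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter and gene-body methylation per gene per sample.

    Promoter = mean beta over a gene's TSS1500/TSS200/5'UTR probes; body =
    mean over its Body probes.  Genes lacking a class get NaN there.
    Returns ``(promoter, body)``, each genes x samples.
    """
    ann = annotation.loc[beta.index.intersection(annotation.index)]
    genes = sorted(ann["gene"].dropna().unique())

    def summarize(classes) -> pd.DataFrame:
        mask = ann["region_class"].isin(classes)
        sub = beta.loc[ann.index[mask]]
        grouped = sub.groupby(ann.loc[mask, "gene"]).mean()
        return grouped.reindex(genes)

    return summarize(PROMOTER_CLASSES), summarize([BODY_CLASS])
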