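"""Allelic imbalance from segmented B-allele fractions.

Absolute copy-number calling is deliberately avoided (purity/heterogeneity
make it unreliable on this material); instead, segments whose mirrored BAF
deviation ``|BAF - 0.5|`` meets a sample-specific threshold — one third of
the maximum deviation after dropping poorly supported outlier segments —
are flagged as allelically imbalanced (LOH or one-allele amplification),
and the per-sample statistic is the percent of covered genome length they
span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEG_COLUMNS = ("sample_id", "chrom", "start", "end", "mean_baf", "n_snps")
#: chromosomes excluded from the covered-genome denominator by default
DEFAULT_EXCLUDED_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


def read_seg_table(path) -> pd.DataFrame:
    """SEG-like TSV with columns sample_id, chrom, start, end, mean_baf, n_snps."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if ((df["mean_baf"] < 0) | (df["mean_baf"] > 1)).any():
        raise ValueError("mean_baf outside [0, 1]")
    if (df["start"] > df["end"]).any():
        raise ValueError("segment start > end")
    return df


def baf_deviation(mean_baf) -> np.ndarray | float:
    """Mirrored BAF deviation ``|BAF - 0.5|`` in [0, 0.5]; 0 = balanced, 0.5 = LOH."""
    return np.abs(np.asarray(mean_baf, dtype=float) - 0.5) if np.ndim(mean_baf) else abs(
        float(mean_baf) - 0.5
    )


def _autosomal(track: pd.DataFrame, exclude_chroms) -> pd.DataFrame:
    return track[~track["chrom"].astype(str).isin(exclude_chroms)]


def ai_threshold(
    track: pd.DataFrame, min_snps: int = 10, exclude_chroms=DEFAULT_EXCLUDED_CHROMS
) -> float:
    """Sample-specific imbalance threshold: max mirrored deviation / 3.

    Outliers are removed before taking the maximum by dropping segments
    supported by fewer than ``min_snps`` SNPs (short noisy segments would
    otherwise dominate the maximum).
    """
    track = _autosomal(track, exclude_chroms)
    kept = track[track["n_snps"] >= min_snps]
    if kept.empty:
        raise ValueError("no segments survive the outlier (n_snps) filter")
    return float(baf_deviation(kept["mean_baf"]).max() / 3.0)


@dataclass(frozen=True)
class AIResult:
    """Allelic-imbalance call for one sample's segmented BAF track."""

    threshold: float
    ai_segments: pd.DataFrame  # flagged subset of the track
    percent_ai: float  # percent of covered genome length in imbalance


def ai_fraction(
    track: pd.DataFrame, threshold: float, exclude_chroms=DEFAULT_EXCLUDED_CHROMS
) -> AIResult:
    """Flag imbalanced segments and compute percent genome in allelic imbalance.

    A segment is flagged when its mirrored deviation is >= ``threshold``
    (strictly > 0 in the degenerate threshold-0 case, so a fully balanced
    genome reports 0%).  The denominator is the total covered (segmented)
    length, not the full genome.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    track = _autosomal(track, exclude_chroms)
    if track.empty:
        raise ValueError("empty BAF track")
    dev = baf_deviation(track["mean_baf"])
    flagged = dev >= threshold if threshold > 0 else dev > 0
    lengths = (track["end"] - track["start"] + 1).astype(float)
    covered = lengths.sum()
    percent = 100.0 * float(lengths[np.asarray(flagged)].sum()) / float(covered)
    return AIResult(
        threshold=float(threshold),
        ai_segments=track[np.asarray(flagged)].reset_index(drop=True),
        percent_ai=percent,
    )


def call_allelic_imbalance(
    track: pd.DataFrame, min_snps: int = 10, exclude_chroms=DEFAULT_EXCLUDED_CHROMS
) -> AIResult:
    """Threshold then flag, in one call (the per-sample pipeline step)."""
    thr = ai_threshold(track, min_snps=min_snps, exclude_chroms=exclude_chroms)
    return ai_fraction(track, thr, exclude_chroms=exclude_chroms)


def percent_ai_by_sample(seg_table: pd.DataFrame, min_snps: int = 10) -> pd.Series:
    """Percent genome in allelic imbalance for every sample in a SEG table."""
    out = {}
    for sample_id, track in seg_table.groupby("sample_id"):
        out[sample_id] = call_allelic_imbalance(track, min_snps=min_snps).percent_ai
    return pd.Series(out).sort_index()
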