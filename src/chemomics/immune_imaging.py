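"""Protein-level (imaging) immune scoring and immune subtypes.

Inputs are already-resolved positive-cell counts per sample and region
(intratumoral / peritumoral) from automated image quantification; marker
gating (e.g. CTL = CD8+CD3+FOXP3-) happens upstream.  Cell fractions are
positive counts over total cells in the region; the protein immune score
(IS) sums the six immune cell fractions; MHC staining is summarized with
the H-score; samples are median-split per region and mapped to the
desert / excluded / infiltrated immune subtypes.
"""

from __future__ import annotations

import pandas as pd

from .immune_expression import dichotomize

IMMUNE_CELL_TYPES = ("t_helper", "ctl", "treg", "b_cell", "m1", "m2")
REGIONS = ("intratumoral", "peritumoral")


def cell_fraction(positive_count, total_cells) -> float:
    """Fraction of positive cells in a region: positive / total, in [0, 1]."""
    if total_cells <= 0:
        raise ValueError("total_cells must be positive")
    if positive_count < 0 or positive_count > total_cells:
        raise ValueError("positive_count must lie in [0, total_cells]")
    return positive_count / total_cells


def h_score(pct_low: float, pct_moderate: float, pct_high: float) -> float:
    """Staining-intensity H-score: 1*(%low) + 2*(%moderate) + 3*(%high), in [0, 300]."""
    for p in (pct_low, pct_moderate, pct_high):
        if p < 0:
            raise ValueError("intensity percentages must be >= 0")
    if pct_low + pct_moderate + pct_high > 100 + 1e-9:
        raise ValueError("intensity percentages sum above 100")
    return 1.0 * pct_low + 2.0 * pct_moderate + 3.0 * pct_high


def protein_immune_score(fractions: dict[str, float]) -> float:
    """Protein IS for one region: the sum of the six immune cell fractions."""
    missing = [c for c in IMMUNE_CELL_TYPES if c not in fractions]
    if missing:
        raise ValueError(f"missing cell-type fractions: {missing}")
    return float(sum(fractions[c] for c in IMMUNE_CELL_TYPES))


def immune_subtype(intra_group: str, peri_group: str) -> str:
    """Immune subtype from the two region-level IS groups.

    (low, low) -> desert; (low, high) -> excluded; (high, anything) ->
    infiltrated.
    """
    for g in (intra_group, peri_group):
        if g not in ("low", "high"):
            raise ValueError(f"group label must be 'low' or 'high', got {g!r}")
    if intra_group == "high":
        return "infiltrated"
    return "excluded" if peri_group == "high" else "desert"


def region_scores(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-region protein immune score from a counts table.

    ``counts`` has one row per sample x region with columns ``sample_id``,
    ``region``, ``total_cells`` and ``<cell_type>_count`` for the six
    immune cell types.  Returns a samples x regions IS table.
    """
    rows = {}
    for (sample, region), grp in counts.groupby(["sample_id", "region"]):
        row = grp.iloc[0]
        fracs = {
            c: cell_fraction(row[f"{c}_count"], row["total_cells"]) for c in IMMUNE_CELL_TYPES
        }
        rows[(sample, region)] = protein_immune_score(fracs)
    ser = pd.Series(rows)
    ser.index.names = ["sample_id", "region"]
    return ser.unstack("region")


def immune_subtypes(counts: pd.DataFrame) -> pd.Series:
    """Desert / excluded / infiltrated labels for a cohort quantification table.

    The IS median split is computed within each region across the cohort.
    """
    scores = region_scores(counts)
    groups = {r: dichotomize(scores[r]) for r in REGIONS if r in scores.columns}
    missing = [r for r in REGIONS if r not in groups]
    if missing:
        raise ValueError(f"missing regions in counts table: {missing}")
    return pd.Series(
        {
            s: immune_subtype(groups["intratumoral"][s], groups["peritumoral"][s])
            for s in scores.index
        },
        name="immune_subtype",
    )


def pd_axis_groups(pd1_fractions: pd.Series, pdl1_fractions: pd.Series) -> pd.DataFrame:
    """Median-dichotomized PD-1 and PD-L1 labels and their combined group.

    Each marker is split independently at its cohort median (ties -> low).
    Returns a DataFrame with ``pd1``, ``pdl1`` and the combined
    ``"PD-1 <hi/lo>/PD-L1 <hi/lo>"`` group label.
    """
    pd1 = dichotomize(pd.Series(pd1_fractions))
    pdl1 = dichotomize(pd.Series(pdl1_fractions)).reindex(pd1.index)
    combined = pd.Series(
        [f"PD-1 {a}/PD-L1 {b}" for a, b in zip(pd1, pdl1)], index=pd1.index
    )
    return pd.DataFrame({"pd1": pd1, "pdl1": pdl1, "combined": combined})
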