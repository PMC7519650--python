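"""Somatic variant tables: reading, impact filtering, and the damaging-DDR rule.

Variants arrive as MAF-like TSV, one row per somatic call, already annotated
upstream (SnpEff impact class; PolyPhen-2 and MutationAssessor verdicts for
missense variants).  Coordinates are 1-based inclusive.  This module never
re-runs any predictor; it applies the classification rules to the verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
POLYPHEN_VERDICTS = ("benign", "possibly_damaging", "probably_damaging", "absent")
MA_VERDICTS = ("neutral", "low", "medium", "high", "absent")
VARIANT_CLASSES = ("SNV", "insertion", "deletion")

REQUIRED_COLUMNS = (
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "impact",
    "polyphen_verdict",
    "mutationassessor_verdict",
    "vaf",
    "alt_reads",
    "total_reads",
)


class VariantTableError(ValueError):
    """Raised with one message per malformed row (1-based file line numbers)."""


def _validate_rows(df: pd.DataFrame, first_data_line: int = 2) -> list[str]:
    errors = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = first_data_line + i
        if row.impact not in IMPACT_CLASSES:
            errors.append(f"line {line}: impact {row.impact!r} not one of {IMPACT_CLASSES}")
        if row.variant_class not in VARIANT_CLASSES:
            errors.append(f"line {line}: variant_class {row.variant_class!r} invalid")
        if not (0.0 <= row.vaf <= 1.0):
            errors.append(f"line {line}: vaf {row.vaf} outside [0, 1]")
        if row.alt_reads > row.total_reads:
            errors.append(f"line {line}: alt_reads {row.alt_reads} > total_reads {row.total_reads}")
        if row.pos < 1:
            errors.append(f"line {line}: pos {row.pos} is not 1-based positive")
    return errors


@dataclass(frozen=True)
class VariantCatalog:
    """A validated collection of somatic variant records across samples."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise VariantTableError(f"missing required columns: {missing}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def snv_counts(self) -> pd.Series:
        """Per-sample SNV count (samples with no SNVs included as 0)."""
        return self._class_counts(("SNV",))

    def indel_counts(self) -> pd.Series:
        """Per-sample insertion + deletion count."""
        return self._class_counts(("insertion", "deletion"))

    def _class_counts(self, classes) -> pd.Series:
        mask = self.df["variant_class"].isin(classes)
        counts = self.df.loc[mask].groupby("sample_id").size()
        return counts.reindex(self.samples, fill_value=0).astype(int)

    def __len__(self) -> int:
        return len(self.df)


def read_variant_table(path) -> VariantCatalog:
    """Read and validate a MAF-like TSV into a :class:`VariantCatalog`.

    Unknown columns are preserved as opaque annotations.  Malformed rows are
    reported collectively, each with its 1-based file line number.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "gene": str, "chrom": str, "ref": str, "alt": str},
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"missing required columns: {missing}")
    try:
        df["pos"] = df["pos"].astype(int)
        df["alt_reads"] = df["alt_reads"].astype(int)
        df["total_reads"] = df["total_reads"].astype(int)
        df["vaf"] = df["vaf"].astype(float)
    except (ValueError, TypeError) as exc:
        raise VariantTableError(f"unparseable numeric column: {exc}") from exc
    errors = _validate_rows(df)
    if errors:
        raise VariantTableError("; ".join(errors))
    return VariantCatalog(df)


def write_variant_table(catalog: VariantCatalog, path) -> None:
    catalog.df.to_csv(path, sep="\t", index=False)


def filter_by_impact(catalog: VariantCatalog, levels) -> VariantCatalog:
    """Keep only records whose SnpEff impact class is in ``levels``.

    Idempotent; ``levels`` must be a nonempty subset of the four classes.
    """
    levels = set(levels)
    if not levels:
        raise ValueError("levels must be a nonempty set of impact classes")
    bad = levels - set(IMPACT_CLASSES)
    if bad:
        raise ValueError(f"unknown impact classes: {sorted(bad)}")
    return VariantCatalog(catalog.df[catalog.df["impact"].isin(levels)].reset_index(drop=True))


def classify_damaging(
    impact: str,
    polyphen_verdict: str = "absent",
    mutationassessor_verdict: str = "absent",
    *,
    rule: str = "and",
) -> bool | None:
    """Damaging-mutation rule for DDR analysis.

    All loss-of-function (HIGH impact) mutations are damaging.  Missense
    (MODERATE impact) mutations are judged by the predictor verdicts:
    PolyPhen-2 flags ``possibly_damaging``/``probably_damaging`` and
    MutationAssessor flags ``medium``/``high``.  Under ``rule="and"``
    (default, the conservative reading) both predictors must flag; under
    ``rule="or"`` either suffices.  LOW/MODIFIER impacts are not damaging.

    Returns ``None`` ("unevaluable") for a MODERATE-impact variant missing
    either predictor verdict — never a silent False.
    """
    if impact not in IMPACT_CLASSES:
        raise ValueError(f"unknown impact {impact!r}")
    if rule not in ("and", "or"):
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    if impact == "HIGH":
        return True
    if impact != "MODERATE":
        return False
    if polyphen_verdict == "absent" or mutationassessor_verdict == "absent":
        return None
    pp = polyphen_verdict in ("possibly_damaging", "probably_damaging")
    ma = mutationassessor_verdict in ("medium", "high")
    return (pp and ma) if rule == "and" else (pp or ma)


def classify_damaging_record(record, *, rule: str = "and") -> bool | None:
    """Apply :func:`classify_damaging` to a variant record (row namedtuple/Series)."""
    return classify_damaging(
        record.impact, record.polyphen_verdict, record.mutationassessor_verdict, rule=rule
    )


def ddr_status(catalog: VariantCatalog, ddr_genes, *, rule: str = "and") -> pd.Series:
    """Per-sample flag: does the sample carry >= 1 damaging mutation in a DDR gene?

    ``ddr_genes`` is a nonempty iterable of gene symbols (the study's DDR
    list is supplied by the user).  Unevaluable records (missense lacking a
    predictor verdict) are excluded from the tally rather than counted
    either way.
    """
    genes = set(ddr_genes)
    if not genes:
        raise ValueError("DDR gene list is empty")
    df = catalog.df[catalog.df["gene"].isin(genes)]
    damaging = df.apply(
        lambda r: classify_damaging(
            r["impact"], r["polyphen_verdict"], r["mutationassessor_verdict"], rule=rule
        )
        is True,
        axis=1,
    ) if len(df) else pd.Series(dtype=bool)
    positive = set(df.loc[list(damaging[damaging].index), "sample_id"]) if len(df) else set()
    return pd.Series(
        [s in positive for s in catalog.samples], index=catalog.samples, dtype=bool
    )


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
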