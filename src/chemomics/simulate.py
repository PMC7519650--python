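"""Synthetic cohorts with the statistical structure the pipeline assumes.

Nothing here claims to model the biology of real tumors: the generator is a
stated world in which every downstream statistic has a known expectation,
so the whole pipeline is testable without controlled-access data.  Defaults
emulate the shape of a 300-tumor chemotherapy cohort: dispersed SNV/indel
burdens, per-sample signature mixtures over SBS1/SBS2/SBS5/SBS13 with a
BRCA2-linked SBS5 excess, segmented BAF tracks with a planted fraction of
the genome in allelic imbalance, expression with subtype and immune
structure, imaging cell counts, and response labels drawn from a logistic
model on the true covariates.

All randomness flows from a single integer seed; the same config and seed
reproduce every table byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .channels import CHANNELS, channel_parts
from .signatures import SIGNATURE_NAMES, load_signature_matrix
from .variants import VariantCatalog

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Synthetic reference sequence and trinucleotide context index


def synthetic_reference(length: int = 1_000_000, seed: int = 0, chrom: str = "chr1"):
    """A seeded random reference sequence with a known trinucleotide makeup.

    Returns ``(sequences, context_index)`` where ``sequences`` maps the
    chromosome name to its sequence string and ``context_index`` maps each
    pyrimidine-centred trinucleotide ``(5', ref, 3')`` to the sorted array
    of 1-based positions carrying that context (purine-centred positions
    are folded to the pyrimidine strand).
    """
    rng = np.random.default_rng(seed)
    seq = "".join(BASES[rng.integers(0, 4, size=length)])
    return {chrom: seq}, build_context_index(seq)


def build_context_index(seq: str) -> dict[tuple[str, str, str], np.ndarray]:
    # base codes 0..3 = A,C,G,T; complement is 3 - code
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    b, f, t = codes[1:-1], codes[:-2], codes[2:]
    pyr = (b == 1) | (b == 3)
    kf = np.where(pyr, f, 3 - t)
    kb = np.where(pyr, b, 3 - b)
    kt = np.where(pyr, t, 3 - f)
    key = kf * 16 + kb * 4 + kt
    positions = np.arange(2, len(seq), dtype=np.int64)  # 1-based interior positions
    order = np.argsort(key, kind="stable")
    sorted_keys = key[order]
    bounds = np.flatnonzero(np.diff(sorted_keys)) + 1
    groups = np.split(positions[order], bounds)
    uniq = np.concatenate(([sorted_keys[0]], sorted_keys[bounds])) if len(sorted_keys) else []
    bases = "ACGT"
    return {
        (bases[k // 16], bases[(k % 16) // 4], bases[k % 4]): g
        for k, g in zip(uniq, groups)
    }


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Cohort configuration


@dataclass
class CohortSimConfig:
    """Stated-world parameters for the synthetic cohort.

    Count burdens use a negative-binomial (gamma-Poisson) model because the
    emulated cohort's burdens span two orders of magnitude; ``*_dispersion``
    is the gamma shape (smaller = wider).  ``exposure_priors`` are Dirichlet
    concentrations over (SBS1, SBS2, SBS5, SBS13); the default favours the
    SBS5 and APOBEC mixtures that dominate bladder tumors.  The response
    model is logistic in the true high-genomic-instability flag, Ba/Sq
    subtype, and immune-hot state.
    """

    n_samples: int = 300
    snv_rate: float = 600.0  # mean SNVs per sample
    snv_dispersion: float = 1.5
    indel_rate: float = 60.0
    indel_dispersion: float = 1.2
    exposure_priors: tuple = (0.8, 1.2, 2.0, 1.2)  # SBS1, SBS2, SBS5, SBS13
    brca2_rate: float = 0.08
    brca2_sbs5_multiplier: float = 2.0
    ai_beta_params: tuple = (2.0, 4.0)  # Beta for true AI fraction (of genome)
    subtype_probs: dict = field(
        default_factory=lambda: {"LumP": 0.35, "LumU": 0.15, "Stroma-rich": 0.15, "Ba/Sq": 0.35}
    )
    response_model: dict = field(
        default_factory=lambda: {"intercept": 0.0, "hgi": 1.0, "basq": -1.0, "immune": 0.5}
    )
    nac_fraction: float = 62.0 / 300.0
    reference_length: int = 200_000
    min_snvs: int = 10  # floor on the dispersed SNV count
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        for name in ("snv_rate", "indel_rate", "snv_dispersion", "indel_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for p in (self.brca2_rate, self.nac_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        probs = np.array(list(self.subtype_probs.values()))
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_probs must be nonnegative and sum to 1")
        if len(self.exposure_priors) != 4 or any(a <= 0 for a in self.exposure_priors):
            raise ValueError("exposure_priors must be 4 positive Dirichlet weights")


# ---------------------------------------------------------------------------
# Building blocks


def _nbinom(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Gamma-Poisson draws with the given mean and gamma shape ``dispersion``."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam)


def sample_snv_channels(rng, per_signature_counts: np.ndarray, sig_matrix) -> np.ndarray:
    """96-channel counts from per-signature mutation counts (mixture draw)."""
    channels = np.zeros(96, dtype=np.int64)
    for s, n in enumerate(per_signature_counts):
        if n > 0:
            channels += rng.multinomial(int(n), sig_matrix.values[:, s])
    return channels


def _positions_for_channels(rng, channels: np.ndarray, context_index) -> list[tuple[int, int]]:
    """(channel, position) pairs drawn from the reference context index."""
    out = []
    for c, n in enumerate(channels):
        if n == 0:
            continue
        five, ref, _, three = channel_parts(c)
        pool = context_index.get((five, ref, three))
        if pool is None or len(pool) == 0:
            raise ValueError(f"reference lacks context {five}{ref}{three}")
        pos = rng.choice(pool, size=int(n), replace=len(pool) < n)
        out.extend((c, int(p)) for p in pos)
    return out


GENE_POOL = [f"GENE{i:03d}" for i in range(1, 151)]
DDR_GENES = ["BRCA2", "ERCC2", "ATM", "BRCA1", "RB1", "PALB2", "FANCA", "CHEK2"]
IMPACT_PROBS = {"HIGH": 0.05, "MODERATE": 0.60, "LOW": 0.20, "MODIFIER": 0.15}


def simulate_baf_track(
    rng,
    percent_ai: float,
    sample_id: str = "S1",
    n_segments: int = 40,
    noise_sd: float = 0.02,
    genome_length: int = 2_800_000_000,
) -> pd.DataFrame:
    """A segmented BAF track with exactly ``percent_ai`` percent of its covered
    length in allelic imbalance.

    Imbalanced segments get mirrored deviations drawn from U(0.25, 0.45)
    (so the max-deviation/3 threshold, at most 0.15, always flags them);
    balanced segments sit at BAF 0.5.  Gaussian segment noise ``noise_sd``
    is added to every mean BAF.  A boundary segment is split so the planted
    fraction is hit exactly.
    """
    if not (0.0 <= percent_ai <= 100.0):
        raise ValueError("percent_ai must be in [0, 100]")
    lengths = rng.dirichlet(np.full(n_segments, 2.0)) * genome_length
    lengths = np.maximum(lengths.astype(np.int64), 1000)
    target = percent_ai / 100.0 * lengths.sum()
    order = rng.permutation(n_segments)
    rows = []
    pos = 1
    acc = 0
    for si in order:
        L = int(lengths[si])
        if acc < target:
            take = min(L, int(round(target - acc)))
            if take > 0:
                dev = rng.uniform(0.25, 0.45)
                rows.append((pos, pos + take - 1, 0.5 - dev, True))
                pos += take
                acc += take
            if take < L:
                rows.append((pos, pos + (L - take) - 1, 0.5, False))
                pos += L - take
        else:
            rows.append((pos, pos + L - 1, 0.5, False))
            pos += L
    df = pd.DataFrame(rows, columns=["start", "end", "mean_baf", "true_ai"])
    df["mean_baf"] = np.clip(df["mean_baf"] + rng.normal(0, noise_sd, len(df)), 0.0, 1.0)
    df["n_snps"] = rng.poisson(500, len(df)) + 20
    df["chrom"] = "1"
    df["sample_id"] = sample_id
    return df[["sample_id", "chrom", "start", "end", "mean_baf", "n_snps", "true_ai"]]


def default_immune_gene_sets() -> dict[str, list[str]]:
    """The generator's own immune cell-type gene lists (synthetic stand-ins)."""
    cell_types = ["T_helper", "CTL", "Treg", "B_cell", "NK", "M1", "M2", "DC"]
    return {ct: [f"{ct}_G{i}" for i in range(1, 11)] for ct in cell_types}


APM_GENES = [f"APM_G{i}" for i in range(1, 9)]
BASAL_GENES = [f"BASAL_G{i}" for i in range(1, 11)]


# ---------------------------------------------------------------------------
# The cohort generator


@dataclass
class SimulatedCohort:
    """Everything the pipeline consumes, plus the sealed ground truth."""

    config: CohortSimConfig
    reference: dict[str, str]
    variant_catalog: VariantCatalog
    baf_tracks: pd.DataFrame
    expression: pd.DataFrame
    cell_counts: pd.DataFrame
    clinical: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: dict

    def write(self, outdir) -> None:
        """Serialize in the formats the pipeline reads (TSV/FASTA/JSON)."""
        from pathlib import Path

        from .immune_expression import write_gmt

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, out / "reference.fa")
        self.variant_catalog.df.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.baf_tracks.to_csv(out / "baf_segments.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.cell_counts.to_csv(out / "cell_counts.tsv", sep="\t", index=False)
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        write_gmt(self.gene_sets, out / "immune_sets.gmt")
        with open(out / "truth.json", "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def simulate_cohort(config: CohortSimConfig | None = None) -> SimulatedCohort:
    """Draw a full synthetic cohort from the stated world of ``config``."""
    if config is None:
        config = CohortSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    sig_matrix = load_signature_matrix()
    reference, context_index = synthetic_reference(
        length=config.reference_length, seed=config.seed + 1
    )
    chrom = next(iter(reference))
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    # --- latent per-sample structure -------------------------------------
    thetas = rng.dirichlet(np.asarray(config.exposure_priors, dtype=float), size=n)
    brca2 = rng.random(n) < config.brca2_rate
    subtypes = rng.choice(
        list(config.subtype_probs), p=list(config.subtype_probs.values()), size=n
    )
    immune_hot = rng.random(n) < 0.5
    true_ai = 100.0 * rng.beta(*config.ai_beta_params, size=n)

    snv_totals = np.maximum(
        _nbinom(rng, config.snv_rate, config.snv_dispersion, n), config.min_snvs
    )
    indel_totals = np.maximum(_nbinom(rng, config.indel_rate, config.indel_dispersion, n), 1)

    # per-signature counts; BRCA2-mutant samples get an SBS5 excess
    per_sig = np.array([rng.multinomial(int(t), th) for t, th in zip(snv_totals, thetas)])
    sbs5_col = SIGNATURE_NAMES.index("SBS5")
    extra = np.where(
        brca2, np.round(per_sig[:, sbs5_col] * (config.brca2_sbs5_multiplier - 1.0)), 0
    ).astype(np.int64)
    per_sig[:, sbs5_col] += extra
    snv_totals = per_sig.sum(axis=1)

    # --- variant catalog (vectorized per sample) ---------------------------
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    impacts = np.array(list(IMPACT_PROBS))
    impact_p = np.array(list(IMPACT_PROBS.values()))
    frames = []
    columns = [
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
    ]

    def read_support(m, mean_vaf_a=2.0, mean_vaf_b=6.0):
        total = np.maximum(10, rng.poisson(100, size=m))
        alt = rng.binomial(total, rng.beta(mean_vaf_a, mean_vaf_b, size=m))
        return alt, total

    for i, sample in enumerate(samples):
        channels = sample_snv_channels(rng, per_sig[i], sig_matrix)
        pairs = _positions_for_channels(rng, channels, context_index)
        m = len(pairs)
        refs, alts, poss = [], [], []
        for c, pos in pairs:
            _, ref, alt, _ = channel_parts(c)
            if reference[chrom][pos - 1] != ref:  # purine strand in the reference
                ref, alt = comp[ref], comp[alt]
            refs.append(ref)
            alts.append(alt)
            poss.append(pos)
        alt_reads, totals = read_support(m)
        snv = pd.DataFrame(
            {
                "sample_id": sample,
                "gene": rng.choice(GENE_POOL, size=m),
                "chrom": chrom,
                "pos": poss,
                "ref": refs,
                "alt": alts,
                "variant_class": "SNV",
                "impact": rng.choice(impacts, p=impact_p, size=m),
                "polyphen_verdict": rng.choice(
                    ["benign", "possibly_damaging", "probably_damaging"], size=m
                ),
                "mutationassessor_verdict": rng.choice(
                    ["neutral", "low", "medium", "high"], size=m
                ),
                "vaf": alt_reads / totals,
                "alt_reads": alt_reads,
                "total_reads": totals,
            },
            columns=columns,
        )
        k = int(indel_totals[i])
        ipos = rng.integers(2, len(reference[chrom]) - 2, size=k)
        irefs = np.array([reference[chrom][p - 1] for p in ipos])
        is_ins = rng.random(k) < 0.5
        ialt_reads, itotals = read_support(k)
        indel = pd.DataFrame(
            {
                "sample_id": sample,
                "gene": rng.choice(GENE_POOL, size=k),
                "chrom": chrom,
                "pos": ipos,
                "ref": np.where(is_ins, irefs, np.char.add(irefs, "A")),
                "alt": np.where(is_ins, np.char.add(irefs, "A"), irefs),
                "variant_class": np.where(is_ins, "insertion", "deletion"),
                "impact": rng.choice(impacts, p=impact_p, size=k),
                "polyphen_verdict": "absent",
                "mutationassessor_verdict": "absent",
                "vaf": ialt_reads / itotals,
                "alt_reads": ialt_reads,
                "total_reads": itotals,
            },
            columns=columns,
        )
        frames.extend([snv, indel])
        if brca2[i]:
            pos = int(rng.integers(2, len(reference[chrom]) - 2))
            total = max(10, int(rng.poisson(100)))
            alt_reads1 = int(rng.binomial(total, 0.4))
            ref = reference[chrom][pos - 1]
            frames.append(
                pd.DataFrame(
                    [
                        (
                            sample,
                            "BRCA2",
                            chrom,
                            pos,
                            ref,
                            "T" if ref != "T" else "A",
                            "SNV",
                            "HIGH",
                            "absent",
                            "absent",
                            alt_reads1 / total,
                            alt_reads1,
                            total,
                        )
                    ],
                    columns=columns,
                )
            )
    catalog = VariantCatalog(pd.concat(frames, ignore_index=True))

    # --- BAF tracks --------------------------------------------------------
    baf = pd.concat(
        [
            simulate_baf_track(rng, true_ai[i], sample_id=s, n_segments=40)
            for i, s in enumerate(samples)
        ],
        ignore_index=True,
    )

    # --- expression with immune + subtype structure ------------------------
    gene_sets = default_immune_gene_sets()
    immune_genes = [g for gs in gene_sets.values() for g in gs]
    background = [f"BG_G{i}" for i in range(1, 301)]
    genes = immune_genes + APM_GENES + BASAL_GENES + background
    expr = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n, len(genes))), index=samples, columns=genes
    )
    expr.loc[immune_hot, immune_genes] += 1.0
    expr.loc[immune_hot, APM_GENES] += 0.8
    expr.loc[subtypes == "Ba/Sq", BASAL_GENES] += 2.0

    # --- imaging cell counts ------------------------------------------------
    cc_rows = []
    from .immune_imaging import IMMUNE_CELL_TYPES

    for i, s in enumerate(samples):
        for region in ("intratumoral", "peritumoral"):
            total = int(rng.poisson(2000)) + 200
            base = 0.04 if immune_hot[i] else 0.015
            row = {"sample_id": s, "region": region, "total_cells": total}
            for ct in IMMUNE_CELL_TYPES:
                frac = np.clip(rng.normal(base, 0.01), 0.0, 0.3)
                row[f"{ct}_count"] = int(round(frac * total))
            row["pd1_count"] = int(rng.binomial(total, np.clip(rng.normal(base, 0.01), 0, 0.5)))
            row["pdl1_count"] = int(rng.binomial(total, np.clip(rng.normal(0.02, 0.01), 0, 0.5)))
            cc_rows.append(row)
    cell_counts = pd.DataFrame(cc_rows)

    # --- true instability features and response -----------------------------
    sbs5_counts = per_sig[:, sbs5_col].astype(float)
    med_sbs5 = np.median(sbs5_counts)
    med_indel = np.median(indel_totals)
    med_ai = np.median(true_ai)
    hgi = (
        (sbs5_counts > med_sbs5)
        | (indel_totals > med_indel)
        | (true_ai > med_ai)
        | brca2
    )
    basq = subtypes == "Ba/Sq"
    rm = config.response_model
    logit = (
        rm["intercept"]
        + rm["hgi"] * hgi.astype(float)
        + rm["basq"] * basq.astype(float)
        + rm["immune"] * immune_hot.astype(float)
    )
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    response = rng.random(n) < p_resp

    # --- clinical records consistent with the drawn responses ---------------
    nac = rng.random(n) < config.nac_fraction
    clin_rows = []
    for i, s in enumerate(samples):
        rec = {
            "sample_id": s,
            "treatment_context": "NAC" if nac[i] else "first_line",
            "post_cx_stage": "",
            "recist": "",
            "bladder_intact": False,
            "post_cr_path_stage": "",
        }
        if nac[i]:
            rec["post_cx_stage"] = (
                str(rng.choice(["pT0N0", "pTaN0", "CISN0"], p=[0.6, 0.3, 0.1]))
                if response[i]
                else str(rng.choice(["pT2N0", "pT3N0", "pT2N1"], p=[0.4, 0.3, 0.3]))
            )
        else:
            intact = bool(rng.random() < 0.55)
            rec["bladder_intact"] = intact
            if response[i]:
                rec["recist"] = str(rng.choice(["CR", "PR"], p=[0.3, 0.7]))
                if rec["recist"] == "CR" and intact:
                    rec["post_cr_path_stage"] = str(rng.choice(["pT0", "pTa"]))
            else:
                rec["recist"] = str(rng.choice(["SD", "PD"]))
        clin_rows.append(rec)
    clinical = pd.DataFrame(clin_rows)

    truth = {
        "exposure_fractions": {
            s: dict(zip(SIGNATURE_NAMES, per_sig[i] / max(1, per_sig[i].sum())))
            for i, s in enumerate(samples)
        },
        "per_signature_counts": {s: per_sig[i] for i, s in enumerate(samples)},
        "snv_totals": dict(zip(samples, snv_totals)),
        "indel_totals": dict(zip(samples, indel_totals)),
        "true_ai_percent": dict(zip(samples, true_ai)),
        "brca2_mutated": dict(zip(samples, brca2)),
        "subtype": dict(zip(samples, subtypes)),
        "immune_hot": dict(zip(samples, immune_hot)),
        "hgi": dict(zip(samples, hgi)),
        "response": dict(zip(samples, response)),
        "response_model": dict(rm),
        "config": asdict(config),
    }
    return SimulatedCohort(
        config=config,
        reference=reference,
        variant_catalog=catalog,
        baf_tracks=baf,
        expression=expr,
        cell_counts=cell_counts,
        clinical=clinical,
        gene_sets=gene_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Paired primary/metastasis simulation


def simulate_paired_tumors(
    n_shared: int,
    n_private_primary: int,
    n_private_met: int,
    trunk_exposures=None,
    branch_exposures=None,
    mean_depth: int = 100,
    seed: int = 0,
    reference_length: int = 200_000,
) -> dict:
    """A primary/metastasis pair with planted shared and private mutations.

    Shared (trunk) mutations appear in both samples at high VAF (clonal,
    Beta(8, 8) around 0.5 of the diploid maximum); metastasis-private
    mutations at lower VAF (subclonal, Beta(2, 8)); primary-private at
    intermediate VAF.  Trinucleotide contexts of shared mutations are drawn
    from ``trunk_exposures`` (fractions over SBS1/SBS2/SBS5/SBS13, default
    uniform) and private ones from ``branch_exposures``.  Per-position read
    counts are emitted for both samples at every union position (binomial
    reads at Poisson(``mean_depth``) coverage).

    Returns a dict with ``calls``, ``readcounts``, ``union_variants``,
    ``reference`` and a ``truth`` record of the planted partition.
    """
    for v in (n_shared, n_private_primary, n_private_met):
        if v < 0:
            raise ValueError("mutation counts must be nonnegative")
    rng = np.random.default_rng(seed)
    sig_matrix = load_signature_matrix()
    trunk = np.asarray(trunk_exposures if trunk_exposures is not None else [0.25] * 4, float)
    branch = np.asarray(branch_exposures if branch_exposures is not None else [0.25] * 4, float)
    trunk, branch = trunk / trunk.sum(), branch / branch.sum()
    reference, context_index = synthetic_reference(length=reference_length, seed=seed + 17)
    chrom = next(iter(reference))

    def draw(n, mix):
        per_sig = rng.multinomial(n, mix) if n else np.zeros(4, dtype=int)
        channels = sample_snv_channels(rng, per_sig, sig_matrix)
        recs = []
        for c, pos in _positions_for_channels(rng, channels, context_index):
            five, ref, alt, three = channel_parts(c)
            actual_ref = reference[chrom][pos - 1]
            if actual_ref != ref:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                ref, alt = comp[ref], comp[alt]
            recs.append((chrom, pos, ref, alt))
        return recs

    shared = draw(n_shared, trunk)
    prim_priv = draw(n_private_primary, branch)
    met_priv = draw(n_private_met, branch)

    def vafs(n, a, b):
        return rng.beta(a, b, size=n) * 0.9 + 0.02

    vaf = {}
    for recs, (a, b) in ((shared, (8, 8)), (prim_priv, (4, 8)), (met_priv, (2, 8))):
        for r, v in zip(recs, vafs(len(recs), a, b)):
            vaf[r] = v

    calls_rows, rc_rows = [], []
    for sample, present in (("primary", shared + prim_priv), ("met", shared + met_priv)):
        present_set = set(present)
        for r in shared + prim_priv + met_priv:
            depth = max(5, int(rng.poisson(mean_depth)))
            alt_reads = int(rng.binomial(depth, vaf[r])) if r in present_set else 0
            rc_rows.append((sample, *r, alt_reads, depth))
            if r in present_set and alt_reads > 0:
                calls_rows.append((sample, *r))
    calls = pd.DataFrame(calls_rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])
    readcounts = pd.DataFrame(
        rc_rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "alt_reads", "total_reads"]
    )
    union = pd.DataFrame(
        shared + prim_priv + met_priv, columns=["chrom", "pos", "ref", "alt"]
    ).drop_duplicates()
    union["variant_class"] = "SNV"
    return {
        "calls": calls,
        "readcounts": readcounts,
        "union_variants": union,
        "reference": reference,
        "truth": {
            "n_shared": n_shared,
            "n_private_primary": n_private_primary,
            "n_private_met": n_private_met,
            "trunk_exposures": trunk.tolist(),
            "branch_exposures": branch.tolist(),
        },
    }
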