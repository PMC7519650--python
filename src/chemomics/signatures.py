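"""Mutational-signature refitting against the four bladder-cancer SBS signatures.

Per-sample 96-channel trinucleotide profiles are refit as non-negative
mixtures of SBS1 (clock-like deamination at NpCpG), SBS2 and SBS13 (APOBEC)
and SBS5 (flat, clock-like, NER/ERCC2-associated) by non-negative least
squares.  A fit is *eligible* when the sample carries more than 100 SNVs and
*assessable* when the cosine similarity between the reconstruction and the
observed profile exceeds 0.9; samples failing either gate stay unassigned.
Dominant-signature clusters group SBS2 and SBS13 into a single APOBEC
("SBS_APO") cluster.

The shipped signature matrix (``data/sbs_signatures_synthetic.tsv``) is a
stylized synthetic stand-in that reproduces the qualitative channel
structure of the four signatures, not the COSMIC release probabilities;
see :func:`build_synthetic_signature_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .channels import CHANNELS, SUBSTITUTIONS, BASES, channel_of

SIGNATURE_NAMES = ("SBS1", "SBS2", "SBS5", "SBS13")
APOBEC_SIGNATURES = ("SBS2", "SBS13")

#: gates used throughout: strictly more than 100 SNVs, cosine strictly above 0.9
MIN_SNVS = 100
MIN_COSINE = 0.9


def build_synthetic_signature_matrix() -> pd.DataFrame:
    """Construct the stylized synthetic stand-in for the four SBS signatures.

    Deterministic (no RNG).  Each column is a probability vector over the 96
    channels capturing the field-known shape of the signature:

    * SBS1  — C>T at NpCpG (spontaneous 5-methylcytosine deamination);
    * SBS2  — C>T at TpCpN, strongest at TpCpA/TpCpT (APOBEC);
    * SBS13 — C>G at TpCpN (APOBEC);
    * SBS5  — broad, featureless profile with mild class-level tilt.

    These are NOT the COSMIC v3 probabilities (synthetic stand-in).
    """
    mat = pd.DataFrame(0.0, index=list(CHANNELS), columns=list(SIGNATURE_NAMES))

    def put(sig: str, label: str, w: float) -> None:
        mat.loc[label, sig] = w

    # SBS1: four NpCpG C>T peaks plus a small flat background
    for five in BASES:
        put("SBS1", f"{five}[C>T]G", 0.17)
    # SBS2: TpC C>T peaks
    put("SBS2", "T[C>T]A", 0.25)
    put("SBS2", "T[C>T]C", 0.08)
    put("SBS2", "T[C>T]G", 0.05)
    put("SBS2", "T[C>T]T", 0.40)
    # SBS13: TpC C>G peaks
    put("SBS13", "T[C>G]A", 0.22)
    put("SBS13", "T[C>G]C", 0.08)
    put("SBS13", "T[C>G]G", 0.04)
    put("SBS13", "T[C>G]T", 0.42)
    # flat background for the peaked signatures
    for sig in ("SBS1", "SBS2", "SBS13"):
        remaining = 1.0 - mat[sig].sum()
        zero = mat[sig] == 0.0
        mat.loc[zero, sig] = remaining / zero.sum()

    # SBS5: broad profile; class-level weights with a gentle deterministic
    # ripple so the column is not exactly uniform within a class
    class_weight = {"C>A": 1.0, "C>G": 0.8, "C>T": 2.0, "T>A": 0.9, "T>C": 2.5, "T>G": 0.8}
    weights = []
    for sub in SUBSTITUTIONS:
        for i in range(16):
            weights.append(class_weight[sub] * (1.0 + 0.15 * np.sin(1.0 + 0.7 * i)))
    w = np.asarray(weights)
    mat["SBS5"] = w / w.sum()

    return mat


def load_signature_matrix(path=None) -> pd.DataFrame:
    """Load the 96 x 4 column-stochastic signature matrix.

    Reads the packaged synthetic stand-in TSV by default, or a user TSV with
    a ``channel`` column and one column per signature.  Validates channel
    order, non-negativity and column sums.
    """
    if path is None:
        ref = resources.files("chemomics").joinpath("data/sbs_signatures_synthetic.tsv")
        with resources.as_file(ref) as p:
            mat = pd.read_csv(p, sep="\t", comment="#", index_col="channel")
    else:
        mat = pd.read_csv(path, sep="\t", comment="#", index_col="channel")
    if list(mat.index) != list(CHANNELS):
        raise ValueError("signature matrix channels do not match the fixed 96-channel order")
    if (mat.values < 0).any():
        raise ValueError("signature matrix has negative entries")
    if not np.allclose(mat.sum(axis=0).values, 1.0, atol=1e-6):
        raise ValueError("signature matrix columns must each sum to 1")
    return mat


def open_reference(path):
    """Open a FASTA for indexed access during profile extraction.

    Returns a ``pyfaidx.Fasta`` (uppercased); any mapping of chromosome name
    to sequence works equally as the ``reference`` argument below.
    """
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def extract_trinucleotide_profile(sample_variants: pd.DataFrame, reference) -> np.ndarray:
    """Bin a sample's SNVs into the 96 trinucleotide channels.

    Parameters
    ----------
    sample_variants : DataFrame with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt`` and ``variant_class``; only rows with
        ``variant_class == "SNV"`` contribute.
    reference : a ``pyfaidx.Fasta`` (or mapping of chrom -> sequence string)
        used to look up the flanking bases and check the ref allele.

    Returns a length-96 integer count vector summing to the SNV count.
    Raises ``ValueError`` listing every record whose ref allele disagrees
    with the reference or whose position lacks both flanks.
    """
    profile = np.zeros(96, dtype=np.int64)
    errors: list[str] = []
    snvs = sample_variants[sample_variants["variant_class"] == "SNV"]
    for row in snvs.itertuples(index=False):
        chrom, pos, ref, alt = str(row.chrom), int(row.pos), str(row.ref), str(row.alt)
        seq = reference[chrom]
        if pos < 2 or pos > len(seq) - 1:
            errors.append(f"{chrom}:{pos} lacks trinucleotide context")
            continue
        tri = str(seq[pos - 2 : pos + 1]).upper()
        if tri[1] != ref:
            errors.append(f"{chrom}:{pos} ref allele {ref} != reference base {tri[1]}")
            continue
        profile[channel_of(tri[0], ref, alt, tri[2])] += 1
    if errors:
        raise ValueError("reference mismatches: " + "; ".join(errors))
    return profile


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class ExposureFit:
    """Non-negative signature exposures for one 96-channel profile."""

    exposures: pd.Series  # mutation counts attributed to each signature
    observed: np.ndarray
    reconstruction: np.ndarray
    cosine_similarity: float
    total_snvs: int
    eligible: bool  # total_snvs > 100
    assessable: bool  # eligible and cosine > 0.9

    @property
    def fractions(self) -> pd.Series:
        tot = self.exposures.sum()
        if tot == 0:
            return self.exposures * np.nan
        return self.exposures / tot


def fit_exposures(
    profile: np.ndarray,
    signature_matrix: pd.DataFrame | None = None,
    *,
    min_snvs: int = MIN_SNVS,
    min_cosine: float = MIN_COSINE,
) -> ExposureFit:
    """Refit a profile as a non-negative mixture of the fixed signatures.

    Solves ``min_w ||M w - p||_2`` with ``w >= 0`` (NNLS), reconstructs the
    profile, and gates the fit: eligible iff the sample has strictly more
    than ``min_snvs`` SNVs, assessable iff additionally the reconstruction's
    cosine similarity to the observed profile strictly exceeds ``min_cosine``.
    """
    if signature_matrix is None:
        signature_matrix = load_signature_matrix()
    p = np.asarray(profile, dtype=float)
    total = int(round(p.sum()))
    if total == 0:
        raise ValueError("cannot fit an all-zero profile")
    M = signature_matrix.values
    w, _ = nnls(M, p)
    recon = M @ w
    cos = _cosine(recon, p)
    eligible = total > min_snvs
    return ExposureFit(
        exposures=pd.Series(w, index=signature_matrix.columns),
        observed=p,
        reconstruction=recon,
        cosine_similarity=cos,
        total_snvs=total,
        eligible=eligible,
        assessable=bool(eligible and cos > min_cosine),
    )


def assign_signature_cluster(fit: ExposureFit) -> str:
    """Dominant-signature cluster: SBS1, SBS5, SBS_APO (= SBS2+SBS13), or unassigned.

    Samples that are not eligible (<= 100 SNVs) or not assessable
    (cosine <= 0.9) are unassigned.
    """
    if not (fit.eligible and fit.assessable):
        return "unassigned"
    grouped = {
        "SBS1": fit.exposures["SBS1"],
        "SBS5": fit.exposures["SBS5"],
        "SBS_APO": fit.exposures["SBS2"] + fit.exposures["SBS13"],
    }
    return max(grouped, key=grouped.get)


def context_mutation_count(
    fit: ExposureFit, signature: str, *, method: str = "proportional"
) -> float:
    """Number of the sample's mutations attributed to ``signature``.

    ``signature`` is one of SBS1, SBS2, SBS5, SBS13 or ``"SBS_APO"``
    (SBS2 + SBS13 summed).  Non-assessable fits return ``nan``.

    ``method="proportional"`` (default) attributes
    ``total_snvs * exposure_fraction``; ``method="posterior"`` splits each
    observed channel's count across signatures by the per-channel posterior
    ``exposure_s * M[c, s]`` and sums — a sensitivity-check mode.
    """
    if not fit.assessable:
        return float("nan")
    sigs = APOBEC_SIGNATURES if signature == "SBS_APO" else (signature,)
    for s in sigs:
        if s not in fit.exposures.index:
            raise KeyError(f"unknown signature {s!r}")
    if method == "proportional":
        tot = fit.exposures.sum()
        if tot == 0:
            return 0.0
        frac = sum(fit.exposures[s] for s in sigs) / tot
        return float(fit.total_snvs * frac)
    if method == "posterior":
        M = load_signature_matrix()[list(fit.exposures.index)].values
        w = fit.exposures.values
        per_channel = M * w  # 96 x 4 unnormalized per-channel posteriors
        denom = per_channel.sum(axis=1)
        denom[denom == 0] = np.inf
        post = per_channel / denom[:, None]
        idx = [list(fit.exposures.index).index(s) for s in sigs]
        return float((post[:, idx].sum(axis=1) * fit.observed).sum())
    raise ValueError(f"unknown method {method!r}")
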