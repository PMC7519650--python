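"""Primary-vs-metastasis comparison: read-count rescue, depth gating, and
trunk/branch classification.

A mutation called in one of a patient's samples may be genuinely present but
sub-threshold in another, so every called mutation is re-examined in every
sample's read counts ("rescue").  Detection is only trusted where the
sequencing depth would have allowed it: from the lowest VAF at which the
mutation was observed, the minimum depth needed to see at least one
alternate read with a chosen probability is computed, and positions that are
under-covered in any sample are dropped rather than scored absent.
Surviving mutations present in every sample are trunk; the rest are branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import signatures as sig

MUTATION_KEY = ["chrom", "pos", "ref", "alt"]


def min_required_depth(min_vaf: float, detect_prob: float = 0.95) -> int:
    """Smallest depth d with P(>= 1 alt read | Binomial(d, min_vaf)) >= detect_prob.

    Equivalently the smallest d with ``(1 - min_vaf)**d <= 1 - detect_prob``.
    """
    if not (0 < min_vaf <= 1):
        raise ValueError("min_vaf must be in (0, 1]")
    if not (0 < detect_prob < 1):
        raise ValueError("detect_prob must be in (0, 1)")
    if min_vaf == 1.0:
        return 1
    d = math.log(1.0 - detect_prob) / math.log(1.0 - min_vaf)
    d_int = math.ceil(d)
    # guard the exact-boundary case against float error
    while (1.0 - min_vaf) ** d_int > 1.0 - detect_prob + 1e-12:
        d_int += 1
    while d_int > 1 and (1.0 - min_vaf) ** (d_int - 1) <= 1.0 - detect_prob + 1e-12:
        d_int -= 1
    return d_int


@dataclass(frozen=True)
class MutationPresenceMatrix:
    """Presence of each union mutation across one patient's samples.

    ``presence`` is a boolean DataFrame (mutations x samples) covering only
    the mutations that survive the depth gate; ``compartment`` labels each
    surviving mutation trunk (present in every sample) or branch;
    ``dropped`` lists mutations excluded for insufficient depth.
    """

    presence: pd.DataFrame
    compartment: pd.Series
    dropped: pd.DataFrame


def rescue_and_classify(
    calls: pd.DataFrame,
    readcounts: pd.DataFrame,
    detect_prob: float = 0.95,
    min_alt_reads: int = 2,
) -> MutationPresenceMatrix:
    """Rescue sub-threshold mutations, gate by depth, classify trunk/branch.

    Parameters
    ----------
    calls : DataFrame of called mutations with columns ``sample_id`` plus
        ``chrom, pos, ref, alt`` — one patient's samples.
    readcounts : DataFrame with ``sample_id, chrom, pos, ref, alt,
        alt_reads, total_reads`` covering every union mutation in every
        sample (missing records are an error).
    min_alt_reads : alternate reads required to rescue a mutation in a
        sample where it was not called.

    A mutation is *present* in a sample if called there or if the sample
    shows at least ``min_alt_reads`` alternate reads.  The lowest VAF among
    samples where it is present sets the minimum required depth; mutations
    under-covered in any sample are dropped, not scored.
    """
    samples = sorted(set(calls["sample_id"]) | set(readcounts["sample_id"]))
    union = calls[MUTATION_KEY].drop_duplicates().reset_index(drop=True)
    keys = [tuple(r) for r in union.itertuples(index=False)]

    rc = readcounts.set_index(["sample_id", *MUTATION_KEY]).sort_index()
    called = set(map(tuple, calls[["sample_id", *MUTATION_KEY]].itertuples(index=False)))

    presence = pd.DataFrame(False, index=pd.MultiIndex.from_tuples(keys, names=MUTATION_KEY),
                            columns=samples)
    depth_ok = pd.Series(True, index=presence.index)
    min_vafs = pd.Series(np.nan, index=presence.index)

    for key in keys:
        vafs, totals = {}, {}
        for s in samples:
            try:
                rec = rc.loc[(s, *key)]
            except KeyError:
                raise ValueError(f"missing read-count record for {key} in sample {s}") from None
            alt = int(rec["alt_reads"]) if np.ndim(rec["alt_reads"]) == 0 else int(rec["alt_reads"].iloc[0])
            tot = int(rec["total_reads"]) if np.ndim(rec["total_reads"]) == 0 else int(rec["total_reads"].iloc[0])
            totals[s] = tot
            is_present = ((s, *key) in called) or (alt >= min_alt_reads)
            presence.loc[key, s] = is_present
            if is_present and tot > 0:
                vafs[s] = alt / tot
        observed = [v for v in vafs.values() if v > 0]
        if not observed:
            depth_ok.loc[key] = False
            continue
        lo = min(observed)
        min_vafs.loc[key] = lo
        required = min_required_depth(lo, detect_prob)
        if any(totals[s] < required for s in samples):
            depth_ok.loc[key] = False

    kept = presence[depth_ok.values]
    compartment = pd.Series(
        np.where(kept.all(axis=1), "trunk", "branch"), index=kept.index, name="compartment"
    )
    dropped = union[~depth_ok.values].reset_index(drop=True)
    return MutationPresenceMatrix(presence=kept, compartment=compartment, dropped=dropped)


def shared_private_summary(
    matrix: MutationPresenceMatrix, primary_sample: str, met_samples
) -> dict:
    """Shared/private counts and the primary-private fraction for one patient.

    ``shared`` = present in the primary and in at least one metastasis;
    ``primary_private`` = present in the primary only; ``met_private`` =
    present only in metastases.  The primary-private fraction is
    ``primary_private / (shared + primary_private)`` — the fraction of the
    primary tumor's mutations not carried over to metastatic lesions.
    """
    pres = matrix.presence
    met_samples = list(met_samples)
    in_primary = pres[primary_sample]
    in_any_met = pres[met_samples].any(axis=1)
    shared = int((in_primary & in_any_met).sum())
    primary_private = int((in_primary & ~in_any_met).sum())
    met_private = int((~in_primary & in_any_met).sum())
    denom = shared + primary_private
    return {
        "n_shared": shared,
        "n_primary_private": primary_private,
        "n_met_private": met_private,
        "primary_private_fraction": (primary_private / denom) if denom else float("nan"),
    }


def compartment_signatures(
    matrix: MutationPresenceMatrix,
    union_variants: pd.DataFrame,
    reference,
    signature_matrix: pd.DataFrame | None = None,
) -> dict:
    """Refit signature exposures separately on trunk and branch mutations.

    ``union_variants`` carries one row per union mutation with ``chrom, pos,
    ref, alt, variant_class``.  Empty compartments yield ``None`` (an
    explicit missing value).  Returns ``{"trunk": ExposureFit | None,
    "branch": ExposureFit | None}``; relative contributions are the fits'
    ``fractions``.
    """
    uv = union_variants.set_index(MUTATION_KEY)
    out = {}
    for comp in ("trunk", "branch"):
        keys = matrix.compartment.index[matrix.compartment == comp]
        if len(keys) == 0:
            out[comp] = None
            continue
        subset = uv.loc[list(keys)].reset_index()
        profile = sig.extract_trinucleotide_profile(subset, reference)
        out[comp] = sig.fit_exposures(profile, signature_matrix) if profile.sum() else None
    return out
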