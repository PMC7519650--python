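"""The 96 single-base-substitution channels in trinucleotide context.

Channel order is fixed across the whole package: the six pyrimidine-strand
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), and within each class
the 5' flanking base then the 3' flanking base in alphabetical order
(A, C, G, T).  Labels follow the common ``5'[ref>alt]3'`` convention,
e.g. ``T[C>A]G``.

Substitutions observed with a purine reference base are folded to the
pyrimidine strand by reverse complementation: the ref and alt bases are
complemented and the flanks are complemented and swapped.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def fold_to_pyrimidine(five: str, ref: str, alt: str, three: str) -> tuple[str, str, str, str]:
    """Map a substitution with its flanks onto the pyrimidine strand.

    Returns ``(five, ref, alt, three)`` unchanged when ``ref`` is already a
    pyrimidine; otherwise the reverse complement.  Folding is idempotent.
    """
    if ref in PYRIMIDINES:
        return five, ref, alt, three
    return COMPLEMENT[three], COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[five]


def channel_of(five: str, ref: str, alt: str, three: str) -> int:
    """Index of the 96-channel bin for one SNV and its trinucleotide context."""
    five, ref, alt, three = fold_to_pyrimidine(five, ref, alt, three)
    label = f"{five}[{ref}>{alt}]{three}"
    try:
        return CHANNEL_INDEX[label]
    except KeyError:  # e.g. ref == alt, or non-ACGT base
        raise ValueError(f"not a valid SNV channel: {label}") from None


def channel_parts(index: int) -> tuple[str, str, str, str]:
    """Inverse of :func:`channel_of` for pyrimidine-strand channels."""
    label = CHANNELS[index]
    return label[0], label[2], label[4], label[6]
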