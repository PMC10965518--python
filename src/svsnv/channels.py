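"""Canonical 96-channel single-base-substitution (SBS) channel definitions.

A channel is a pyrimidine-normalized substitution in trinucleotide context:
the mutated base (C or T after strand collapsing) with one flanking base on
each side.  Channels are ordered COSMIC-style: the six substitution classes
C>A, C>G, C>T, T>A, T>C, T>G, each expanded over the 16 (5', 3') flank
combinations in alphabetical order, giving labels like ``A[C>A]A``.
"""

from __future__ import annotations

import re

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Channel keys in canonical order: (substitution, 5' base, 3' base).
CHANNELS: tuple[tuple[str, str, str], ...] = tuple(
    (sub, five, three) for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

#: Canonical labels, e.g. "A[C>A]A", in the same order as CHANNELS.
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub, five, three in CHANNELS
)

CHANNEL_INDEX: dict[tuple[str, str, str], int] = {c: i for i, c in enumerate(CHANNELS)}
LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

_LABEL_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")

#: Indices of T-centered (A-T base pair) and C-centered (G-C base pair) channels.
AT_CHANNEL_INDICES: tuple[int, ...] = tuple(
    i for i, (sub, _, _) in enumerate(CHANNELS) if sub[0] == "T"
)
GC_CHANNEL_INDICES: tuple[int, ...] = tuple(
    i for i, (sub, _, _) in enumerate(CHANNELS) if sub[0] == "C"
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N allowed)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def parse_channel_label(label: str) -> tuple[str, str, str]:
    """Parse ``A[C>A]G``-style text into a (substitution, 5', 3') key."""
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"unrecognized channel label: {label!r}")
    five, ref, alt, three = m.groups()
    if ref == alt:
        raise ValueError(f"reference equals alternate in channel label: {label!r}")
    return (f"{ref}>{alt}", five, three)


def channel_from_context(ref: str, alt: str, five: str, three: str):
    """Map a substitution plus flanks to its pyrimidine-normalized channel key.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand.  Returns ``None`` when the context contains a base
    outside {A, C, G, T} (unclassifiable).
    """
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    if any(b not in BASES for b in (ref, alt, five, three)):
        return None
    if ref == alt:
        raise ValueError("reference and alternate base are identical")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    return (f"{ref}>{alt}", five, three)
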