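"""96-channel trinucleotide mutation spectra and A-T vs G-C channel comparisons.

Each single-base substitution is classified in the context of the flanking
1 bp on each side and collapsed onto the pyrimidine strand, giving the
standard 96 channels.  The module also implements the extreme-channel
comparison: within the A-T (T-centered) or G-C (C-centered) channel class,
rank channels, take the top-k and bottom-k, and compare per-sample subset
sums between two conditions with a two-tailed Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .channels import (AT_CHANNEL_INDICES, CHANNEL_INDEX,
                       CHANNEL_LABELS, GC_CHANNEL_INDICES,
                       channel_from_context)
from .variant_io import SnvRecord


@dataclass
class MutationSpectrum:
    """96-channel non-negative count vector plus an unclassifiable tally."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    unclassifiable: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any() or self.unclassifiable < 0:
            raise ValueError("negative count in spectrum")

    @property
    def total_classified(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "MutationSpectrum") -> "MutationSpectrum":
        return MutationSpectrum(self.counts + other.counts,
                                self.unclassifiable + other.unclassifiable)

    def as_dict(self) -> dict[str, int]:
        return {lab: int(c) for lab, c in zip(CHANNEL_LABELS, self.counts)}


@dataclass
class ChannelComparison:
    """Welch's t-test on per-sample summed counts over one channel subset."""

    subset_id: str
    channels: tuple[str, ...]
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    t_statistic: float | None
    p_value: float | None


def _fetch_context(sequence, chrom: str, pos: int) -> str | None:
    """1-based trinucleotide centered at pos, or None at chromosome edges."""
    seq = sequence[chrom]
    if pos < 2:
        return None
    if hasattr(seq, "__getitem__") and not isinstance(seq, str):
        # pyfaidx FastaRecord: 0-based slicing, len() available
        if pos + 1 > len(seq):
            return None
        return str(seq[pos - 2: pos + 1]).upper()
    if pos + 1 > len(seq):
        return None
    return seq[pos - 2: pos + 1].upper()


def classify_snv(snv: SnvRecord, sequence) -> tuple[str, str, str] | None:
    """Classify one SNV into its pyrimidine-normalized channel.

    ``sequence`` maps chromosome name to sequence (a plain string or a
    pyfaidx record).  Returns ``None`` (unclassifiable) when a flank falls
    outside the chromosome or the context contains N, and raises if the
    recorded reference base disagrees with the sequence.
    """
    ctx = _fetch_context(sequence, snv.chrom, snv.pos)
    if ctx is None or len(ctx) != 3:
        return None
    if ctx[1] != snv.ref:
        raise ValueError(
            f"reference mismatch at {snv.chrom}:{snv.pos}: "
            f"sequence has {ctx[1]}, record says {snv.ref}")
    return channel_from_context(snv.ref, snv.alt, ctx[0], ctx[2])


def build_spectrum(snvs: Iterable[SnvRecord], sequence) -> MutationSpectrum:
    """Tally SNVs into a 96-channel spectrum; order-independent."""
    counts = np.zeros(96, dtype=np.int64)
    unclassifiable = 0
    for snv in snvs:
        key = classify_snv(snv, sequence)
        if key is None:
            unclassifiable += 1
        else:
            counts[CHANNEL_INDEX[key]] += 1
    return MutationSpectrum(counts, unclassifiable)


def spectrum_from_channels(channel_indices: Iterable[int]) -> MutationSpectrum:
    """Build a spectrum directly from channel indices (no sequence needed)."""
    counts = np.bincount(np.fromiter(channel_indices, dtype=np.int64, count=-1),
                         minlength=96)
    if counts.shape[0] > 96:
        raise ValueError("channel index out of range")
    return MutationSpectrum(counts.astype(np.int64))


def split_by_basepair(spec: MutationSpectrum) -> dict[str, int]:
    """Total counts in A-T (T-centered) vs G-C (C-centered) base-pair classes."""
    at = int(spec.counts[list(AT_CHANNEL_INDICES)].sum())
    gc = int(spec.counts[list(GC_CHANNEL_INDICES)].sum())
    return {"AT_count": at, "GC_count": gc}


def compare_extreme_channels(
    spectra_by_sample: Mapping[str, MutationSpectrum],
    condition_of: Mapping[str, str],
    condition_a: str,
    condition_b: str,
    k: int = 10,
    basepair_class: str = "AT",
    rank_by: str = "pooled",
) -> tuple[ChannelComparison, ChannelComparison]:
    """Compare top-k and bottom-k channels of one base-pair class between conditions.

    Channels within the class are ranked by their mean per-sample count
    pooled over both conditions by default; ``rank_by="condition_b"`` ranks
    on the induced condition alone.  Pooled ranking is the default because
    ranking on one condition and then testing that same condition's counts
    biases the extreme subsets (the bottom channels are selected partly for
    their downward noise in that condition, inflating the false-positive
    rate of the subset test); pooled ranking spreads the selection noise
    symmetrically.  For each subset the per-sample summed counts are
    compared between conditions with a two-tailed Welch's t-test.  With fewer
    than two samples in either condition the test fields are ``None``.

    Returns ``(top_comparison, bottom_comparison)``.
    """
    if basepair_class == "AT":
        idx = np.array(AT_CHANNEL_INDICES)
    elif basepair_class == "GC":
        idx = np.array(GC_CHANNEL_INDICES)
    else:
        raise ValueError("basepair_class must be 'AT' or 'GC'")
    if not 1 <= k <= len(idx):
        raise ValueError(f"k must be in [1, {len(idx)}]")

    samples_a = [s for s in spectra_by_sample if condition_of[s] == condition_a]
    samples_b = [s for s in spectra_by_sample if condition_of[s] == condition_b]
    if not samples_a or not samples_b:
        raise ValueError("both conditions need at least one sample")

    def class_matrix(samples: Sequence[str]) -> np.ndarray:
        return np.array([spectra_by_sample[s].counts[idx] for s in samples], dtype=float)

    mat_a, mat_b = class_matrix(samples_a), class_matrix(samples_b)
    rank_scores = (mat_b.mean(axis=0) if rank_by == "condition_b"
                   else np.vstack([mat_a, mat_b]).mean(axis=0))
    order = np.argsort(rank_scores, kind="stable")

    def make(subset_order: np.ndarray, subset_id: str) -> ChannelComparison:
        sub = idx[subset_order]
        labels = tuple(CHANNEL_LABELS[i] for i in sub)
        sums_a = {s: int(spectra_by_sample[s].counts[sub].sum()) for s in samples_a}
        sums_b = {s: int(spectra_by_sample[s].counts[sub].sum()) for s in samples_b}
        t = p = None
        if len(samples_a) >= 2 and len(samples_b) >= 2:
            va = np.array(list(sums_a.values()), dtype=float)
            vb = np.array(list(sums_b.values()), dtype=float)
            if np.allclose(va, va[0]) and np.allclose(vb, vb[0]) and va[0] == vb[0]:
                t, p = 0.0, 1.0  # identical constant groups: no difference
            else:
                res = stats.ttest_ind(vb, va, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
        return ChannelComparison(subset_id, labels, sums_a, sums_b, t, p)

    top = make(order[-k:], f"{basepair_class} highest {k}")
    bottom = make(order[:k], f"{basepair_class} lowest {k}")
    return top, bottom
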