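"""Proximity stratification of SNVs around SV breakpoints and the
expected-random SNV count model.

An "SV site" is a breakpoint locus.  SNVs within distance ``d`` of any
breakend (membership in the merged union of per-breakend windows
``[pos - d, pos + d]``, clipped at chromosome ends) form the near stratum;
all others are far.  The expected number of SNVs falling near SV sites under
uniform random placement is modeled two ways:

* naive:      ``n_snv / G * n_sv * 2 * R``  — the per-site two-flank formula,
  which ignores neighborhood overlap and chromosome-end clipping and can
  exceed ``n_snv``;
* corrected:  ``n_snv * merged_length / G`` — the exact uniform-placement
  expectation over the merged neighborhoods.

The two agree exactly when no neighborhoods overlap and none is clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeDef
from .variant_io import SnvRecord, SvBreakend

DEFAULT_PROXIMITY_BP = 1_000_000
#: Default range grid: log-spaced 1 kb .. 10 Mb.
DEFAULT_RANGES: tuple[int, ...] = tuple(
    int(r) for r in np.unique(np.round(np.logspace(3, 7, 13)).astype(np.int64))
)


@dataclass
class IntervalSet:
    """Per-chromosome sorted, merged 1-based inclusive intervals."""

    by_chrom: dict[str, np.ndarray]  # (n, 2) arrays of [start, end]

    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0] + 1).sum()
                       for iv in self.by_chrom.values() if len(iv)))

    def contains(self, chrom: str, pos: int | np.ndarray):
        """Membership test; vectorized over positions."""
        iv = self.by_chrom.get(chrom)
        pos = np.asarray(pos)
        if iv is None or len(iv) == 0:
            return np.zeros(pos.shape, dtype=bool) if pos.ndim else False
        j = np.searchsorted(iv[:, 0], pos, side="right") - 1
        inside = (j >= 0) & (pos <= iv[np.clip(j, 0, len(iv) - 1), 1])
        return inside if pos.ndim else bool(inside)

    def to_bed(self, path) -> None:
        """Write as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom in sorted(self.by_chrom):
                for start, end in self.by_chrom[chrom]:
                    fh.write(f"{chrom}\t{start - 1}\t{end}\n")


@dataclass
class ProximityPartition:
    distance_bp: int
    near: list[SnvRecord]
    far: list[SnvRecord]
    neighborhoods: IntervalSet


@dataclass
class ExpectedRandomCurve:
    """Observed vs expected near-SNV counts over a grid of ranges R."""

    ranges_bp: tuple[int, ...]
    observed: np.ndarray
    expected_naive: np.ndarray
    expected_corrected: np.ndarray
    n_snv: int
    n_sv: int
    sv_unit: str = "breakends"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "range_bp": list(self.ranges_bp),
            "observed": self.observed,
            "expected_naive": self.expected_naive,
            "expected_corrected": self.expected_corrected,
        })


def merge_neighborhoods(breakends: Iterable[SvBreakend], d: int,
                        genome: GenomeDef) -> IntervalSet:
    """Union of per-breakend windows [pos-d, pos+d], clipped and merged.

    Overlapping or bookended (adjacent) windows are merged per chromosome.
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    raw: dict[str, list[tuple[int, int]]] = {}
    for b in breakends:
        genome.validate_position(b.chrom, b.pos)
        lo = max(1, b.pos - d)
        hi = min(genome.lengths[b.chrom], b.pos + d)
        raw.setdefault(b.chrom, []).append((lo, hi))
    merged: dict[str, np.ndarray] = {}
    for chrom, spans in raw.items():
        spans.sort()
        out: list[list[int]] = []
        for lo, hi in spans:
            if out and lo <= out[-1][1] + 1:  # overlap or adjacency
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi])
        merged[chrom] = np.array(out, dtype=np.int64)
    return IntervalSet(merged)


def partition_snvs(snvs: Sequence[SnvRecord], breakends: Iterable[SvBreakend],
                   d: int = DEFAULT_PROXIMITY_BP,
                   genome: GenomeDef | None = None) -> ProximityPartition:
    """Split SNVs into near/far strata by merged breakend neighborhoods."""
    if genome is None:
        raise ValueError("a GenomeDef is required to clip neighborhoods")
    neighborhoods = merge_neighborhoods(breakends, d, genome)
    near: list[SnvRecord] = []
    far: list[SnvRecord] = []
    for snv in snvs:
        genome.validate_position(snv.chrom, snv.pos)
        (near if neighborhoods.contains(snv.chrom, snv.pos) else far).append(snv)
    return ProximityPartition(d, near, far, neighborhoods)


def expected_random_count(n_snv: int, genome_length: int, n_sv: int,
                          range_R: int) -> float:
    """Naive expected near-SNV count: ``n_snv / G * n_sv * 2 * R``.

    The two-flank formula as printed; uncapped, so it can exceed ``n_snv``
    when neighborhoods overlap.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if min(n_snv, n_sv, range_R) < 0:
        raise ValueError("counts and range must be non-negative")
    return n_snv / genome_length * n_sv * 2 * range_R


def observed_vs_expected_curve(
    snvs: Sequence[SnvRecord],
    breakends: Sequence[SvBreakend],
    genome: GenomeDef,
    ranges: Sequence[int] = DEFAULT_RANGES,
    sv_unit: str = "breakends",
) -> ExpectedRandomCurve:
    """Observed, naive-expected and overlap-corrected near counts per range R.

    ``sv_unit`` selects whether the SV count in the naive formula counts
    breakends (default) or distinct events.
    """
    ranges = [int(r) for r in ranges]
    if any(b > a for a, b in zip(ranges[1:], ranges)):
        raise ValueError("ranges must be sorted ascending")
    if sv_unit == "breakends":
        n_sv = len(breakends)
    elif sv_unit == "events":
        n_sv = len({(b.sample, b.event_id) for b in breakends})
    else:
        raise ValueError("sv_unit must be 'breakends' or 'events'")
    n_snv = len(snvs)
    G = genome.total_length
    observed = np.zeros(len(ranges), dtype=np.int64)
    naive = np.zeros(len(ranges))
    corrected = np.zeros(len(ranges))
    for i, R in enumerate(ranges):
        part = partition_snvs(snvs, breakends, d=R, genome=genome)
        observed[i] = len(part.near)
        naive[i] = expected_random_count(n_snv, G, n_sv, R)
        corrected[i] = n_snv * part.neighborhoods.total_length() / G
    return ExpectedRandomCurve(tuple(ranges), observed, naive, corrected,
                               n_snv=n_snv, n_sv=n_sv, sv_unit=sv_unit)
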