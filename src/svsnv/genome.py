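"""Genome definition: ordered chromosomes, lengths, optional copy numbers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names and lengths defining the analyzed genome.

    Parameters
    ----------
    names
        Chromosome names in their reporting order; must be unique.
    lengths
        Mapping from chromosome name to length in bp (all > 0).
    copy_numbers
        Optional per-chromosome copy count (integer >= 1), used to normalize
        SV totals by chromosome number; ``None`` disables that normalization.
    """

    names: tuple[str, ...]
    lengths: Mapping[str, int]
    copy_numbers: Mapping[str, int] | None = field(default=None)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        missing = [n for n in self.names if n not in self.lengths]
        if missing:
            raise ValueError(f"chromosomes without length: {missing}")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise ValueError(f"non-positive length for {name}")
        if self.copy_numbers is not None:
            for name in self.names:
                cn = self.copy_numbers.get(name)
                if cn is None or int(cn) < 1:
                    raise ValueError(f"invalid copy number for {name}")

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int] | Sequence[tuple[str, int]],
                     copy_numbers: Mapping[str, int] | None = None) -> "GenomeDef":
        items = list(lengths.items()) if isinstance(lengths, Mapping) else list(lengths)
        return cls(tuple(n for n, _ in items), {n: int(l) for n, l in items},
                   copy_numbers)

    @property
    def total_length(self) -> int:
        """Total genome length G in bp."""
        return sum(self.lengths[n] for n in self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def validate_position(self, chrom: str, pos: int) -> None:
        if chrom not in self.lengths:
            raise ValueError(f"chromosome {chrom!r} not in genome definition")
        if not (1 <= pos <= self.lengths[chrom]):
            raise ValueError(
                f"position {chrom}:{pos} outside [1, {self.lengths[chrom]}]")
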