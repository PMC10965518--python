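"""Read/write the standard formats the pipeline touches.

SNVs arrive as VCF 4.x (read through cyvcf2), SV breakends as BEDPE or BED,
the genome as a FASTA (+.fai) or a two-column chrom-sizes table, and
reference SBS signatures as a tab-delimited 96 x K probability matrix in the
COSMIC text layout.  Internal coordinates are 1-based inclusive (the VCF
convention); BED/BEDPE 0-based half-open coordinates are converted at the
boundary.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .channels import BASES, CHANNEL_LABELS, parse_channel_label, CHANNEL_INDEX
from .genome import GenomeDef

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "OTHER")


@dataclass(frozen=True)
class SnvRecord:
    """One somatic single-base substitution (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str = "sample"
    condition: str = "condition"

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT allele in {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class SvBreakend:
    """One SV breakpoint position ("SV site"); two breakends may share an event id."""

    chrom: str
    pos: int
    svtype: str = "OTHER"
    event_id: str = ""
    sample: str = "sample"
    condition: str = "condition"

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.chrom}:{self.pos}")


class SignatureMatrix:
    """96 x K reference signature matrix (channels x named signatures).

    Rows follow the canonical channel order; every column is a probability
    vector (non-negative, summing to 1 within 1e-6 after normalization-check
    at 1e-3 on input).
    """

    def __init__(self, data: pd.DataFrame):
        if list(data.index) != list(CHANNEL_LABELS):
            data = data.reindex(list(CHANNEL_LABELS))
            if data.isna().any().any():
                raise ValueError("signature matrix does not cover all 96 channels")
        values = data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("negative entry in signature matrix")
        sums = values.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = [c for c, s in zip(data.columns, sums) if abs(s - 1.0) > 1e-3]
            raise ValueError(f"signature columns do not sum to 1: {bad}")
        self.data = data / sums  # exact renormalization within declared tolerance

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def __len__(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# genome definitions


def read_chrom_sizes(path) -> GenomeDef:
    """Read a two-column (name, length) chrom-sizes table (also accepts .fai)."""
    names, lengths = [], {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected name and length")
            name, length = parts[0], int(parts[1])
            if name in lengths:
                raise ValueError(f"{path}:{i}: duplicate chromosome {name}")
            names.append(name)
            lengths[name] = length
    return GenomeDef(tuple(names), lengths)


def genome_from_fasta(path) -> tuple[GenomeDef, "pyfaidx.Fasta"]:
    """Index a FASTA and derive a GenomeDef from its sequence lengths."""
    import pyfaidx

    fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)
    lengths = {name: len(fasta[name]) for name in fasta.keys()}
    return GenomeDef(tuple(fasta.keys()), lengths), fasta


# ---------------------------------------------------------------------------
# SNVs


def read_snv_vcf(path, sample: str = "sample", condition: str = "condition",
                 genome: GenomeDef | None = None, pass_only: bool = False,
                 ) -> tuple[list[SnvRecord], dict[str, int]]:
    """Read biallelic single-base substitutions from a VCF.

    Multi-allelic records are split into one record per single-base alternate
    allele; indels and symbolic alleles are skipped and tallied in the skip
    report.  The FILTER column is ignored unless ``pass_only`` is set.

    Returns
    -------
    (records, skip_report)
        ``skip_report`` counts skipped records by reason
        (``indel``, ``symbolic``, ``filtered``).
    """
    from cyvcf2 import VCF

    records: list[SnvRecord] = []
    skipped: collections.Counter = collections.Counter()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    for var in vcf:
        if pass_only and var.FILTER is not None:  # None means PASS/'.' in cyvcf2
            skipped["filtered"] += 1
            continue
        ref = var.REF.upper()
        alts = [a.upper() for a in (var.ALT or [])]
        if len(ref) != 1 or ref not in BASES:
            skipped["indel"] += 1
            continue
        emitted = False
        for alt in alts:
            if alt.startswith("<") or alt in (".", "*") or "[" in alt or "]" in alt:
                if not emitted:
                    skipped["symbolic"] += 1
                emitted = True
                continue
            if len(alt) != 1 or alt not in BASES:
                if not emitted:
                    skipped["indel"] += 1
                emitted = True
                continue
            if genome is not None:
                genome.validate_position(var.CHROM, var.POS)
            records.append(SnvRecord(var.CHROM, var.POS, ref, alt,
                                     sample=sample, condition=condition))
            emitted = True
        if not alts:
            skipped["indel"] += 1
    return records, dict(skipped)


def write_snv_vcf(records: Iterable[SnvRecord], path, genome: GenomeDef | None = None) -> None:
    """Write SNV records as a minimal sorted VCF 4.2 file."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if genome is not None:
            for name in genome.names:
                fh.write(f"##contig=<ID={name},length={genome.lengths[name]}>\n")
        else:
            for name in sorted({r.chrom for r in records}):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# SV breakends


def read_sv_breakends(path, dialect: str = "bedpe", sample: str = "sample",
                      condition: str = "condition",
                      genome: GenomeDef | None = None) -> list[SvBreakend]:
    """Read SV breakends from a BEDPE (two breakends/row) or BED (one/row) file.

    BED/BEDPE intervals are 0-based half-open on disk; each breakend position
    is taken as the interval end converted to 1-based (i.e. ``end`` column,
    which equals start+1 for point intervals).
    """
    if dialect not in ("bedpe", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[SvBreakend] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if dialect == "bedpe":
                if len(f) < 6:
                    raise ValueError(f"{path}:{i}: BEDPE needs >=6 columns")
                name = f[6] if len(f) > 6 and f[6] != "." else f"sv{i}"
                svtype = _normalize_svtype(f[10]) if len(f) > 10 else "OTHER"
                for chrom, start, end in ((f[0], f[1], f[2]), (f[3], f[4], f[5])):
                    pos = _bed_point(start, end, path, i)
                    if genome is not None:
                        genome.validate_position(chrom, pos)
                    out.append(SvBreakend(chrom, pos, svtype, event_id=name,
                                          sample=sample, condition=condition))
            else:
                if len(f) < 3:
                    raise ValueError(f"{path}:{i}: BED needs >=3 columns")
                name = f[3] if len(f) > 3 and f[3] != "." else f"sv{i}"
                pos = _bed_point(f[1], f[2], path, i)
                if genome is not None:
                    genome.validate_position(f[0], pos)
                out.append(SvBreakend(f[0], pos, "OTHER", event_id=name,
                                      sample=sample, condition=condition))
    return out


def _bed_point(start: str, end: str, path, lineno: int) -> int:
    s, e = int(start), int(end)
    if s < 0 or e <= s:
        raise ValueError(f"{path}:{lineno}: invalid interval [{s}, {e})")
    return e  # 0-based half-open end == 1-based position of last base


def _normalize_svtype(text: str) -> str:
    t = text.strip().upper()
    aliases = {"BND": "TRA", "CTX": "TRA", "ITX": "TRA", "INS": "OTHER"}
    t = aliases.get(t, t)
    return t if t in SV_TYPES else "OTHER"


def write_sv_bedpe(breakends: Iterable[SvBreakend], path) -> None:
    """Write breakends as BEDPE, pairing the two breakends of each event id."""
    by_event: dict[tuple[str, str], list[SvBreakend]] = collections.defaultdict(list)
    for b in breakends:
        by_event[(b.sample, b.event_id)].append(b)
    with open(path, "w") as fh:
        for (sample, event_id), bes in sorted(by_event.items()):
            if len(bes) > 2:
                raise ValueError(f"event {event_id!r} has {len(bes)} breakends")
            a = bes[0]
            b = bes[1] if len(bes) == 2 else bes[0]
            fh.write("\t".join(map(str, [
                a.chrom, a.pos - 1, a.pos, b.chrom, b.pos - 1, b.pos,
                event_id, ".", "+", "+", a.svtype])) + "\n")


# ---------------------------------------------------------------------------
# signature matrices and 96-channel catalogs


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a COSMIC-layout tab-delimited 96 x K signature probability file.

    The first column holds channel labels (``A[C>A]A`` style); row order is
    arbitrary on disk and is canonicalized on read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"expected 96 channel rows, found {df.shape[0]}")
    canonical = [CHANNEL_LABELS[CHANNEL_INDEX[parse_channel_label(lab)]]
                 for lab in df.index]
    if len(set(canonical)) != 96:
        raise ValueError("duplicate channels in signature matrix")
    df.index = canonical
    return SignatureMatrix(df.reindex(list(CHANNEL_LABELS)))


def write_signature_matrix(sig: SignatureMatrix, path) -> None:
    sig.data.rename_axis("Type").to_csv(path, sep="\t")


def write_catalog(catalog: Mapping[str, np.ndarray] | pd.DataFrame, path) -> None:
    """Write per-sample 96-channel count vectors as a tab-delimited catalog."""
    df = pd.DataFrame(dict(catalog)) if not isinstance(catalog, pd.DataFrame) else catalog
    df.index = list(CHANNEL_LABELS)
    df.rename_axis("Type").to_csv(path, sep="\t")


def read_catalog(path) -> pd.DataFrame:
    """Read a 96-channel tab-delimited catalog (channels x samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"expected 96 channel rows, found {df.shape[0]}")
    canonical = [CHANNEL_LABELS[CHANNEL_INDEX[parse_channel_label(lab)]]
                 for lab in df.index]
    df.index = canonical
    return df.reindex(list(CHANNEL_LABELS))
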