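"""Synthetic paired SV/SNV call sets with exported ground truth.

The generator emulates the statistical structure the analysis assumes:

* SV breakpoints drawn from a mixture of a uniform genome-wide component and
  shared hotspot intervals, identical across two conditions (only the random
  stream differs);
* an SV-proximal SNV component: per breakend, a Poisson(``k``) number of SNVs
  placed uniformly within ``c`` bp of the breakend;
* an SV-independent uniform background whose per-Mb rate ``b`` differs
  between conditions;
* per-stratum 96-channel signature mixtures, realized against the local
  sequence context by rejection sampling (so purine-strand placements are
  reverse-complemented correctly).

Every output is reproducible from a single integer seed, and the
ground-truth parameters round-trip through JSON so parameter-recovery tests
can compare pipeline estimates against what was simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import (AT_CHANNEL_INDICES, CHANNELS, CHANNEL_LABELS,
                       COMPLEMENT, GC_CHANNEL_INDICES)
from .genome import GenomeDef
from .variant_io import SignatureMatrix, SnvRecord, SvBreakend, SV_TYPES

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Per-channel realization table: (pyrimidine-strand trinucleotide, its
#: reverse complement, forward (ref, alt), reverse-strand (ref, alt)).
_CHANNEL_REALIZATION: list[tuple[str, str, tuple[str, str], tuple[str, str]]] = []
for _sub, _five, _three in CHANNELS:
    _target = _five + _sub[0] + _three
    _rc = "".join(COMPLEMENT[b] for b in reversed(_target))
    _CHANNEL_REALIZATION.append(
        (_target, _rc, (_sub[0], _sub[2]),
         (COMPLEMENT[_sub[0]], COMPLEMENT[_sub[2]])))

# Default study conditions: two MEF-like conditions sharing SV hotspots, the
# second with a 2.8-fold elevated SV-independent background enriched in
# T-centered channels.
DEFAULT_CONDITIONS = ("unirradiated", "irradiated")
DEFAULT_CHROM_LENGTHS = {f"chr{i}": 30_000_000 for i in range(1, 6)}
DEFAULT_N_SV = 100          # events per condition (two breakends each)
DEFAULT_BACKGROUND_PER_MB = {"unirradiated": 2.0, "irradiated": 5.6}
DEFAULT_CLUSTER_MEAN = 30.0  # SNVs per breakend
DEFAULT_CLUSTER_WIDTH = 500_000
DEFAULT_HOTSPOT_WEIGHT = 0.5


@dataclass
class SimulationTruth:
    """Ground-truth parameters of one simulated two-condition dataset."""

    seed: int
    chrom_lengths: dict[str, int]
    condition_labels: tuple[str, str]
    n_sv: dict[str, int]                      # events per condition
    hotspots: list[tuple[str, int, int]]      # shared 1-based inclusive intervals
    hotspot_weight: float
    cluster_mean: float                       # k: SNVs per breakend
    cluster_width_bp: int                     # c
    background_per_mb: dict[str, float]       # b per condition
    near_mixture: dict[str, float] | None = None         # signature -> proportion
    background_mixtures: dict[str, dict[str, float]] | None = None  # per condition
    realized: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cluster_mean < 0 or self.cluster_width_bp <= 0:
            raise ValueError("cluster mean must be >= 0 and width > 0")
        if any(v < 0 for v in self.background_per_mb.values()):
            raise ValueError("background rates must be >= 0")
        for mix in self._mixtures():
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"signature mixture sums to {s}, not 1")

    def _mixtures(self):
        if self.near_mixture:
            yield self.near_mixture
        for mix in (self.background_mixtures or {}).values():
            yield mix

    @property
    def genome(self) -> GenomeDef:
        return GenomeDef.from_lengths(self.chrom_lengths)


def default_truth(seed: int = 0, **overrides) -> SimulationTruth:
    """The default simulated study conditions (see module docstring)."""
    params = dict(
        seed=seed,
        chrom_lengths=dict(DEFAULT_CHROM_LENGTHS),
        condition_labels=DEFAULT_CONDITIONS,
        n_sv={c: DEFAULT_N_SV for c in DEFAULT_CONDITIONS},
        hotspots=[("chr1", 5_000_001, 7_000_000),
                  ("chr2", 12_000_001, 14_000_000),
                  ("chr3", 20_000_001, 22_000_000),
                  ("chr4", 1_000_001, 3_000_000)],
        hotspot_weight=DEFAULT_HOTSPOT_WEIGHT,
        cluster_mean=DEFAULT_CLUSTER_MEAN,
        cluster_width_bp=DEFAULT_CLUSTER_WIDTH,
        background_per_mb=dict(DEFAULT_BACKGROUND_PER_MB),
        near_mixture={"synNEAR": 1.0},
        background_mixtures={"unirradiated": {"synGC": 0.7, "synAT": 0.3},
                             "irradiated": {"synGC": 0.3, "synAT": 0.7}},
    )
    params.update(overrides)
    return SimulationTruth(**params)


# ---------------------------------------------------------------------------
# genome and reference-signature simulation


def simulate_genome(lengths: Mapping[str, int], seed: int,
                    ) -> tuple[GenomeDef, dict[str, str]]:
    """I.i.d. uniform A/C/G/T sequence per chromosome, reproducible by seed."""
    genome = GenomeDef.from_lengths(dict(lengths))
    rng = np.random.default_rng(seed)
    sequences = {}
    for chrom in genome.names:
        idx = rng.integers(0, 4, size=genome.lengths[chrom], dtype=np.uint8)
        sequences[chrom] = _BASE_LUT[idx].tobytes().decode("ascii")
    return genome, sequences


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def synthetic_signature_matrix(seed: int = 0, n_random: int = 1,
                               include_basepair: bool = True,
                               alpha: float = 0.25) -> SignatureMatrix:
    """Generate a synthetic reference signature matrix.

    ``include_basepair`` adds two disjoint-support columns, ``synGC``
    (uniform over the 48 C-centered channels) and ``synAT`` (uniform over
    the 48 T-centered channels); ``n_random`` adds peaked Dirichlet(alpha)
    columns named ``synNEAR``, ``syn2``, ``syn3``, ...  All columns are
    synthetic, for simulation and testing — they are not COSMIC signatures.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    if include_basepair:
        gc = np.zeros(96)
        gc[list(GC_CHANNEL_INDICES)] = 1.0 / 48
        at = np.zeros(96)
        at[list(AT_CHANNEL_INDICES)] = 1.0 / 48
        cols["synGC"] = gc
        cols["synAT"] = at
    for j in range(n_random):
        name = "synNEAR" if j == 0 else f"syn{j + 1}"
        cols[name] = rng.dirichlet(np.full(96, alpha))
    df = pd.DataFrame(cols, index=list(CHANNEL_LABELS))
    return SignatureMatrix(df)


def mixture_channel_distribution(refs: SignatureMatrix,
                                 proportions: Mapping[str, float]) -> np.ndarray:
    """Collapse a signature mixture into one 96-channel probability vector."""
    dist = np.zeros(96)
    for name, p in proportions.items():
        dist += p * refs[name]
    total = dist.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("mixture proportions must sum to 1")
    return dist / total


# ---------------------------------------------------------------------------
# SV simulation


def simulate_svs(genome: GenomeDef, n_sv: int,
                 hotspots: Sequence[tuple[str, int, int]],
                 hotspot_weight: float, seed_or_rng, condition: str,
                 sample: str | None = None) -> list[SvBreakend]:
    """Draw ``n_sv`` SV events (two breakends each) from a hotspot mixture.

    With probability ``hotspot_weight`` a breakend-pair anchor falls in a
    hotspot interval (chosen proportional to interval length), otherwise
    uniformly on the genome.  Intra-chromosomal events (DEL/DUP/INV) place
    the partner breakend a log-uniform 10 kb - 1 Mb away; translocations
    draw it independently from the same mixture.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if not 0.0 <= hotspot_weight <= 1.0:
        raise ValueError("hotspot weight must be in [0, 1]")
    for chrom, start, end in hotspots:
        genome.validate_position(chrom, start)
        genome.validate_position(chrom, end)
    sample = sample or condition
    chroms = list(genome.names)
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    chrom_p = lengths / lengths.sum()
    hs_len = np.array([end - start + 1 for _, start, end in hotspots], dtype=float)
    hs_p = hs_len / hs_len.sum() if len(hotspots) else None

    def draw_position() -> tuple[str, int]:
        if len(hotspots) and rng.random() < hotspot_weight:
            h = rng.choice(len(hotspots), p=hs_p)
            chrom, start, end = hotspots[h]
            return chrom, int(rng.integers(start, end + 1))
        ci = rng.choice(len(chroms), p=chrom_p)
        return chroms[ci], int(rng.integers(1, lengths[ci] + 1))

    out: list[SvBreakend] = []
    for i in range(n_sv):
        svtype = SV_TYPES[rng.integers(0, 4)]  # DEL/DUP/INV/TRA
        chrom1, pos1 = draw_position()
        if svtype == "TRA":
            chrom2, pos2 = draw_position()
        else:
            size = int(np.exp(rng.uniform(np.log(1e4), np.log(1e6))))
            pos2 = pos1 + size
            chrom2 = chrom1
            if pos2 > genome.lengths[chrom1]:
                pos2 = max(1, pos1 - size)
        event_id = f"{condition}_sv{i}"
        out.append(SvBreakend(chrom1, pos1, svtype, event_id, sample, condition))
        out.append(SvBreakend(chrom2, pos2, svtype, event_id, sample, condition))
    return out


# ---------------------------------------------------------------------------
# SNV simulation


def _context_alleles(seq: str, pos: int, ch_idx: int):
    """Alleles realizing channel ``ch_idx`` at 1-based ``pos``, or None."""
    if pos < 2 or pos + 1 > len(seq):
        return None
    tri = seq[pos - 2: pos + 1]
    target, rc, fwd, rev = _CHANNEL_REALIZATION[ch_idx]
    if tri == target:
        return fwd
    if tri == rc:
        return rev
    return None


def _random_substitution(rng, ref: str) -> str:
    alts = [b for b in "ACGT" if b != ref]
    return alts[rng.integers(0, 3)]


def simulate_snvs(genome: GenomeDef, sequences: Mapping[str, str] | None,
                  breakends: Sequence[SvBreakend], truth: SimulationTruth,
                  condition: str, seed_or_rng,
                  refs: SignatureMatrix | None = None,
                  sample: str | None = None, max_retries: int = 1000,
                  ) -> tuple[list[SnvRecord], pd.DataFrame]:
    """Simulate background and SV-proximal SNVs for one condition.

    Background SNVs: Poisson(b * G/1e6) uniform positions.  Proximal SNVs:
    per breakend, Poisson(k) positions at breakend +/- Uniform(1, c), never
    on the breakend itself.  With ``sequences`` and ``refs`` given, each
    SNV's channel is drawn from its stratum's signature mixture and realized
    against the local context by rejection sampling (bounded retries, then a
    context-agnostic fallback counted in the labels).  Without sequences,
    alleles are drawn uniformly and channels are not assigned.

    Returns the records and a per-record label table
    (stratum, signature mixture used, drawn channel, fallback flag).
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    sample = sample or condition
    chroms = list(genome.names)
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    chrom_cum = np.cumsum(lengths / lengths.sum())

    near_cum = bg_cum = None
    if sequences is not None and refs is not None:
        if truth.near_mixture:
            near_cum = np.cumsum(
                mixture_channel_distribution(refs, truth.near_mixture))
        if truth.background_mixtures and condition in truth.background_mixtures:
            bg_cum = np.cumsum(mixture_channel_distribution(
                refs, truth.background_mixtures[condition]))

    records: list[SnvRecord] = []
    labels: list[tuple] = []

    def place(draw_pos, dist_cum, stratum: str) -> None:
        chrom, pos = draw_pos()
        if dist_cum is None:
            if sequences is not None:
                ref = sequences[chrom][pos - 1]
            else:
                ref = "ACGT"[rng.integers(0, 4)]
            alt = _random_substitution(rng, ref)
            records.append(SnvRecord(chrom, pos, ref, alt, sample, condition))
            labels.append((stratum, None, False))
            return
        ch_idx = int(np.searchsorted(dist_cum, rng.random() * dist_cum[-1]))
        for _ in range(max_retries):
            alleles = _context_alleles(sequences[chrom], pos, ch_idx)
            if alleles is not None:
                records.append(SnvRecord(chrom, pos, alleles[0], alleles[1],
                                         sample, condition))
                labels.append((stratum, CHANNEL_LABELS[ch_idx], False))
                return
            chrom, pos = draw_pos()
        ref = sequences[chrom][pos - 1]  # fallback: context-agnostic placement
        alt = _random_substitution(rng, ref)
        records.append(SnvRecord(chrom, pos, ref, alt, sample, condition))
        labels.append((stratum, CHANNEL_LABELS[ch_idx], True))

    # background component
    G = genome.total_length
    b = truth.background_per_mb[condition]
    n_background = rng.poisson(b * G / 1e6)

    def draw_background() -> tuple[str, int]:
        ci = int(np.searchsorted(chrom_cum, rng.random() * chrom_cum[-1]))
        return chroms[ci], int(rng.integers(2, lengths[ci]))  # flanks stay inside

    for _ in range(n_background):
        place(draw_background, bg_cum, "background")

    # SV-proximal component
    c = truth.cluster_width_bp
    for be in breakends:
        L = genome.lengths[be.chrom]
        n_prox = rng.poisson(truth.cluster_mean)

        def draw_proximal(be=be, L=L) -> tuple[str, int]:
            offset = int(rng.integers(1, c + 1)) * (1 if rng.random() < 0.5 else -1)
            pos = min(max(be.pos + offset, 2), L - 1)
            if pos == be.pos:  # clamping collision: keep off the breakend
                pos = pos + 1 if pos < L - 1 else pos - 1
            return be.chrom, pos

        for _ in range(n_prox):
            place(draw_proximal, near_cum, "proximal")

    label_df = pd.DataFrame(labels, columns=["stratum", "channel", "fallback"])
    return records, label_df


def simulate_dataset(truth: SimulationTruth,
                     with_sequence: bool = True,
                     refs: SignatureMatrix | None = None):
    """Simulate the full two-condition dataset described by ``truth``.

    Returns a dict with the genome, sequences (or None), reference matrix
    used (or None), and per-condition breakends, SNV records and label
    tables.  All randomness derives from ``truth.seed``.
    """
    ss = np.random.SeedSequence(truth.seed)
    seeds = ss.spawn(1 + 2 * len(truth.condition_labels))
    if with_sequence:
        genome, sequences = simulate_genome(
            truth.chrom_lengths, np.random.default_rng(seeds[0]).integers(2**31))
        if refs is None:
            refs = synthetic_signature_matrix(seed=truth.seed)
    else:
        genome, sequences, refs = truth.genome, None, None
    out = {"genome": genome, "sequences": sequences, "refs": refs,
           "breakends": {}, "snvs": {}, "labels": {}}
    for i, cond in enumerate(truth.condition_labels):
        rng_sv = np.random.default_rng(seeds[1 + 2 * i])
        rng_snv = np.random.default_rng(seeds[2 + 2 * i])
        bes = simulate_svs(genome, truth.n_sv[cond], truth.hotspots,
                           truth.hotspot_weight, rng_sv, cond)
        snvs, labels = simulate_snvs(genome, sequences, bes, truth, cond,
                                     rng_snv, refs=refs)
        out["breakends"][cond] = bes
        out["snvs"][cond] = snvs
        out["labels"][cond] = labels
    realized = {cond: {k: int(v) for k, v in
                       out["labels"][cond]["channel"].value_counts().items()}
                for cond in truth.condition_labels}
    fallbacks = {cond: int(out["labels"][cond]["fallback"].sum())
                 for cond in truth.condition_labels}
    truth.realized = {"channel_counts": realized, "fallback_counts": fallbacks}
    return out


# ---------------------------------------------------------------------------
# truth persistence

_REQUIRED_FIELDS = ("seed", "chrom_lengths", "condition_labels", "n_sv",
                    "hotspots", "hotspot_weight", "cluster_mean",
                    "cluster_width_bp", "background_per_mb")


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        raw = json.load(fh)
    missing = [f for f in _REQUIRED_FIELDS if f not in raw]
    if missing:
        raise ValueError(f"truth file missing fields: {missing}")
    raw["condition_labels"] = tuple(raw["condition_labels"])
    raw["hotspots"] = [tuple(h) for h in raw["hotspots"]]
    known = {f.name for f in dataclasses.fields(SimulationTruth)}
    extra = set(raw) - known
    if extra:
        raise ValueError(f"truth file has unknown fields: {sorted(extra)}")
    return SimulationTruth(**raw)
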