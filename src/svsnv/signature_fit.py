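"""Non-negative refitting of 96-channel spectra onto reference SBS signatures.

Given a spectrum ``m`` (96 counts) and a reference matrix ``S`` (96 x K
probability columns), solve ``min ||m - S e||_2`` subject to ``e >= 0`` and
report exposures on the SNV-count scale, together with the cosine similarity
between the reconstruction and the input.  Spectra with 10 or fewer SNVs are
refused outright — attributions on so few mutations are not meaningful.

Refitting is applied per proximity stratum (within ``d`` of SV breakpoints
vs elsewhere) and to the whole genome, so signature levels near SV sites can
be compared against the genome-wide background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .genome import GenomeDef
from .spectrum import MutationSpectrum, build_spectrum
from .sv_proximity import DEFAULT_PROXIMITY_BP, partition_snvs
from .variant_io import SignatureMatrix, SnvRecord, SvBreakend

MIN_SNVS = 10  # strata with <= this many SNVs are not analyzed


class TooFewSnvsError(ValueError):
    """Raised when a spectrum has too few SNVs for signature attribution."""


@dataclass
class ExposureVector:
    """Per-signature SNV-count attribution for one spectrum."""

    signatures: tuple[str, ...]
    exposures: np.ndarray          # counts, >= 0
    residual_norm: float
    cosine: float                  # reconstruction vs input spectrum
    input_total: float

    @property
    def proportions(self) -> np.ndarray:
        total = self.exposures.sum()
        return self.exposures / total if total > 0 else self.exposures

    def as_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=list(self.signatures))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"signature": list(self.signatures),
                             "exposure": self.exposures,
                             "proportion": self.proportions})


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two 96-vectors; errors on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def refit_exposures(spec: MutationSpectrum | np.ndarray, refs: SignatureMatrix,
                    min_snvs: int = MIN_SNVS,
                    prune_tolerance: float | None = None) -> ExposureVector:
    """Attribute a spectrum to reference signatures by NNLS.

    ``spec`` may be a MutationSpectrum or a raw 96-vector of (possibly
    real-valued) channel counts.  Exposures are on the SNV-count scale (they
    need not sum exactly to the input total; the residual carries the rest).
    ``prune_tolerance`` enables backward elimination: signatures whose
    removal costs less than that much reconstruction cosine are dropped,
    greedily.
    """
    if isinstance(spec, MutationSpectrum):
        m = spec.counts.astype(float)
    else:
        m = np.asarray(spec, dtype=float)
        if m.shape != (96,):
            raise ValueError("spectrum vector must have 96 channels")
    total = m.sum()
    if total <= min_snvs:
        raise TooFewSnvsError(
            f"spectrum has {total} SNVs; attribution requires more than {min_snvs}")
    S = refs.values
    active = list(range(S.shape[1]))
    e, rnorm = scipy.optimize.nnls(S, m)
    cos = cosine_similarity(S @ e, m)
    if prune_tolerance is not None:
        improved = True
        while improved and len(active) > 1:
            improved = False
            for drop in list(active):
                trial = [j for j in active if j != drop]
                e_t, rn_t = scipy.optimize.nnls(S[:, trial], m)
                cos_t = cosine_similarity(S[:, trial] @ e_t, m)
                if cos - cos_t < prune_tolerance:
                    active, cos, rnorm = trial, cos_t, rn_t
                    e = np.zeros(S.shape[1])
                    e[trial] = e_t
                    improved = True
                    break
    return ExposureVector(tuple(refs.names), np.asarray(e), float(rnorm),
                          float(cos), input_total=float(total))


@dataclass
class StratifiedAttribution:
    """Exposure refits for near-SV, far-from-SV and whole-genome strata."""

    near: ExposureVector | None
    far: ExposureVector | None
    whole_genome: ExposureVector | None
    not_analyzed: tuple[str, ...]  # strata failing the >10-SNV filter
    n_near: int
    n_far: int


def stratified_attribution(snvs: Sequence[SnvRecord],
                           breakends: Sequence[SvBreakend],
                           genome: GenomeDef,
                           sequence,
                           refs: SignatureMatrix,
                           d: int = DEFAULT_PROXIMITY_BP,
                           min_snvs: int = MIN_SNVS) -> StratifiedAttribution:
    """Refit exposures separately for SNVs near SV sites, far, and genome-wide.

    Strata with too few SNVs are reported as not analyzed rather than
    raising, so a sparse stratum does not abort the others.
    """
    part = partition_snvs(snvs, breakends, d=d, genome=genome)
    results: dict[str, ExposureVector | None] = {}
    skipped: list[str] = []
    for name, subset in (("near", part.near), ("far", part.far),
                         ("whole_genome", list(snvs))):
        spec = build_spectrum(subset, sequence)
        try:
            results[name] = refit_exposures(spec, refs, min_snvs=min_snvs)
        except TooFewSnvsError:
            results[name] = None
            skipped.append(name)
    return StratifiedAttribution(results["near"], results["far"],
                                 results["whole_genome"], tuple(skipped),
                                 n_near=len(part.near), n_far=len(part.far))
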