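# Methods

`svsnv` analyzes paired somatic call sets — single-nucleotide variants
(SNVs) and structural-variant (SV) breakpoints — to separate the SNV load
of a genome into a component that tracks SVs and a component that does not,
and to ask whether the mutational *processes* (SBS signatures) near SV
breakpoints differ from those acting genome-wide.

## Data model and conventions

Internal coordinates are 1-based inclusive (the VCF convention); BED/BEDPE
0-based half-open coordinates are converted at the I/O boundary and the
conversion is its own inverse. An "SV site" is a breakpoint locus: every
breakend of an event counts, because both ends of a rearrangement are
lesion positions. Counting functions expose `sv_unit="breakends"`
(default) or `"events"` and record which was used. Records on chromosomes
absent from the genome definition are rejected rather than dropped, so
denominators (genome length G) stay consistent.

## 96-channel spectra

Each substitution is classified in the context of one flanking base on
each side and collapsed onto the pyrimidine strand (C- or T-centered),
giving the 96 standard channels in COSMIC order. Contexts containing N or
falling off a chromosome end are counted as unclassifiable, never
silently dropped, so classified + unclassifiable always equals the input
count. Spectra are additive and strand-invariant by construction; both
properties are asserted in tests on randomized fixtures against an
independent per-record tally.

The A-T versus G-C comparison ranks the 48 T-centered (or C-centered)
channels, takes the top-k and bottom-k (k = 10 by default), sums each
subset per sample, and applies a two-tailed Welch's t-test between
conditions on those per-sample sums (one test per subset, not per
channel). Ranking uses the mean per-sample count **pooled over both
conditions**. Ranking on the induced condition alone is available
(`rank_by="condition_b"`) but is not the default: selecting the extreme
channels on the same counts that are then tested biases the bottom subset
(the channels are picked partly for their downward noise), which in
simulation inflated the bottom-subset false-positive rate to ~67% at
α = 0.05; pooled ranking spreads the selection noise symmetrically across
conditions and restores the nominal level.

## Proximity stratification and the expected-random model

SNVs within distance d (default 1 Mb) of any breakend form the "near"
stratum; membership is evaluated against the merged union of per-breakend
windows [pos − d, pos + d], clipped at chromosome ends. The expected
number of near SNVs under uniform random placement is reported two ways:

* **naive**: `n_SNV / G × n_SV × 2 × R` — the two-flank formula (each SV
  site contributes a flank of R on each side). It ignores overlap between
  neighborhoods and clipping at chromosome ends, so it can exceed n_SNV;
  it is reported verbatim for comparability.
* **corrected**: `n_SNV × L_merged / G`, where L_merged is the merged
  neighborhood length — the exact uniform-placement expectation.

The "×2" is read as the two flanks of each counted SV site (the
alternative reading — two breakends per event — is equivalent to choosing
`sv_unit="events"` with twice the range). On non-overlapping, unclipped
neighborhoods the two expectations agree up to discretization: an
inclusive integer interval of radius R covers 2R + 1 bases while the
formula counts 2R, a relative difference of 1/(2R) per site. Tests assert
equality at exactly that resolution. The default range grid is 13
log-spaced values from 1 kb to 10 Mb.

## Windowed decomposition

SVs (breakends) and SNVs are counted in windows of w ∈ {15, 30, 60} Mb
tiling each chromosome from position 1. The final partial window of each
chromosome is flagged and excluded from regression by default (a flag
length-weights it instead); the handling of chromosome remainders is a
genuinely open choice and exclusion keeps the count model homogeneous.
Ordinary least squares of SNV count on SV count across windows gives:

* the **slope** — SV-dependent SNVs per SV (its natural unit from a
  counts-on-counts regression; it is deliberately not rescaled to a
  per-Mb quantity);
* the **intercept** — SV-independent SNVs per window, converted to a rate
  per Mb by dividing by w/10⁶.

OLS is the default (a Poisson GLM with identity link is available);
regression pools windows across chromosomes within one sample. Condition
comparisons report slope and intercept-rate ratios with delta-method 95%
confidence intervals, plus Student and Welch t-tests on the window-level
residuals of the two fits. Per-chromosome SV accumulation rates
(breakends per Mb) are Pearson-correlated between conditions, and SV
totals are divided by chromosome copy numbers when the genome definition
carries them.

## Signature refitting

De novo signature extraction is out of scope; the implemented analogue is
non-negative least squares (NNLS) refitting: given a 96 × K reference
matrix S of signature probability columns and a spectrum m, solve
min ‖m − S·e‖₂ subject to e ≥ 0 (scipy's active-set NNLS, which satisfies
the KKT conditions to machine precision). Exposures are reported on the
SNV-count scale, with the residual norm and the cosine similarity between
reconstruction and input. Refitting is scale-equivariant, and duplicate
reference columns cannot worsen the residual (the split between
duplicates is arbitrary but their total is stable). Spectra with ≤ 10
SNVs are refused — attributions on so few mutations are noise — and in
the stratified analysis such strata are reported as not analyzed rather
than aborting the rest. An optional backward-elimination mode drops a
signature when removing it costs less than a stated cosine tolerance; it
is off by default.

## Synthetic data generator

The generator produces the structure the analysis assumes, with exported
ground truth, so every stage is testable by parameter recovery:

* **Genome**: i.i.d. uniform A/C/G/T per chromosome. Default scale:
  5 chromosomes × 30 Mb — large enough for 1 Mb proximity neighborhoods
  and minutes-scale test runs.
* **SVs**: n_sv events per condition (default 100), each with two
  breakends; anchors drawn from a mixture of a uniform component and
  shared hotspot intervals (default 4 hotspots of 2 Mb, mixture weight
  0.5). Both conditions use the same hotspots; only the random stream
  differs, which is what makes the between-condition per-chromosome SV
  correlation non-trivial.
* **SNVs**: a background component, Poisson(b × G/10⁶) uniform positions
  with b = 2/Mb in the first condition and 5.6/Mb (2.8-fold) in the
  second; and a proximal component, Poisson(k = 30) SNVs per breakend
  placed at breakend ± Uniform(1, c) with c = 0.5 Mb (uniform within the
  cluster; no distance decay is modeled). SNVs never coincide with
  breakend positions, keeping distance-0 semantics unambiguous.
* **Channels**: each SNV's channel is drawn from its stratum's signature
  mixture (near-SV: a peaked synthetic signature; background: a mixture
  of C-centered and T-centered block signatures, T-enriched in the second
  condition) and realized against the local sequence context by rejection
  sampling with a 1000-retry cap and a context-agnostic fallback; the
  truth file records realized channel counts and fallback tallies, so the
  achieved mixture is auditable. Reference signatures are synthetic
  (generated, clearly named `syn*`); no COSMIC catalog is shipped.

All randomness flows from one integer seed through `numpy`'s SeedSequence
spawning; identical seeds give identical call sets across runs, and the
truth JSON round-trips losslessly.

What the generator does **not** emulate: sequencing error and coverage
dropout, real trinucleotide composition (the genome is uniform), clonal
structure, kataegis-style local hypermutation beyond the uniform cluster,
and distance decay of SV-proximal mutation rates. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to real-data artifacts.

## Problem sizes used in tests and the acceptance script

Regression-recovery runs use 9 chromosomes × 180 Mb — 108 complete 15 Mb
windows (54 at 30 Mb, 27 at 60 Mb) — simulated without sequence, since
only positions enter the window counts; 20 seeds in tests, 10 in the
acceptance script. Sequence-bearing runs (spectra, refitting, stratum
separation) use the 5 × 30 Mb default; the Monte-Carlo check of the
expected-random formula uses a 100 Mb genome with two breakends placed so
neighborhoods stay non-overlapping and unclipped across the whole 1 kb –
10 Mb range grid.

## Numerical choices and degenerate inputs

Ties in channel ranking are broken by stable sort order. A regression
with all-identical SV counts raises a degenerate-design error; fewer than
3 usable windows is an error. Ratio estimates with a non-positive
denominator are returned as undefined; a non-positive numerator yields
the ratio with no confidence interval (flagged). Cosine similarity on a
zero vector is an error rather than a silent 0. Signature columns must
sum to 1 within 10⁻³ on input and are renormalized exactly after
validation.
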