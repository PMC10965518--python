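# svsnv

Co-analysis of somatic SNVs and structural variants (SVs): are point
mutations riding along with genomic rearrangements, or arising
independently of them — and do the mutational signatures near SV
breakpoints differ from the rest of the genome?

The package is aimed at analysts working with somatic call sets (e.g.
irradiated vs unirradiated cell clones, or tumor cohorts) who want to:

* build pyrimidine-normalized 96-channel trinucleotide mutation spectra
  and compare T-centered (A-T) vs C-centered (G-C) channel classes
  between conditions;
* test whether SNVs cluster around SV breakpoints, comparing the observed
  near-SV SNV count against its expected random value
  `E = n_SNV / G × n_SV × 2 × R` over ranges R from 1 kb to 10 Mb
  (an overlap-corrected expectation `n_SNV × L_merged / G` is always
  reported alongside);
* decompose SNV load by counting SVs and SNVs in 15/30/60 Mb windows and
  regressing SNV on SV counts: the slope estimates SV-dependent SNVs per
  SV, the intercept (per Mb) the SV-independent background rate
  `snv_w = intercept + slope × sv_w`;
* attribute spectra to reference SBS signatures by non-negative least
  squares refitting, separately for SNVs within 1 Mb of SV sites and for
  the whole genome;
* simulate all of the above with known ground truth, so every estimator
  is validated by parameter recovery.

## Worked example

Simulate a two-condition dataset and decompose its SNV load:

```
$ svsnv simulate --seed 5 --out-dir sim/
$ svsnv decompose --vcf sim/unirradiated.snvs.vcf \
    --sv sim/unirradiated.svs.bedpe --chrom-sizes sim/genome.sizes \
    --window 15000000 --keep-partial --out decomp.json
$ python -m json.tool decomp.json
{
    "15000000": {
        "intercept_rate_snv_per_mb": 1.1086470143612985,
        "intercept_se": 17.680096982931765,
        "intercept_snv_per_window": 16.629705215419477,
        "n_windows": 10,
        "r_squared": 0.9955639398343771,
        "slope_se": 0.7364150523281064,
        "slope_snv_per_sv": 31.20351473922902
    }
}
```

The simulator places Poisson(30) SNVs within 0.5 Mb of each SV breakend
on top of a 2 SNVs/Mb uniform background, so the slope recovers ~30 SNVs
per SV (here 31.2 ± 0.7). The intercept rate is noisy on this small
default genome — 1.11 with a standard error of 1.18 SNVs/Mb from only 10
windows of 15 Mb; the acceptance script below runs the same recovery at
108 windows, where it lands within a few percent of the 2/Mb truth.
The same library calls are available in Python
(`svsnv.count_in_windows`, `svsnv.fit_decomposition`, ...), and
`svsnv run-all --seed 5 --out-dir out/` executes every stage — spectra,
proximity curves, decomposition per window size, condition comparison,
stratified signature refits — into one JSON summary stamped with the seed
and a config hash.

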