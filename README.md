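# c4cnv

Multiallelic copy-number genotyping and case-control association for the
complement *C4* locus, from raw MLPA peak heights to pooled random-effects
estimates.

Copy-number variation at *C4* is multiallelic: diploid genomes carry 0–5
copies of the *C4A* isotype and 0–4 copies of *C4B*. Associating such a
locus with disease (here: late-stage age-related macular degeneration, AMD)
takes a chain of steps that each need careful QC — quantitative probe
intensities must be normalized and converted to integers, the integers
coded additively in logistic models, per-study effects pooled across
cohorts, and the signal disentangled from linked SNPs in the neighbouring
*CFB/C2* region. `c4cnv` implements that chain as a tested, reusable
pipeline, together with a synthetic-data generator that provides ground
truth for every stage.

## The method

**Dosage normalization.** For sample *i* and test probe *j* (`C4A`, `C4B`,
`C4-ex30` for total *C4*), with control probes at the diploid loci *EP300*
and *CREBBP*:

```
r_ij = h_ij / (h_i,EP300 + h_i,CREBBP)      d_ij = r_ij / median_i(r_ij)
```

computed per normalization batch (study). The ratio cancels per-sample run
intensity and batch scale; the median rescaling puts the modal copy-number
class near dosage 1. Where the total-*C4* probe failed, the total dosage is
imputed as `(d_C4A + d_C4B) / 2` and flagged.

**Integer calling.** Dosages cluster at equispaced values `k·s`. Sorted
dosages are partitioned at gaps, the most populous subgroup is anchored to
the configured modal integer (2 for *C4A*/*C4B*, 4 for total *C4*), and
every sample is assigned to the nearest point of the anchored grid. Zero
dosage means an absent peak: copy number 0, flagged as a suspected
homozygous deletion for wet-lab confirmation. Calls near an assignment
boundary (within 1.5 robust SDs of the batch noise) are flagged
low-confidence.

**Association.** Logistic regression with the genotype coded as the number
of gene copies, so `exp(β)` is the odds ratio per copy; adjusted for age
and sex (and study when pooling), with stratified runs (sex, disease
subtype, age bands <71 / 71–78 / >78 years) and models conditioned on the
four *CFB/C2* variants rs429608, rs114190211, rs204993, rs142511358.

**Meta-analysis.** Per-study log odds ratios are pooled with the
DerSimonian–Laird random-effects estimator; heterogeneity is reported as Q,
τ² and I², and p-values are Bonferroni-corrected for the three CNV loci
tested.

**Haplotypes.** For the small SNP panel, haplotype frequencies are
estimated by the classical EM algorithm for unphased genotypes, and the
average number of *C4A* copies carried per haplotype is obtained by
regressing diploid copy number on posterior-expected haplotype dosages
(no intercept), so frequency-weighted haplotype loads reproduce the
population mean copy number exactly.

## Worked example

Generate a synthetic cohort (1050 samples across three study batches, true
per-copy odds ratio 0.81 for *C4A*) and run the whole pipeline:

```
c4cnv simulate --seed 3 --outdir demo
c4cnv run demo/config.yaml        # config listing the three demo files
```

The report's *C4A* forest table from this exact run:

```
### C4A (OR per copy)
study             OR            95% CI  weight
AUS            0.633 [  0.506;  0.791]  34.2%
WUE            0.849 [  0.674;  1.069]  33.7%
MUE-TUE        0.987 [  0.769;  1.266]  32.2%
pooled (RE)    0.806 [  0.623;  1.042]  100.0%
Q = 7.209 (df 2), I2 = 72.3%, tau2 = 0.0372, p_het = 0.0272, p = 0.0994
```

Each study row is that study's covariate-adjusted logistic estimate of the
odds ratio per additional *C4A* copy; the pooled row is the random-effects
combination. At this cohort size the pooled point estimate (0.806) sits on
the generating truth (0.81) while the interval is still wide — the
generator's recovery properties at full study scale are exercised by the
test suite and the acceptance script. The run directory additionally
contains the normalized dosages, integer calls with QC flags, the
homozygous-deletion worklist, the per-model association table, the
haplotype report (frequencies and per-haplotype *C4A* load) and a run log
with per-stage row counts.

The same stages are available as library functions (`normalize_dosages`,
`call_integer_cn`, `fit_cn_logistic`, `pool_random_effects`,
`em_haplotype_frequencies`, ...) and as CLI subcommands (`simulate`,
`dose`, `call`, `assoc`, `meta`, `haplo`, `summary`, `run`).

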