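# Methods

This note documents the models behind `c4cnv`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions that matter for reproducing results.

## Generative model (synthetic data)

Copy numbers are generated **per haploid genome** and summed to diploid.
Each haplotype in a small SNP-haplotype table carries a distribution of
haploid *C4A* copies; drawing the haplotype pair and the haploid copies
jointly makes the haplotype–copy-number linkage coherent by construction,
which is what the conditional and haplotype analyses need to be testable.
*C4B* haploid copies are drawn independently (default 0/1/2 at
0.12/0.73/0.15), giving a diploid mode of 2 and range 0–4.

The default haplotype table has six haplotypes above 1 % frequency over
four SNPs. One low-copy haplotype (mean 0.6 haploid *C4A* copies) carries
the alternate allele of the third SNP and one high-copy haplotype (mean
1.5) carries the alternate allele of the first, emulating the tagging
structure the analysis must resolve. The patterns, frequencies and copy
distributions are synthetic placeholders chosen to be realistic for a
European-ancestry cohort — population copy-number frequencies for this
locus are not published at the resolution needed, so these values are the
package's own defaults, not measured ones. The implied diploid *C4A*
distribution has mode 2 (≈43 %), mean ≈2.0, and ≈2 % homozygous deletions.

Disease status follows
`P(case) = expit(β₀ + β_cn·c4a + β_age·(age−72) + β_sex·female + γ_study)`
with defaults β_cn = ln 0.81 (the protective per-copy effect used as
generating truth), β_age = 0.05/year, β_sex = 0.10, β₀ = 0.4. Cohorts are
assembled by rejection sampling from this population model until each
study's case and control quotas are filled; a draw cap
(`max_draw_factor`, default 400× the quota) turns degenerate logits into a
diagnostic error instead of a hang. Case/control totals and per-study
fractions default to the three-study composition 633/547/356 cases and
404/384/321 controls.

Peak heights are `probe_scale · copies · batch_scale(study) ·
sample_scale · ε`, with ε lognormal with mean 1 and coefficient of
variation `peak_noise_cv` (default 0.04) and a per-sample lognormal run
intensity (CV 0.15). Lognormal noise keeps heights positive and matches
the unimodal, symmetric dosage clusters seen in real MLPA data at small
CV. Control probes always represent 2 copies; zero copies produce an
exactly absent peak. The `C4-ex30` probe can be omitted for designated
studies to emulate a batch-wide probe failure.

**What the generator does not emulate:** sequence-level structure of the
locus (HERV insertion, isotype-defining sites), ligation-site
polymorphisms that miscall deletions in real MLPA, plate-level (as opposed
to study-level) batch effects, genotyping error in the SNP panel,
pedigree structure, and ascertainment beyond simple case/control quotas.
Passing recovery tests therefore show the *pipeline's* correctness under
its stated noise model, not robustness to every artefact of real data.

## Dosage normalization

`r = h_test / (h_EP300 + h_CREBBP)`, then division by the batch median of
`r` per probe. Batches default to the study label (normalization was
per-study in the motivating design; Fig-1-style per-study distributions
require it) and are configurable. The median is taken over cases and
controls pooled. Peak heights, not areas, are the default input; an
`height_column` option reads areas. Missing total-C4 dosages are imputed
as the isotype mean and explicitly flagged, never silently.

## Integer calling

The primary engine sorts dosages per batch, partitions at gaps larger than
`gap_frac` (default 0.5) times the expected spacing `1/modal`, anchors the
most populous subgroup to the configured modal integer (2, 2, 4 for
*C4A*, *C4B*, total), estimates the per-copy spacing from subgroup-centre
differences (robust to empty copy classes), and assigns every dosage to
the nearest point of the anchored equispaced grid. This is deterministic,
order-free and monotone: a higher dosage never receives a lower integer.
A constrained equispaced-mean Gaussian mixture (shared variance, free
weights, grid offset and scale re-estimated by EM) is available via
`CallingConfig(method="mixture")` and must satisfy the same invariants.

Numerical decisions:

* a dosage exactly half-way between two grid points goes to the **lower**
  integer and is flagged low-confidence — conservative toward deletion,
  which the confirmation worklist then catches;
* `cn = 0` always sets the suspected-homozygous-deletion flag; the
  worklist operation emits all zero-copy calls with study and dosage;
* calls outside the locus's admissible range (0–5 *C4A*, 0–4 *C4B*,
  0–9 total) are clamped to it and flagged;
* batches under 30 samples are refused (medians and gap structure are
  unreliable below that);
* a single gap-free subgroup spanning more than 1.5 expected spacings is
  an error ("no discernible subgroup structure") rather than a guess.

The low-confidence flag is noise-adaptive: a call is flagged when its
distance to the nearest assignment boundary is below `flag_sigma`
(default 1.5) times the robust SD (1.4826·MAD) of the batch's grid
residuals. The per-copy spacing of total *C4* (0.25 in dosage units) is
half that of the isotypes, so at the same noise the total locus flags more
calls — by design, uncertainty shows up as flags rather than as wrong
confident calls. At noise CV 0.04 this yields ≥ 99 % raw concordance for
*C4A*/*C4B*, ≥ 99 % concordance among confident total-C4 calls, and
`cn_total = cn_C4A + cn_C4B` in ≥ 99 % of samples with measured totals and
confident calls at all three loci. Confidence itself
(1 − 2·|offset|, 1 at a grid centre, 0 on a boundary) is an artifact of
this implementation, not a calibrated probability.

The differential-bias QC compares mean unrounded dosages of modal-class
carriers between cases and controls with Welch's t-test (pooled and per
study); no particular test is canonical here and Welch's makes the fewest
variance assumptions.

## Association

Models are fitted by maximum likelihood (IRLS, statsmodels `Logit`) with
Wald standard errors from the observed information; `exp(β ± 1.96·se)`
gives the 95 % CI. Codings that affect only nuisance terms: female = 1,
study indicators with the largest study as reference. Missing covariates
are handled complete-case per model, with per-model n reported.
Separation is detected via non-convergence or a coefficient exceeding 15
in absolute value and raised as an error naming the term; singular designs
are rejected before fitting. Age bands are <71, [71, 78], >78 years — the
band edges belong to the middle group, a choice the boundary text of the
motivating stratification leaves open (its stratum counts do not sum to
the cohort total, an upstream inconsistency this package cannot resolve).
Subtype strata compare each late-stage subtype's cases against **all**
controls, so those strata overlap by construction.

The model grid fits per-study crude models, the pooled study-adjusted
model, stratified models, and conditioned models (none, each
leave-one-out triple of the four *CFB/C2* SNPs, and the full quadruple).
Failures in one grid cell are recorded in the output row, never abort the
grid.

## Meta-analysis

DerSimonian–Laird moments estimator: fixed-effect weights `w = se⁻²`,
`Q = Σw(β−β_FE)²`, `τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw))`, random-effect
weights `1/(se²+τ²)`, I² = max(0, (Q−(k−1))/Q)·100. DL is the default and
the tested contract because it is the standard closed-form choice for a
handful of studies; REML is available behind `method="reml"`. No
small-sample (Knapp–Hartung) adjustment is applied — plain Wald pooling
matches the symmetric log-scale intervals this workflow reports. One
study passes through unchanged with τ² = 0 and I² reported as not
applicable. Bonferroni correction defaults to m = 3, the three CNV loci.

## Haplotypes

The classical EM estimator for unphased multilocus genotypes replaces
genome-scale phasing: with at most 8 SNPs the diplotype expansion is exact
and fast, and no external phasing binary is needed. Initialization is the
linkage-equilibrium product of allele frequencies plus a uniform 1e-12
floor (deterministic tie-break that avoids zero-locking); convergence is a
log-likelihood change below 1e-8 or 500 iterations; a seeded multi-start
option guards against local optima. Missing genotypes are summed over in
the E-step. Monomorphic input short-circuits to a single haplotype with no
iteration. Reported frequencies are the posterior-expected haplotype
dosage column means divided by two, which makes frequency bookkeeping
exactly consistent with the dosage matrix used downstream; haplotypes
below 1 % are collapsed into an "other" bin for reporting.

Downstream models use posterior-expected (fractional) haplotype dosages
rather than a best-guess phase, propagating phase uncertainty. The average
*C4A* copies per haplotype come from a no-intercept least-squares
regression of diploid copy number on the full haplotype-dosage basis: it
is the unique linear estimand consistent with additive haploid copy
contributions, and it guarantees `2·Σ freq_k·mean_k` equals the population
mean diploid copy number to numerical precision. A carrier-mean
alternative (`method="carrier_mean"`) is provided for comparison but is
not the contract. Haplotypes with zero observed dosage are reported as not
estimable.

## Problem sizes and tolerances in the test and acceptance runs

Recovery simulations use cohorts of 1050 samples (600/450) at noise CV
0.04 for calling, 2500 samples for haplotype-frequency (±0.02) and
copy-load (±0.1) recovery, 200 replicates at the full 1536/1109 study
scale for per-copy log-OR recovery (|bias| < 0.05, ~95 % Wald coverage),
1000 single-study cohorts of n = 600 for type-I error (0.05 ± 0.02), and
100 replicates of three 800-sample studies with planted per-copy ORs
0.7/1.0/1.3 for heterogeneity power (≥ 80 %). These sizes keep the whole
suite within a few minutes on one CPU while leaving the Monte-Carlo error
well inside each tolerance. Exact-arithmetic checks (normalization
identities, the 2×2 Woolf equivalence at 1e-6, the likelihood-grid
equivalence at 1e-4, the DL oracle at 1e-10, EM vs brute-force simplex
maximization at 1e-4) are independent of cohort size.

## Known limitations

* Total-C4 integer calls at the default noise level carry a ~20–25 %
  low-confidence rate; the isotype loci do not. Analyses of total *C4*
  should respect the flags.
* The calling engine assumes a single shared spacing per batch; strongly
  copy-dependent variance would bias boundaries for high copy numbers.
* The EM phasing is exact only up to 8 SNPs and provides no recombination
  or reference-panel modelling.
* Case/control quotas are filled by rejection from a prospective
  population model; extreme baseline logits are rejected rather than
  inverted retrospectively.
* The synthetic haplotype patterns and copy-number frequencies are
  placeholders (see above), so numeric results on synthetic data
  characterize the method, not the real locus.
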