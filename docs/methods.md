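# Methods

## Amplification error model

Preamplification is modelled as a molecule-level branching process. Each
cycle, every molecule independently produces one copy with probability
*p* (the per-cycle efficiency); each newly synthesised copy acquires a
substitution at a tracked hotspot with probability
*e* = base_error_rate × locus_multiplier (errors per base per
duplication). Parents persist unchanged; mutant molecules propagate in
later cycles; back-mutation is an *e*² effect and is ignored. The model is
molecule-level, not strand-level: one duplication event per selected
molecule per cycle, error applied to the copy only. A strand-resolved
semiconservative treatment would change the accumulation constant, not the
qualitative behaviour; the convention is exposed through the estimator's
`model_factor`.

Under this model the expected mutant fraction after *c* cycles at *p* = 1
is *f* = *c·e*/2: every cycle the newly synthesised strands are half of
the post-cycle population, and each early mutant lineage grows at the same
rate as the total. For *p* < 1 the package computes the expectation
iteratively (`expected_error_fraction`); at *p* = 0.95 and 22 cycles the
constant is ≈ 10.7 rather than 11.

Inversion gives the error-rate estimator ê = 2·*f*_obs/*c* with
*f*_obs = mut/wt. Confidence bounds are exact Clopper–Pearson intervals on
the binomial proportion mut/(mut+wt), mapped through
*p* → 2·(*p*/(1−*p*))/*c*; because *p̂*/(1−*p̂*) = mut/wt identically, the
point estimate always lies inside the transformed interval. Estimates
above 10⁻² violate the linear-accumulation assumption and are flagged.

### Variance caveat (jackpots)

The branching process has Luria–Delbrück-type jackpot variance: a mutation
in the first cycles founds a large clone, so the distribution of the final
mutant fraction is heavy-tailed relative to a binomial with the same mean.
The binomial CI of the estimator quantifies *sampling* uncertainty of the
droplet counts, not this process variance; the CI-coverage experiments
therefore draw counts from pools fixed at the analytic expected fraction,
which isolates the estimator's sampling machinery. Coverage against fully
stochastic amplification histories would be lower at small expected
counts; this is a known limitation of single-assay rate estimates, not of
the implementation.

## Simulator design and defaults

Defaults emulate the studied protocol: 22 preamplification cycles (12 as
the alternative condition), per-cycle efficiency 0.95, 3 pooled 1-ng
reactions ≈ 909 haploid genome equivalents of input, sequencing depth
10,000×, sequencing miscall rate 10⁻⁴, 20,000 droplets per well with four
or more wells merged (the simulator's default of 80,000 droplets
corresponds to four merged wells). AR is X-linked, so male samples
contribute one template per genome equivalent and female samples two.
Efficiency and input amount are declared assumptions — the protocol does
not fix them — and are overridable in `AmplificationConfig`.

Polymerase profiles carry a vendor-reported genome-averaged rate
(HotStarTaq 2×10⁻⁵, Phusion 4.4×10⁻⁷; SuperFi is specified only as a
bound, ≤ 2×10⁻⁷) and locus multipliers for the synthetic study scenario.
The multipliers are calibrated once from the observed artifact fractions
through *f* ≈ *c·e*/2 — Phusion×45 at F877L puts the expected ddPCR-arm
artifact fraction at ≈ 2.1×10⁻⁴, the centre of the observed
0.007–0.036 % range; Phusion×13 at T878A matches 0.004–0.011 %;
HotStarTaq×11 at F877L reproduces the sequencing-arm artifact fractions of
0.2–0.3 %; SuperFi×0 at every hotspot reproduces its uniformly clean
assays. These are scenario constants, not fitted parameters, and the
tests treat them as fixed study conditions.

Droplet partitioning samples the loaded molecules per allele, then uses
Poisson-loading occupancy: the wild-type channel count is
Binomial(D, 1−exp(−λ)) with λ = molecules/droplets, while the rare mutant
molecules are placed individually and deduplicated. This is exact for the
mutant channel in the regime of interest and accurate for the wild-type
channel to the (negligible) multinomial correlation.

What the generator does not emulate: fragment-length and GC-dependent
amplification bias, UMI/duplex error correction, droplet fluorescence
thresholding (inputs are classified counts), contamination, and real
inter-patient variation in cfDNA yield. Passing tests therefore
demonstrate internal consistency of the counting model and the analysis
chain, not performance on real plasma libraries.

## Filter cascade

Boundary semantics follow the protocol wording exactly: base quality ≥ 25
inclusive, mapping quality strictly > 18, alt reads ≥ 15 inclusive,
allelic fraction strictly > 0.15 % (a candidate at exactly 0.15 % is
excluded) and ≤ 50 %. The next-allele rule is read as
frequency-vs-frequency (equivalently count-vs-count at one site, since the
denominator is shared); with no second non-reference allele it passes
vacuously. All filters but the cohort-prevalence rule are conjunctive and
order-independent; prevalence is applied last over provisional calls, is a
strict majority (> 50 %), and counts every sample in the run including
controls (configurable via `cohort_samples` — whether the original
pipeline counted controls is not stated; with 6/13 carriers both readings
give the same outcome on the packaged cohort).

The allelic-fraction convention is 100·alt/ref, not 100·alt/(alt+ref):
the packaged tables' printed values uniquely identify it (33/7924 prints
0.42; the other convention gives 0.41). Table reproduction rounds half-up
at the printed precision; no packaged cell is a half-way case. Per-read
quality gating is gate-then-count: reads failing either threshold are
removed before aggregation (averaging-then-gating is not implemented; the
original pipeline's internal order is unstated, and gating is what the
protocol sentence describes).

## ddPCR quantification and copy number

The default reported statistic is the raw mutant/wild-type channel ratio,
because the study tables print exactly that and omit total droplet
counts; Poisson quantities (λ, fractional abundance, CIs) are computed
whenever totals are available (simulated data). Saturated assays (mutant
droplets, zero wild-type) report 100 % with a SATURATED flag — the
printed convention for pure mutant control wells. Double-positive
droplets count toward both channels; excluding them from the mutant count
is configurable.

Copy number is cn = (λ_target/λ_reference) × reference copies, sex-aware:
an X-linked reference (ZXDB) has 1 expected copy in a male sample, 2 in a
female; an autosomal reference (NSUN3) has 2, scaled to the male X
baseline. The increased-CN threshold is 1.9, inclusive. The exact formula
used by the original reader software is not printed, so the CN pathway is
property-tested rather than table-tested.

## Statistical comparisons

The paired locus comparison (F877L vs T878A artifact fractions under one
polymerase, 7 samples assayed for both) uses the exact two-sided Wilcoxon
signed-rank test (exact for n ≤ 25; zero differences dropped), giving
p = 2/2⁷ ≈ 0.016 when one locus is higher in all 7 pairs; a paired t-test
is reported alongside. No multiple-testing correction is applied: five
pre-specified hotspots in a confirmatory design. The test suite checks the
exact p-values against full 2ⁿ sign-flip enumeration.

## Concordance classification

Rules, in order: a positive no-template control anywhere invalidates the
run; a (locus, polymerase) whose preamplified wild-type control DNA is
mutant-positive is ARTIFACT_PRONE for that polymerase and cannot validate
or refute; a sequencing call positive under any clean polymerase is
VALIDATED (positive evidence takes precedence); negative under every
clean polymerase with data, FALSE_POSITIVE; otherwise NOT_ASSESSED.
Positivity is ≥ 1 mutant droplet (configurable). Healthy-donor sequencing
controls have no ddPCR arm of their own; `control_equivalents` maps them
onto the preamplified wild-type genomic DNA control, which is the same
mutation-free substrate — this is the package's rule for closing that gap
and is disabled by passing an empty mapping.

## Fixtures and problem sizes

All packaged data are plain-text tables regenerated from printed counts;
the FASTA context windows and locus coordinates are synthetic
(filename-labelled) because true genomic windows are not part of the
source tables — sequence-context features (GC content, homopolymer and
dinucleotide repeats) are therefore illustrative. Stochastic test sizes —
1000 amplification replicates for the mean-fraction law, 500 replicates
for KS equivalence against the per-lineage oracle and for CI coverage,
low-occupancy droplet experiments (λ = 0.02, 10⁶ droplets) for estimator
coverage — were chosen so that 3-SE bands and coverage proportions are
decisive while the full suite runs in a few seconds.
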