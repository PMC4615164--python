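# Methods

## The measurement model

A positional RIP-qPCR experiment probes one transcript with a set of short
amplicons (two near the ends, several internal, each ≤75 bp by design) and
measures, for each amplicon, its abundance in a factor pulldown (IP) versus
a matched aliquot of the same RNase-digested lysate (input). `looplens`
models the chain from Ct values back to molecule configurations.

**Ct → quantity.** Each primer pair's amplification efficiency E (template
multiplication per cycle, ideally 2) is fitted from its dilution curve by
ordinary least squares of Ct on log10(dilution), E = 10^(−1/slope). A
reaction's relative log abundance is −Ct·ln E, on an arbitrary per-assay
scale. Technical replicates are averaged in log space (equivalently, mean
Ct), since Ct noise is approximately additive in cycles; averaging
natural-scale quantities instead would upweight low-Ct outliers. The
per-assay scale — including any preamplification applied identically to IP
and input — cancels exactly in the IP/Input ratio, so no preamplification
bias correction is attempted.

**QC.** Individual reactions that are instrument-flagged or have an
undetermined Ct are dropped; whole sample × assay groups are dropped when
the technical-replicate SD exceeds `qc.max_tech_sd` (default 0.5 cycles) or
the mean Ct exceeds `qc.max_ct` (default 28, appropriate after
preamplification). Both thresholds are config-exposed; the defaults are
conventional reaction-quality cuts, and every dropped group is reported
with the rule that fired. Filtering is total — an empty result is legal and
surfaced as an error only when downstream stages need data.

**Normalization.** Two schemes, both scalar divisions of a profile:
*within-transcript* divides each amplicon's ratio by the arithmetic mean
over that transcript's amplicons (each profile then averages to exactly 1);
*cross-transcript* divides all profiles of a factor by the mean
reference-end ratio over transcripts (3′ for PAB1, 5′ for eIF4E/4G).
Arithmetic rather than geometric means are used because the plotted
quantities are linear-scale averages; a geometric option exists. The
cross-transcript divisor is computed per biological replicate (rather than
on replicate-averaged values) so replicate-level variation propagates into
the SEM; the choice is recorded in the manifest. Because both schemes are
scalar divisions, the closed-loop index is invariant to the choice — this
is asserted in the test suite.

## The closed-loop index

For a profile with both end classes present, the index is the
distal/proximal ratio of (class-mean) normalized end enrichments: distal =
3′ for cap factors, 5′ for PAB1. It is computed per biological replicate
and then averaged (mean ± SEM over replicates), matching how replicate
error is usually reported on the index itself; index-of-averaged-profiles
is available by aggregating first. Values above 1 are flagged
(`over_unity`), not truncated: sampling noise can push a ratio past 1
without biological meaning, and truncation would bias replicate means.

An optional background-subtraction mode computes
(distal − internal)/(proximal − internal), treating the internal amplicons
as a nonspecific baseline. It is off by default — internal amplicons serve
as a visual floor rather than an established correction, and subtraction
can produce nonpositive ends at low signal.

**Why a lower bound.** In the generative model below, with complete end
separation the ideal cap-factor index is c·p_closed/(p_closed+p_cap_only):
the true closed fraction among factor-engaged molecules, attenuated by the
co-capture efficiency c ≤ 1 and inflated only by the (small) background
term. Partial digestion adds a further co-location term that vanishes as
λ·length grows. The estimator therefore operates as a lower bound whenever
digestion is sufficient to separate the ends (λ·length ≫ 1, the intended
operating regime); with essentially no digestion both ends ride on the same
fragment and the index tends to 1 regardless of looping — which is why
controlled RNase digestion is integral to the assay, not an optional step.

## Statistics

- **Technical CIs**: Student-t intervals on the log scale,
  exp(mean ± t·se), asymmetric on the natural scale.
- **Condition comparisons**: a global one-tailed paired t-test across
  transcripts on replicate-mean indices (direction: second condition
  higher), refused below 3 common transcripts; per-transcript Welch
  two-sample t-tests on biological replicates, corrected across transcripts
  by Holm (default; Benjamini–Hochberg via config). Welch is used because
  3-vs-3 replicates give no basis for assuming equal variances, and no
  pairing of replicate numbers across conditions is assumed. Degenerate
  inputs (zero variance) resolve to p = 0.5/1/0 by the sign of the mean
  difference instead of NaN.
- **Fold range**: max/min of replicate-mean indices with transcript names.
- **Variance explained**: OLS R² of cap-factor 3′ enrichment on PAB1 3′
  enrichment across transcripts — the check that poly(A)-proximity effects
  alone cannot account for cap-side 3′ variation.
- **Covariate correlations**: Spearman by default (the index is
  ratio-scaled and skewed), Pearson optionally; pairwise deletion of
  missing covariate cells with per-covariate n reported.

## The simulator

Per molecule: a configuration state drawn from per-transcript probabilities
(closed / cap_only / tail_only / free); RNase cuts as a homogeneous Poisson
process at λ cuts/nt (an amplicon of span L survives with probability
e^(−λL)); capture rules — the factor's anchor-end fragment is retained when
the state includes the factor, the opposite anchor of a closed molecule
with per-factor co-capture efficiency c, any other fragment with background
probability β; input = all fragments. Counts per sample × assay become
Ct = intercept_a − ln(count)/ln(E_a) + N(0, σ) per technical replicate,
with E_a and intercept_a drawn once per dataset (the per-assay scale is
arbitrary and must cancel — tested). Zero counts yield undetermined
(missing) Cts. Dilution curves are generated from the same E_a.

Closed-form expected IP/Input ratios for every amplicon are derived from
the independence of Poisson counts on disjoint intervals (see
`expected_enrichment`); Monte-Carlo agreement with these expectations on a
parameter grid is the cornerstone test of the simulator.

Defaults, chosen once as a realistic study design: 16 transcripts of
900–3000 nt whose cap-side closed fractions span 0.05–0.8 (the wide
between-mRNA spread the assay is built to detect); 5 amplicons of 70 nt per
transcript; λ = 0.01/nt so a 70-nt amplicon survives ~50% of molecules (the
digestion dose→λ mapping is not identifiable from assay descriptions, so λ
is calibrated to this design target); co-capture c = 0.8; background
β = 0.002; 20 000 molecules per transcript × replicate; σ_Ct = 0.15 cycles;
E_a ∈ [1.85, 2.0]; 3 technical and 3 biological replicates; factors eIF4E
and PAB1 (eIF4E and eIF4G are mechanistically one cap-factor channel).
Conditions are parameter overlays — e.g. a starvation-like condition can
lower λ (granule-protected RNA digests poorly) and raise β — with no claim
of mechanistic fidelity.

**What the simulator does not emulate.** Preamplification bias, primer
thermodynamics and sequence effects; footprint protection of bound regions
(cuts are homogeneous); an explicit poly(A) tail (PAB1 anchors to the
fragment carrying the final nucleotide); between-chip batch effects;
transcript-level abundance differences (each transcript gets its own
molecule pool, which downstream ratios cancel anyway). Biological-replicate
variation arises solely from molecule sampling and read-out noise, not from
culture-to-culture parameter drift, so real-data SEMs will be larger than
simulated ones. Background retention is drawn independently per amplicon
rather than once per fragment; marginal per-assay expectations — everything
the pipeline consumes — are unaffected, only the (unused) joint
distribution across amplicons sharing a fragment differs. Note also that in
this generator cap-side and PAB1-side 3′ enrichments are intrinsically
coupled through p_closed, so simulated variance-explained values are high
by construction; on real data this quantity is an empirical question.
Passing recovery tests therefore demonstrate estimator correctness under
the stated mechanism, not robustness to every real-data artifact.

## Validation experiments (problem sizes)

The shipped tests validate: exact efficiency recovery on noiseless curves;
the normalization invariants to 1e−9; Monte-Carlo vs closed-form agreement
at 10⁵ molecules over a 12-point grid (3 conditional SEs); parameter
recovery at the study design size over several seeds (Spearman ≥ 0.9;
MAE ≤ 0.05 with c = 1, β = 0); the lower-bound property at c = 0.5 (≥95% of
transcript × seed combinations undershoot); type-I error control of the
Holm-corrected per-transcript test under a simulated null (1000
replications at 1000 molecules — the count-level fast path, since test
calibration does not depend on the qPCR read-out); and the canonical
profile shapes at a cap-side closed fraction of 0.35 with PAB1-side
co-capture tuned to a 0.06 distal ratio.

## Known limitations

- The index conflates the closed fraction with co-capture efficiency c;
  absolute prevalence statements are lower bounds only, and comparisons
  across factors inherit each factor's own c.
- Efficiency-fit noise propagates multiplicatively through E^ΔCt; with
  short dilution series (4 levels × 3 replicates) this contributes a
  few-percent relative error to indices, visible as a small spread around
  truth in recovery runs.
- With very low counts (weak signals near the Ct ceiling) the index
  distribution is skewed and 3-replicate t-based inference is approximate;
  the QC ceiling `qc.max_ct` exists to keep such groups out.
- Coordinates are transcript-space and strand-agnostic; genomic mapping of
  amplicons is out of scope, as are melt curves, raw fluorescence
  processing and proprietary chip-export formats.
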