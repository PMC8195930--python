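# Methods

## Scope and model

`tcrdyn` analyses peripheral-blood TCR-β repertoires sampled at two
timepoints around the start of an anti-PD-L1 treatment course — a
pre-infusion baseline (C1D1) and day 15, before the second dose (C1D15) —
and asks whether early repertoire dynamics predict overall survival. The
unit of observation is the *clonotype*: a unique nucleotide-level CDR3
rearrangement. Several nucleotide clonotypes may translate to the same
amino-acid CDR3; that redundancy ("convergence") is itself a signal of
antigen-driven selection and is measured separately from diversity.

### Sample retention (QC)

A sample enters the analysis only if it has at least 1,000 unique clones, a
library read depth of at least 800,000 reads, and at least 40% productive
reads. All three comparisons are inclusive (`>=`). The read-depth criterion
is applied to total library reads; when a clonotype table does not carry a
depth field, depth defaults to the sum of read counts over all rows.
Patients with one passing timepoint are kept for baseline-only analyses;
the paired (dynamic) analyses require both.

### Clonality

Diversity at each timepoint is summarised by clonality,

    clonality = 1 − H / ln R,    H = −Σᵢ pᵢ ln pᵢ,

where `pᵢ` are clone frequencies over productive clones and `R` is the
number of unique productive clones. The statistic is 0 for a perfectly even
repertoire and approaches 1 as a single clone dominates; it is invariant to
the logarithm base and to uniform rescaling of counts. It is undefined for
`R ≤ 1` (ln R = 0); callers receive an explicit undefined-metric error
rather than a sentinel value. Frequencies are computed over productive
records only: unproductive rearrangements (CDR3 containing a stop) are kept
in the tables for the productive-fraction QC but never enter a metric.

### TCR convergence frequency (TCF)

TCF is the aggregate frequency of productive clones whose amino-acid CDR3
is exactly shared by at least one other nucleotide-distinct clone. Sharing
is plain string equality of the amino-acid CDR3, with no V/J-gene matching
requirement — the minimal reading of "sharing an amino acid sequence".
Clones with a missing amino-acid sequence are excluded from the grouping.

### Treatment dynamics

Relative clonality `RCL = clonality(C1D15) / clonality(C1D1)` and relative
convergence `RTCF` defined the same way. Ratios of exactly 1 are classified
as "increased" (the grouping rule is `RCL ≥ 1`). A zero baseline makes the
ratio undefined; the patient is then excluded from that grouping with a
recorded reason rather than given an arbitrary value. The dual grouping
labels a patient "dual-increase" iff both RCL ≥ 1 and RTCF ≥ 1.

### Convergence networks

Per patient, both timepoints are pooled into one graph: one node per unique
(amino-acid CDR3, timepoint) pair among productive clones, an edge whenever
the Levenshtein distance between two node sequences is ≤ 1. A sequence
present at both timepoints therefore yields two nodes joined by a
distance-0 edge, matching a display that colours nodes by timepoint.
Convergent groups are the connected components of this graph
(single-linkage transitive closure). The network is summarised by its
diameter: breadth-first search from every node, maximum finite
shortest-path length, maximised over components (unreachable pairs never
contribute; an edgeless graph has diameter 0). The "1 bp difference"
phrasing sometimes used for this construction is interpreted as one
amino-acid edit, since the distance matrix is over amino-acid sequences.

Diameter is reported in *edge* units (the convention of igraph-style
libraries); a `diameter_units: vertices` configuration converts to vertex
counts (edges + 1 on non-empty paths). The downstream median split is
invariant to the choice, which the test suite asserts. Cohorts are
dichotomised at the median diameter with the median itself in the "low"
group (the split is strictly greater-than); an even cohort uses the
midpoint of the two central order statistics.

Edit distances are computed with the banded alignment of `edlib`; the
pairwise search buckets sequences by length (pairs differing in length by
more than the threshold are skipped) and early-abandons beyond the
threshold. The test suite verifies exact equivalence against a dense
dynamic-programming oracle.

### Survival association

Overall survival is time from treatment start to death from any cause;
unreached events are right-censored. Groups are compared with Kaplan–Meier
curves (median = smallest time with survival ≤ 0.5, reported as the literal
token `NR` when never reached) and the log-rank test. Hazard ratios come
from Cox proportional-hazards models fit by partial likelihood
(`statsmodels` PHReg), with Efron tie handling by default (Breslow
available); per-term effects are reported as HR with Wald 95% CI and
p-value, matching the usual table layout. The multivariable model is built
by pure backward elimination from the full covariate set: refit after
removing the single term with the largest Wald p ≥ 0.2, stop when all
remaining terms have p < 0.2; removed terms are recorded in a trace, and an
all-noise model may legitimately end empty. In small cohorts a term can
show monotone likelihood (complete separation); the pipeline drops such a
term with a note and refits rather than abandoning the model, while the
library-level `cox_fit` surfaces the diagnostic error.

RCL enters the univariable analysis two ways, mirroring the dual reporting
convention: as a continuous covariate and as the binary increased-clonality
indicator; both rows are emitted.

The association between clinical covariates and clonality *change* is
modelled as a multivariable binomial-family (logistic) regression of the
increased-clonality indicator on the covariate set, with per-covariate Wald
p-values; constant covariates are dropped with a reason, and complete
separation raises a diagnostic error.

## Synthetic cohort generator

No patient-level data are deposited with the study this design follows, so
the package ships a seeded generator that emulates the data-generating
assumptions the analysis relies on:

* **Clone sizes.** Unnormalised weights `(rank^(−a) · ε)^s` with `a` the
  power-law exponent (default 1.0, a Zipf-like tail typical of
  immunosequencing), `ε` multiplicative log-normal noise (σ = 0.25), and
  `s` a per-sample skew modifier: `s → 0` gives a near-uniform repertoire
  (clonality → 0), larger `s` sharpens it.
* **Convergence.** Each clone re-uses an earlier clone's amino-acid CDR3
  with probability `convergence_rate` (default 0.10) under a fresh
  nucleotide sequence; with probability `near_neighbor_rate` (default
  0.05) it is a one-edit mutation of an earlier sequence, populating
  network edges. Nucleotide variants are fresh random strings rather than
  codon back-translations — clone identity is nucleotide-level, so this is
  sufficient for the convergence semantics.
* **Paired dynamics.** Per patient, a latent shift `δ ~ N(0, 0.35)` scales
  the day-15 skew modifier by `exp(δ)`; the realized RCL (recomputed from
  the generated tables by the same metric code the pipeline uses) tracks δ.
  The default shift mean of 0 encodes the observation that diversity is on
  average similar before and after one dose.
* **Outcome coupling.** Survival is exponential with hazard
  `λ · exp(β · 1[RCL ≥ 1])`, `λ = 0.03/month` (median OS ≈ 23 months for
  the reference group, bracketing the 17–28 month medians typical of this
  setting) and `β = ln 3.32` by default, the univariable effect size of the
  increased-clonality indicator in the motivating cohort. Censoring is
  independent: with probability 0.30 a uniform censor time on
  [0, 36] months, otherwise administrative censoring at 36 months.
* **Cohort shape.** 71 patients, both timepoints each; binary covariates
  drawn at the baseline prevalences of the motivating cohort (male 54.9%,
  age ≥ 65 50.7%, squamous 52.1%, PD-L1 low/negative 29.0%, ECOG 1 63.4%,
  ever-smoker 93.0%, prior line 29.6%, liver metastases 27.5%). Defaults of
  1,100 clones and 10⁶ reads per sample place every default sample above
  the retention thresholds; QC-failing samples are injected explicitly
  (first `n_qc_fail` patients' baselines get `qc_fail_clone_count` clones)
  so filter tests are exact, rather than arising stochastically.
* **Sequences.** Amino-acid CDR3 lengths uniform on 8–20 over the 20
  standard residues; no C…F motif constraint is imposed (metric behaviour
  does not depend on it). 10% of reads are unproductive (CDR3 with a stop),
  spread over ~5% of clones, so the productive-fraction QC path is
  exercised.

Everything derives from one `numpy` `default_rng` seed; re-running with the
same seed reproduces every output file byte-for-byte.

### What the generator does not emulate

V(D)J recombination statistics, codon usage, sequencing error, PCR
amplification bias, HLA-driven public clonotypes, or any correlation
between covariates and repertoire structure beyond the outcome coupling
above. Passing tests therefore demonstrate that the estimators and the
pipeline recover known structure under the stated model — not that the
biological effect sizes would reproduce in new patient data.

## Numerical and design choices

* Frequencies are validated to sum to 1 within 1e-9 after ingestion; exact
  zeros are dropped before entropy evaluation.
* The clonality formula is the standard normalised-entropy definition; its
  two printed endpoints (0 = all clonotypes equally common, 1 = single
  dominant clone) pin the convention.
* Tie handling defaults to Efron (less biased with many ties); Breslow is
  exposed and both agree exactly on tie-free data (asserted in tests).
* Wald (not likelihood-ratio) tests are used per term, matching the
  HR + CI + p table layout.
* Cross-checks are dual-route throughout: `edlib` vs a pure-Python DP
  table, `statsmodels` PHReg vs `lifelines` CoxPHFitter, BFS diameter vs
  dense Floyd–Warshall, TCF vs an exhaustive pair scan, clustering vs
  union-find closure.
* Problem sizes in the test suite: oracle suites use 1000 random string
  pairs, 200 random repertoires for TCF, 100 sequence sets of up to 60
  sequences for the pairwise matrix, graphs of up to 60 nodes for the
  diameter; recovery uses 100 cohorts of 500 patients at 40 clones per
  sample (the survival layer depends on the realized group indicator, not
  on per-sample depth) and 200 null cohorts of 100 patients. The analysis
  drivers simulate 71 patients at 150 clones / 60k reads with
  proportionally scaled QC thresholds; network diameters grow with
  sampling depth, so their absolute values at this scale are smaller than
  at full depth while the high/low split logic is unchanged.

## Known limitations

* TCF uses exact amino-acid equality only; a variant requiring identical V
  genes is a plausible alternative reading and is deliberately not the
  default.
* The undefined cases (single-clone repertoires, zero baseline TCF) are
  excluded rather than imputed; cohorts with many such patients lose power
  in the corresponding groupings.
* Backward elimination explores a single removal path (no re-entry); with
  correlated covariates the retained set is order-dependent in edge cases.
* The generator attaches hazard to the RCL group only; TCF and diameter
  groupings carry no built-in effect, so their survival splits in synthetic
  data are null checks, not effect reproductions.
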