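# tcrdyn

Peripheral TCR-β repertoire dynamics and survival association for
paired-timepoint immunotherapy cohorts.

Checkpoint-inhibitor response is hard to predict from static biomarkers.
One candidate readout is how the circulating T-cell receptor repertoire
*changes* over the first treatment cycle: whether it narrows onto few
clones, whether nucleotide-distinct clones converge onto shared amino-acid
CDR3 sequences, and how richly connected the repertoire's sequence-
similarity network is. `tcrdyn` implements that analysis end to end for
translational researchers working with bulk TCR-β clonotype tables
(AIRR rearrangement TSV or a simple CSV dialect) sampled at a pre-infusion
baseline (C1D1) and day 15 (C1D15):

1. **QC** — retain samples with ≥ 1,000 unique clones, ≥ 800,000 reads and
   ≥ 40% productive reads;
2. **Metrics** — clonality `1 − H/ln R` (normalised Shannon entropy over
   productive clone frequencies; 0 = perfectly even, 1 = single dominant
   clone) and TCR convergence frequency (TCF): the aggregate frequency of
   clones sharing an amino-acid CDR3 with another nucleotide-distinct
   clone;
3. **Dynamics** — per-patient ratios RCL = clonality(C1D15)/clonality(C1D1)
   and RTCF, dichotomised at 1 (ratio = 1 counts as increased), plus the
   dual-increase grouping;
4. **Networks** — per-patient graphs over amino-acid CDR3s (both
   timepoints pooled) with edges at Levenshtein distance ≤ 1; convergent
   groups are connected components; each network is summarised by its
   BFS diameter and cohorts split at the median diameter;
5. **Survival** — Kaplan–Meier curves and medians, log-rank tests,
   univariable and backward-selected multivariable Cox proportional-
   hazards models (Efron or Breslow ties; retain terms with p < 0.2), and
   a logistic model linking clinical covariates to clonality change.

Because studies of this kind rarely deposit sequence-level data, the
package includes a first-class synthetic-cohort generator
(`tcrdyn.simulate`) with power-law clone sizes, controlled convergence,
latent clonality shifts and survival coupled to the realized RCL group —
every pipeline stage is testable, seeded and reproducible without any
external data.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
71-patient cohort (150 clones / 60k reads per sample, proportionally
scaled QC, three QC failures injected) and write their tables under
`results/`:

```
python analysis/01_simulate.py
python analysis/02_qc_and_metrics.py
python analysis/03_networks.py
python analysis/04_survival.py
```

Output of `02` and `04` (seed 20251002):

```
142 samples read; 139 passed QC, 3 excluded
68 of 71 patients have both timepoints after QC
median baseline clonality: 0.2060
median TCF:                0.2824
patients with increased clonality (RCL >= 1): 35 / 68

univariable Cox, increased_clonality: HR 2.25 [1.28, 3.94], p = 0.005
multivariable model retains 4 terms (backward elimination, p < 0.2):
  ...
  increased_clonality: HR 2.29 [1.26, 4.17], p = 0.007
```

Reading: the three constructed low-complexity samples are the exact QC
exclusions; patients whose clonality rose after one dose (RCL ≥ 1) die at
about 2.3 times the hazard of those whose repertoire diversified — the
effect built into the generator (the simulation truth attaches an elevated
hazard to the increased-clonality group), recovered here from the written
clonotype tables through the full QC → metrics → survival path.

The same pipeline runs from the shell:

```
tcrdyn simulate --seed 7 --n-patients 20 --out cohort/
tcrdyn run --seed 7 --out report/          # simulate-mode pipeline
tcrdyn metrics  --input-dir cohort/ --out out/   # stage-wise entry points
tcrdyn network  --input-dir cohort/ --out out/
tcrdyn survival --input-dir cohort/ --out out/
```

or from Python:

```python
from tcrdyn import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=7))
print(report.km_summaries)        # median OS per grouping, log-rank p
print(report.cox_table)           # univariable + multivariable HR/CI/p
```

## Layout

```
src/tcrdyn/        library: io, metrics, network, survival, simulate,
                   pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, oracle and acceptance)
scripts/           acceptance script
docs/methods.md    model, assumptions, parameter choices, limitations
```
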