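# clockscreen

Analysis pipeline for circadian luciferase-reporter screens in plants:
per-seedling rhythm estimation by FFT-seeded nonlinear least squares
(FFT-NLLS), control-normalized screen statistics with batch-level quality
control, histogram-based subpopulation detection, Welch/Bonferroni hit
calling with effect classification, and comparative-C<sub>T</sub> (2^−ΔΔCT)
quantification of clock-gene qPCR time courses. A synthetic-data generator
emulates the whole study design with known ground truth, so every stage is
testable without raw imaging data.

## The problem

Genetic screens that monitor a clock reporter (e.g. *CCA1p::Luciferase*)
image hundreds of seedlings hourly for days under constant light, then ask
which transgenic populations alter clock **period**, **phase**, or
**rhythmicity**. Each population of independent T1 insertion lines is
heterogeneous, so a screen must handle batch effects between imaging runs,
arrhythmic individuals, and populations that split into phenotypically
distinct subpopulations.

## Models and statistics

**Rhythm estimation.** A detrended trace is modelled as a sum of cosines,

x(t) = b₀ + b₁t + Σₖ aₖ cos(2π(t − φₖ)/τₖ),

with components seeded from successive periodogram peaks and all parameters
refit jointly by nonlinear least squares. Component addition stops when the
newest amplitude's joint confidence region (Scheffé-scaled linearized
covariance, 95%) includes zero. The circadian component is the one with
period in a configurable window (default 15–35 h) and the lowest **relative
amplitude error**, RAE = amplitude confidence half-width / amplitude ∈ [0, 1].
RAE > 0.6 (strict) marks a seedling arrhythmic.

**Screen statistics.** An imaging batch passes QC only if its concurrent
control population's period SD is below 0.75 h (strict). Within passing
batches each plant's metric is normalized by subtracting the concurrent
control mean. Each decoy population (or detected subpopulation) is compared
to a control pool — normalized wildtype plants for period, the full set of
normalized decoy plants for phase — with a two-sided Welch's t-test at a
Bonferroni-corrected level α/m (m = populations in the family). Significant
hits are *minor* or *major* by |mean difference| (1 h for period, 2 h for
phase).

**Subpopulations.** Normalized period values are binned (default 0.5 h);
histogram peaks keep their seedlings between flanking troughs and are
discarded when they hold fewer than 3 seedlings, sit only one bin from
another peak, or rise fewer than 3 counts above their higher flanking
trough. Two or more surviving peaks split the population at the troughs.

**qPCR.** Relative expression is 2^−ΔΔCT with ΔCT = CT(target) −
CT(reference gene) and the reference point at each replicate's first
expression peak. Genotype phase differences are compared replicate-wise
(Welch, Bonferroni-corrected; circular, reported as the signed difference of
minimal magnitude modulo the fitted period).

## Worked example

Simulate one imaging experiment with a concurrent 20-plant control, a
60-plant population that hides a long-period subpopulation, a uniformly
long-period population, and a null population — then run the full pipeline:

```python
import clockscreen as cs

design = cs.ScreenDesign(experiments=[
    cs.ExperimentSpec("E1", populations=(
        cs.PopulationSpec("ACF5-like", n=60, mixture=(
            cs.MixtureComponent(fraction=11/12, period_effect=0.4),
            cs.MixtureComponent(fraction=1/12, period_effect=2.8),
        )),
        cs.PopulationSpec("long-period", n=20, period_effect=1.5),
        cs.PopulationSpec("null", n=20),
    )),
])
sim = cs.simulate_screen(design, seed=7, traces=True)
traces = sim.traces.merge(sim.layout[["plant_id", "is_control"]], on="plant_id")
result = cs.run_full_screen(cs.RunConfig(), traces=traces)
print(result.hits.loc[result.hits.metric == "period"])
```

Output (period hits):

```
population_id subpop_index  n  mean_diff  p_value  significant effect_class
    ACF5-like         <NA> 60       0.76 1.39e-08         True        minor
    ACF5-like            0 55       0.55 1.45e-07         True        minor
    ACF5-like            1  5       3.13 1.68e-10         True        major
  long-period         <NA> 20       1.69 4.93e-15         True        major
         null         <NA> 20       0.03 8.31e-01        False         none
```

Reading it: the whole `ACF5-like` population looks like a 0.76 h *minor*
lengthening, but the histogram detector splits it into a 55-plant minor
group (+0.55 h) and a 5-plant *major* subpopulation (+3.1 h) — the pattern
that whole-population averaging would blur. The planted +1.5 h population is
called major; the null population is clean. `result.manifest` records the
configuration and every filter count (120 plants in, 120 fit, 1 of 1 batch
passing QC, 1 multimodal population, 2 subpopulations tested).

The same flow is available from the shell:

```bash
clockscreen simulate --design design.yaml --seed 7 --out traces.csv --layout layout.csv
clockscreen run --traces traces.csv --layout layout.csv --outdir results/
```

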