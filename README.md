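# endonet

Whole-brain functional-connectivity **endophenotype** analysis for
three-group (affected / unaffected-sibling / control) neuroimaging designs,
with a built-in synthetic-cohort generator so that the entire pipeline is
testable without scan data.

An endophenotype is a heritable, quantifiable marker found both in affected
individuals and in their unaffected genetic relatives. For whole-brain
functional connectivity the operational question is: does a network metric
differ across matched groups of autistic adolescents (ASC), unaffected
siblings (SIB), and typically-developing controls (CON), with siblings
intermediate? `endonet` implements the full analysis chain needed to answer
it:

1. **Preprocessing** — expansion of an 8-column nuisance basis (6 rigid-body
   realignment parameters + mean CSF and white-matter signals) to 32
   regressors (base, backward-difference derivatives, squares of both), OLS
   confound regression, optional running-median despiking, and an ideal
   0.01 Hz high-pass / optional 0.1 Hz low-pass DFT filter.
2. **Connectivity** — Pearson correlation between the time series of the
   258 analysis nodes of a 264-region, 14-network parcellation, followed by
   *proportional thresholding*: only the strongest 20% of connection weights
   (round(0.2 · 258·257/2) = 6631 edges) is retained per subject.
3. **Graph metrics** — node strength `s_i = Σ_j w_ij`; Onnela weighted
   clustering `C`; global efficiency `E = ⟨1/d_ij⟩` with edge lengths
   `1/w`; both normalized by their mean over 100 random networks preserving
   size, density, degree sequence and (approximately) strength sequence.
4. **Node disruption index (NDI)** — the slope of the regression of
   `(s_i^subject − s̄_i^CON)` on the control-template strengths `s̄_i^CON`;
   0 means a typical strength topography.
5. **Hub topography** — the 20% highest-strength nodes, tallied across the
   9 analysed functional networks, plus intra-/inter-network block weights.
6. **Motion QC** — framewise displacement
   `FD_t = Σ|Δtrans| + 50 mm · Σ|Δrot|`, per-edge FC–motion correlations,
   their distance-ordered moving average, the fitted distance slope
   (reported per metre), and 100-permutation empirical p-values.
7. **Group statistics** — one-way ANOVA (from raw data *or* from printed
   group means/SDs/sizes), planned pooled-variance t-tests, cross-condition
   correlations, and a rule-based endophenotype pattern classifier.

The synthetic cohort follows a band-limited (0.01–0.1 Hz) factor model
`x_it = g·h_i·F_t + w·G_t^net(i) + c·U_t + ε_it` whose single knob `g`
(global coupling, graded CON > SIB > ASC) produces the hypoconnectivity
gradient, with optional distance-decaying motion artifacts tied to the
simulated realignment traces.

## Worked example

```python
import numpy as np
from endonet import (CohortDesign, correlation_matrix, endophenotype_pattern,
                     generate_cohort, load_default_parcellation,
                     mean_connectivity, proportional_threshold)
from endonet.preprocess import FilterSpec, preprocess_timeseries

parc = load_default_parcellation()          # 258 analysis nodes, 14 networks
cohort = generate_cohort(parc, CohortDesign(seed=42))   # 3 groups x 14 subjects

by_group = {g: [] for g in ("CON", "SIB", "ASC")}
for sub in cohort:
    confounds = np.hstack([sub.realignment, sub.truth["confounds"]])
    clean = preprocess_timeseries(sub.timeseries, confounds, FilterSpec())
    net = proportional_threshold(correlation_matrix(clean), density=0.2)
    by_group[sub.group].append(mean_connectivity(net))

pattern = endophenotype_pattern({g: np.array(v) for g, v in by_group.items()})
for g, v in by_group.items():
    print(f"{g}: mean FC = {np.mean(v):.3f} (sd {np.std(v, ddof=1):.3f})")
print(f"ANOVA F({pattern.anova.df_between}, {pattern.anova.df_within}) = "
      f"{pattern.anova.F:.2f}, p = {pattern.anova.p:.2g}")
print("pattern:", pattern.label)
```

prints

```
CON: mean FC = 0.670 (sd 0.013)
SIB: mean FC = 0.555 (sd 0.014)
ASC: mean FC = 0.418 (sd 0.010)
ANOVA F(2, 39) = 1470.16, p = 1.9e-37
pattern: endophenotype
```

Mean retained-edge connectivity is highest in controls, intermediate in
siblings and lowest in the ASC group; the ANOVA over the three groups is
significant, the ordering is monotone, and the planned ASC-vs-CON
comparison is significant, so the classifier labels the metric an
endophenotype.

The same analysis is available from the shell:

```sh
endonet run -c config.yaml --seed 42 -o out/      # all stages, JSON report
endonet simulate -c config.yaml -o out/           # cohort TSVs only
```

with `simulate / preprocess / connect / metrics / qc / stats` subcommands
for individual stages.

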