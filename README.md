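# tnegsig

Prognostic gene-signature discovery and multigene-index evaluation for
node-negative, adjuvant-naive hormone receptor-negative (HRneg) and
triple-negative (Tneg) breast cancer.

Early-stage HRneg/Tneg breast cancers are aggressive as a class, yet
most conservatively managed patients never relapse — and the
commercial multigene predictors, built around proliferation modules,
carry no prognostic information in this subtype. `tnegsig` implements,
as a tested and reusable pipeline, the discovery protocol for
signatures that do stratify these patients: multi-source microarray
preprocessing and batch merging, a two-pronged candidate screen
(per-source nearest-shrunken-centroid ranking plus a Monte-Carlo
cross-validation Cox screen), Cox sign-consistency filtering with
hold-out confirmation, a sign-corrected composite expression index,
cut-point optimisation, stepwise gene prioritisation, and head-to-head
comparison of multiple signatures on a common cohort. A synthetic
cohort generator with known ground truth (batch-shifted multi-source
log2 expression, proportional-hazards DMFS outcomes, an ERBB2-like
bimodal gene for HER2 stratification) makes every stage testable
without external downloads.

The package is aimed at biostatisticians and computational biologists
who want to reproduce, stress-test or extend this class of survival
screening protocol.

## The core statistic

Candidate genes enter a signature with a hazard direction: set `P`
(expression positively associated with hazard) or set `N`
(protective). The per-sample composite index is the sign-corrected,
unweighted mean of the merged, batch-adjusted log2 expression,

    index = ( Σ_{i∈P} x_i − Σ_{j∈N} x_j ) / n ,

where `n` counts the signature genes actually present in the cohort.
Higher index ⇒ worse predicted prognosis. Cohorts are dichotomised at
the median or the upper third quartile of the index (high group =
index ≥ cut) and the split is assessed by the log-rank test and the
Cox hazard ratio of the group indicator. Screening-scale univariate
Cox fits use an in-package Newton solver vectorised across thousands
of genes (Efron or Breslow ties), cross-checked against lifelines.

The published 14-gene HRneg/Tneg signature (union of an 11-gene HRneg
list and a 7-gene Tneg list sharing 4 genes; 12 protective genes and 2
hazard-increasing, RGS4 and HAPLN1) ships as packaged signature files,
along with its component lists.

## Worked example

Discover a signature on a simulated 2,000-gene, 199-sample,
three-source cohort with ten planted prognostic genes, then evaluate
its index at the upper-third-quartile cut:

```python
import tnegsig as t

params = t.SimulationParams(n_genes=2000, n_prognostic=10,
                            effect_magnitude=0.8, seed=7)
cohort, truth = t.simulate_cohort(params)
cohort = t.assign_her2_status(cohort, t.ERBB2_FEATURE)
result = t.discover(cohort, {"discovery": ["S1", "S2"], "holdout": ["S3"]},
                    mccv_config=t.MCCVConfig(seed=7))

merged = t.merge_cohorts(
    [t.mean_center_within_source(cohort.subset_samples(cohort.source_mask(s)))
     for s in cohort.sources],
    strategy="dwd_lite",
)
idx = t.compute_index(merged, result.combined_signature)
groups, cp = t.dichotomize(idx, merged.times, merged.events, percentile=75)
print(f"Q3 cut {cp.cut_value:.3f}: {cp.n_high} high / {cp.n_low} low, "
      f"HR {cp.hr_high_vs_low:.2f} (95% CI {cp.hr_ci95[0]:.2f}-{cp.hr_ci95[1]:.2f}), "
      f"log-rank P {cp.logrank_p:.2e}")
opt = t.optimize_cutpoint(idx, merged.times, merged.events)
print(f"optimal cut at the {opt.percentile:.1f}th percentile, "
      f"log-rank P {opt.logrank_p:.2e}")
```

Output:

```
Q3 cut 0.203: 49 high / 150 low, HR 6.65 (95% CI 4.30-10.28), log-rank P 1.93e-22
optimal cut at the 74.9th percentile, log-rank P 7.69e-21
```

Reading this: the upper-third-quartile cut assigns 150 of 199 patients
(75%) to the good-prognosis group; the remaining quarter carries a
6.7-fold hazard of distant metastasis, and the unconstrained log-rank
search over the 20th–80th percentile band lands at the 75th percentile
— the Q3 cut is empirically near-optimal on this cohort, as it is in
the clinical setting the simulation emulates. The discovered signature
here recovers 5 of the 10 planted genes, plus screen-level false
positives; see `docs/methods.md` for the screens' operating
characteristics and their limits.

The same run is available from the shell:

```sh
tnegsig run --seed 7 --out demo_run --config config.yaml
tnegsig report --out demo_run
```

where `config.yaml` holds the stage blocks (`simulate:`, `discover:`,
`index:`, `compare:`); every artifact is TSV/JSON, and the run closes
with a manifest of config hash and per-artifact checksums that is
reproducible given the seed.

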