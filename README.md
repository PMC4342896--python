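# myoarray

Reverse-phase protein microarray (RPMA) analysis of energy-metabolism
biomarkers in neuromuscular disease cohorts.

`myoarray` implements the full quantification-to-diagnosis workflow for a
19-protein muscle-biopsy panel (glycolysis, glycogenolysis, fatty-acid
oxidation, Krebs cycle, respiratory chain, oxidative phosphorylation) and
its three derived bioenergetic ratios (bF1/GAPDH, BEC index, bF1/LDHA):

* **Synthetic cohorts** drawn from group-level mean ± SEM summaries with a
  moment-matched truncated-normal generator, plus raw **spot-level array
  simulation** (quadruplicate spots, serial-dilution standards, blanks,
  multiplicative technical noise).
* **Quantification**: blank-based background, replicate aggregation with
  percent-CV (SCV) tracking, OLS standard curves, calibration.
* **Normalization & signatures**: fold of control, log2-relative
  transform, per-sample bioenergetic ratios.
* **Statistics**: pooled t, one-way ANOVA, and Dunnett many-to-one
  comparisons via Monte-Carlo integration of the correlated max|T| null —
  exact under unbalanced group sizes.
* **Clustering**: from-scratch Euclidean/WPGMA agglomerative linkage
  (UPGMA optional), tree cutting, majority-vote cluster-to-class scoring,
  Newick export.
* **Interval-rule classifier**: closed-interval rules on bF1/LDHA plus one
  disease-specific marker, with both sensitivity conventions reported
  (TP/(TP+FP) and recall TP/(TP+FN)).

## Quick start

```python
from myoarray import (
    default_cohort_spec, simulate_cohort, clustering_experiment,
)

# one synthetic cohort from the packaged nine-group summaries (73 biopsies)
cohort = default_cohort_spec(seed=42).subset(["CTR", "ComplexI", "GlycV"])
expr = simulate_cohort(cohort)
print(expr.data[["NADHs9", "PYGM", "GAPDH"]].groupby(expr.classes).mean())
```

```text
             NADHs9  PYGM  GAPDH
class_label
CTR            0.87  1.10   0.82
ComplexI       1.53  1.46   0.85
GlycV          1.18  0.00   0.72
```

Replicate the published three-group clustering evaluation (controls vs
Complex I deficiency vs McArdle disease, WPGMA at k=3 on log2-relative
NADHs9 / PYGM / bF1-GAPDH) over 200 simulated cohorts:

```python
means = clustering_experiment("mito_glycv", n_replicates=200, seed=0)
print(round(means["sensitivity_GlycV"], 1),    # 100.0
      round(means["precision_ComplexI"], 1),   # 89.7
      round(means["specificity_control"], 1))  # 96.3
```

The complete pipeline — simulate, spot, quantify, normalize, test,
cluster, classify — runs in one call (or `myoarray run`):

```python
from myoarray.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(outdir="out", seed=17))
print(report["stages"]["quantify"]["array_mean_scv_percent"])  # ~7.9
```

Every intermediate lands as CSV in `out/`, the dendrograms as Newick, and
`report.json` embeds the seeds and a config hash so identical
configurations reproduce identical reports.

## Command line

```bash
myoarray simulate-cohort --seed 1 --out cohort.csv
myoarray simulate-array  --expr cohort.csv --cv 8.6 --out spots.csv
myoarray quantify        --spots spots.csv --out calibrated.csv
myoarray signatures      --expr calibrated.csv --control-label CTR --out sig.csv
myoarray stats           --expr sig.csv --control-label CTR --out stats.csv
myoarray cluster         --expr sig.csv --markers NADHs9,PYGM,bF1_GAPDH \
                         --control-label CTR --k 3 --out perf.json
myoarray classify        --expr sig.csv --target DMD --out dmd.json
myoarray run             --seed 17 --outdir out
```

## Repository layout

* `src/myoarray/` — the library (`simulate`, `quantify`, `signatures`,
  `stats`, `cluster`, `classify`, `experiments`, `pipeline`, `cli`);
  packaged cohort summaries and interval rules under `data/`.
* `examples/` — five narrative scripts, one per capability; each runs
  standalone in seconds.
* `docs/methods.md` — the statistical model, generator design,
  conventions, and known limitations of the replication experiments.
* `tests/` — unit, property-based (hypothesis), and acceptance tests;
  `scripts/acceptance.py --seed 1 --out results/acceptance.json` computes
  the headline replication numbers from scratch.

## Testing

```bash
python -m pytest            # full suite, a few minutes on one CPU
```

Two acceptance tests fail by design: under the documented simulation
conditions (per-sample SD reconstructed as SEM·√n from the group
summaries) the dystrophies-vs-controls clustering does not reach the
published pooled sensitivity/specificity. The computation is kept faithful
rather than tuned; `docs/methods.md` analyzes the discrepancy.
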