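# sparseqtl

Sparse Bayesian multi-locus eQTL mapping for small inbred panels, single-
or multi-tissue, with an Evolutionary Stochastic Search sampler.

## The problem

In a recombinant inbred panel (~29 fully inbred strains derived from two
founders), a transcript's expression is measured in one or several tissues
and every strain is genotyped at hundreds of markers. Which small set of
markers jointly controls the transcript? Single-marker scans answer a
different question (is *this* marker associated, marginally?) and struggle
when a strong cis effect masks a weak trans effect, or when a weak effect
is shared across tissues. This package fits a sparse Bayesian
(multi-)regression over all markers at once:

* a matrix-variate g-prior links effects across tissues and integrates out
  analytically, leaving an exact score per marker subset;
* a Beta-Binomial prior on model size enforces sparsity and makes the null
  model the preferred explanation of pure noise at realistic marker counts;
* a population of parallel-tempered chains (with crossover and exchange
  moves) searches model space, and every reported probability is computed
  from the exact renormalised posterior over the visited models;
* Bayes-factor declaration thresholds are calibrated to a target false
  discovery rate by refitting strain-reshuffled null panels;
* post-processing collapses linked markers, labels control points cis or
  trans, and draws exact conditional posteriors of per-tissue effect sizes
  and of the residual cross-tissue correlation.

Classical comparators (multivariate Hotelling T² scan, univariate
permutation scan, two-stage sequential search, Storey q-values) and a
recombinant-inbred simulator with five pleiotropy scenarios are included.

## Worked example

Simulate a 29-strain panel on the default 780-marker map with one strong
cis effect (1.5 residual sd) and one weak trans effect (0.5 residual sd)
shared across 4 tissues, then map the probe:

```python
import numpy as np
from sparseqtl import SparseBayesianEQTL
from sparseqtl import simulate as sim

mm = sim.default_marker_map()                       # 20 chr x 39 markers
X = sim.simulate_ri_genotypes(29, mm, rng=7)
panel, truth = sim.simulate_expression(X, sim.ScenarioSpec("B", "strong"), rng=7)
print([(mm.names[j], e) for j, e in zip(truth["planted"], truth["effects"])])
# [('c18m35', 1.5), ('c13m23', 0.5)]

est = SparseBayesianEQTL(n_chains=2, n_sweeps=2500, burn_in=500, random_state=0)
est.fit(X.codes, panel.values)

print([mm.names[j] for j in est.best_model_.included])
# ['c18m35']
top = np.argsort(est.mppi_)[::-1][:3]
print([(mm.names[j], round(float(est.mppi_[j]), 3)) for j in top])
# [('c18m36', 0.548), ('c18m35', 0.451), ('c13m25', 0.062)]
print(round(est.log10_bf_best_vs_null_, 2))
# 6.38
print(np.round(est.coef_[list(est.best_model_.included)], 2))
# [[3.06 3.12 2.77 2.94]]
```

The cis locus is recovered exactly (log10 Bayes factor 6.38 against the
null), with its posterior inclusion mass split between the planted marker
`c18m35` and its 2.5 cM neighbour `c18m36` — tight linkage at n = 29 makes
adjacent markers nearly interchangeable, which is why post-processing
collapses markers within 5 cM into one control point. The fitted
per-tissue coefficients (≈ 3.0) match the generating value: a 1.5-sd
standardized effect corresponds to a coefficient of 2 × 1.5 under the
±0.5 genotype coding. The weak trans effect surfaces only as a small
bump (`c13m25`, MPPI 0.062): a 0.5-sd shared effect does not carry enough
evidence to pay the sparsity prior's multiplicity cost at 780 markers —
see `docs/methods.md` for why strong cross-tissue residual correlation
makes this *harder*, not easier.

The same pipeline is scriptable end to end:

```bash
sparseqtl --seed 7 simulate --scenario B --n-probes 10 --out-dir data/
sparseqtl --seed 7 run --mode sbmr --bf-cutoff 2 \
    --genotypes data/genotypes.tsv --marker-map data/marker_map.tsv \
    --expression t1=data/expression_tissue1.tsv \
    --expression t2=data/expression_tissue2.tsv \
    --expression t3=data/expression_tissue3.tsv \
    --expression t4=data/expression_tissue4.tsv \
    --out results.tsv
```

Identical command lines give byte-identical outputs; every output file
carries a provenance header with the command, seed and config hash.

## Layout

| module | contents |
| --- | --- |
| `sparseqtl.model` | integrated matrix-variate score, priors, exact enumeration |
| `sparseqtl.sampler` | tempered-population search (`run_ess`), visited-model trace |
| `sparseqtl.summaries` | MPPI, Bayes factors, FDR-calibrated thresholds |
| `sparseqtl.postprocess` | marker collapsing, cis/trans labels, effect-size posteriors |
| `sparseqtl.baselines` | Hotelling T², marginal scan, two-stage search, Storey q-values |
| `sparseqtl.simulate` | RI genotype/expression simulator, ROC utilities, imputation |
| `sparseqtl.io` / `sparseqtl.cli` | TSV dialects, run configuration, `sparseqtl` CLI |
| `sparseqtl.estimators` | scikit-learn style `SparseBayesianEQTL` facade |

## Reproduction

```bash
pip install --no-build-isolation -e .
python -m pytest -q tests/                      # full suite incl. acceptance
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`scripts/acceptance.py` runs the principal computations at reduced scale
(sampler-vs-enumeration agreement, null FDR calibration, scenario
recovery, ROC comparison, comparator checks) and writes the headline
quantities as JSON; all randomness derives from `--seed`.

The acceptance tests in `tests/test_acceptance.py` encode the release
criteria at fixed tolerances. Two documented findings are expected to
fail there by design honesty rather than be weakened: with the default
generator settings the weak (0.5 sd) trans effect is not recovered by the
sparse best model more often than by the two-stage scan, and on the
no-cis weak-correlation scenario the full-curve ranking AUC of the
Bayesian model trails the unpenalised Hotelling scan by under 0.01.
`docs/methods.md` ("Known limitations") gives the quantitative analysis.
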