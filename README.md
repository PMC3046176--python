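# gmdrpower

Detection of gene–gene interactions in case-control studies with
**MDR** (multifactor dimensionality reduction) and **GMDR** (its
score-based generalization with covariate adjustment), plus the analytic
and simulation machinery needed to *design* such studies: theoretical
classification accuracy, heritability, permutation significance
thresholds, and Monte-Carlo power.

## What it does

* **Analysis** — exhaustive cross-validated *k*-locus MDR/GMDR search on a
  case-control dataset. Multilocus genotype cells are pooled into
  high-/low-risk groups by the sign of their average residual score
  (`y − π̂` from a covariate-only null logistic model); model choice uses
  testing accuracy (TA) and cross-validation consistency (CVC) with a
  parsimony rule across interaction orders. Without covariates the score
  engine reduces exactly to classic count-based MDR.
* **Theory** — closed-form conditional genotype distributions for
  logistic penetrance models (two-locus checkerboard, trigenic 3ULM,
  tetragenic 4ULM) under HWE/LE priors, the implied theoretical
  classification accuracy with and without covariate adjustment
  (Gauss–Hermite quadrature over a normal covariate), prevalence, and
  variance-explained (Culverhouse-style) heritability.
* **Simulation & power** — balanced case-control simulator by rejection
  sampling from the generative law; permutation-based 5% TA thresholds
  (score shuffling for GMDR, phenotype shuffling for MDR); Monte-Carlo
  power as the fraction of replicates in which the *true* functional
  locus set is selected and clears the threshold.

## Quick start (CLI)

Simulate a strong two-locus interaction and analyze it:

```console
$ gmdr simulate --model checkerboard --maf 0.5 --beta-g 2.5 --n 2000 --seed 7 --out example.txt
wrote example.txt (n=2000, population prevalence ~0.1432)

$ gmdr analyze --input example.txt --orders 1,2 --seed 0
order	model	mean_TA	CVC	fold_TAs
1	2	0.4724	6	0.4281,0.4501,0.4700,0.5024,...
2*	1,2	0.7781	10	0.7916,0.7279,0.7510,0.8052,...
```

The starred row is the selected order; the planted pair (markers 1,2)
is recovered in all 10 folds. Theoretical quantities for the same
scenario:

```console
$ gmdr accuracy --model checkerboard --maf 0.5 --beta-g 2.5
accuracy	sensitivity	specificity	balanced_accuracy	K	h2
0.647	0.751	0.543	0.647	0.147	0.043

$ gmdr accuracy --model checkerboard --maf 0.5 --beta-g 2.5 --adjust
accuracy	sensitivity	specificity	balanced_accuracy	K	h2
0.746	0.865	0.627	0.746	0.147	0.043
```

Power for a scenario (threshold from 1000 permutations of one dataset):

```console
$ gmdr power --model checkerboard --maf 0.5 --beta-g 1.5 --n 2000 \
      --replicates 100 --permutations 1000 --seed 2024
```

`--cov-sd auto` (the default) calibrates the covariate SD so the
covariate-integrated group penetrances of the reference configuration
match 0.073/0.221.

## Quick start (Python)

```python
from gmdrpower import ScenarioSpec, simulate_case_control, analyze_dataset

spec = ScenarioSpec("checkerboard", maf=0.5, beta_g=2.5,
                    covariate_sd=3.18, n_total=2000, seed=7)
sim = simulate_case_control(spec)
res = analyze_dataset(sim.dataset, method="gmdr", orders=(1, 2))
print(res.final_model, res.final_mean_ta)   # (0, 1) ~0.78
```

## Testing and reproduction

```bash
python -m pytest -q tests/                  # full suite, ~30 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline quantities (theoretical
accuracy table, heritability, adjusted-score accuracy, scaled-down power
and calibration runs, accuracy–heritability correlation) and writes them
as JSON. Methodological details, parameter defaults, and known
limitations are documented in [docs/methods.md](docs/methods.md).

## Layout

```
src/gmdrpower/
  data_io.py     dataset / scenario I-O (tab format, PLINK-style ped/map, YAML)
  scoring.py     null logistic model and residual scores
  mdr_engine.py  CV partitioning, cell tables, exhaustive vectorized search
  analytic.py    priors, penetrance models, theoretical accuracy, heritability
  simulator.py   balanced case-control rejection sampler, permutation nulls
  power.py       permutation thresholds, Monte-Carlo power, scenario grids
  cli.py         `gmdr` command group
```
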