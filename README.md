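# qsarpt

QSAR modelling of human placental transfer of bisphenols from molecular and
chromatographic peak-shape descriptors.

## The problem

Bisphenol A substitutes (BPS, BPAF, BPFL, ...) differ widely in how
efficiently they cross the human placenta, even though their structures are
similar.  The transfer efficiency of compound *i* is summarised by its
**clearance index** CI — the ex vivo placental transfer rate divided by the
transfer rate of the freely diffusing reference antipyrine in the same
perfusion — measured in replicate on several placentae.  Because classical
in-silico descriptors (LogP, polar surface area, orbital energies, ...)
barely contrast within this family, chromatographic behaviour is used as an
experimental descriptor set instead: each compound is run on a panel of 13
reversed-phase columns with two organic modifiers (acetonitrile, methanol),
and four quantities are read off each chromatogram — retention relative to
BPA, k′ = (tr − tr_ref)/tr_ref; full peak width at 5 % height; asymmetry
b/a at 4.4 % height; and tailing factor (a + b)/(2a) at 5 % height — giving
13 × 2 × 4 = 104 chromatographic slots next to 50 molecular ones.

The modelling pipeline is:

1. **Autoscale** descriptors (centre, unit SD).
2. **Importance-weight** them with a sigmoid-output network trained by
   backpropagation on min-max-rescaled CI; keep descriptors whose mean
   absolute input weight exceeds **twice the median** of all weights.
3. **Enumerate uncorrelated combinations**: recursively split every pair
   with pairwise R² > 0.5, which yields the maximal independent sets of the
   correlation graph.
4. **Weighted multilinear regression** of CI on each combination
   (weights 1, 1/Y or 1/Y²), pruning non-significant descriptors (p ≥ 0.05,
   switching to stepwise-AIC when many are non-significant), filtering on
   R² > 0.7 and ranking by BIC.
5. **Validate** with three leave-many-out (LMO) data sets (11 training / 4
   test compounds, 55/20 observations, high-leverage compounds pinned to
   training), reporting R², RMSEC, leave-one-compound-out Q², RMSECV,
   QLMO² = 1 − (PRESS/n_EXT)/(SS_tr/n_TR), RMSEP, Lin's concordance
   coefficient CCC and Pearson²/Spearman², with verdicts against
   R² > 0.65, Q² > 0.5, QLMO² > 0.65, CCC > 0.85.

The published final models are shipped as fixtures, e.g. the
chromatography-only model
`CI = 0.48 − 0.66·T3A2 − 0.05·PFPA7 + 0.07·CC18A7 − 0.50·C8M7 − 0.14·PFPM7 + 0.38·CNM8`
(scaled descriptor space, 1/Y weighting), together with the per-compound
CI summary and the published train/test allocations.

Because the individual replicate CI values behind the original study are
unpublished, everything is exercised end-to-end on **synthetic studies**: a
generator produces exponentially-modified-Gaussian chromatograms per
compound and condition, measures them with the same peak code, and plants a
linear model in scaled descriptor space with Gaussian replicate noise.

## Worked example

```python
import qsarpt as q
from qsarpt.pipeline import PipelineConfig, run_pipeline

bundle = q.paperlike_study(seed=1)          # 15 compounds x 5 replicates
res = run_pipeline(PipelineConfig(mode="chromatographic", seed=1), bundle=bundle)
print(res.final_model.codes)
for line in res.report.verdict_strings().values():
    print(line)
```

prints (seed 1):

```
('CC18A7', 'CNM7', 'FBA2', 'FPA7')
r2=0.807 passes >0.65
q2=-0.426 fails >0.5
qlmo2=0.757 passes >0.65
ccc=0.829 fails >0.85
```

Read: the four-descriptor model refit on the three training sets explains
~81 % of the CI variance (R² 0.807) and predicts the held-out test
compounds reasonably (QLMO² 0.757), but leave-one-compound-out
cross-validation collapses (Q² −0.426) and the concordance with the
identity line misses its criterion (CCC 0.829 < 0.85) — the selection
stage, given only 15 compounds against 104 candidate descriptors, has kept
chance-correlated descriptors whose coefficients are unstable when a
compound is withheld.  This instability is a real property of the procedure
at this sample size; see `docs/methods.md`.

The same run from a shell:

```bash
qsarpt simulate --seed 1 --out study/
qsarpt run --config config.yaml          # paths + options in YAML
qsarpt peaks --manifest study/manifest.csv --reference S01 --out peaks.csv
qsarpt replay --model eq3 --descriptors descriptors.csv
```

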