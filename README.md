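# harold

**Is the extra ipsilateral motor activity of older adults compensatory?
A tested, fully synthetic re-implementation of the complete analysis
chain for asking that question.**

Older adults activate ipsilateral (right) motor cortex more than young
adults during right-hand finger responses — the HAROLD pattern
(hemispheric asymmetry reduction in older adults).  Whether this
hyperactivation *helps* (compensation) or is nonspecific
(inefficiency/dedifferentiation) cannot be decided from mean activation
alone.  This package implements the three-pronged test used in lifespan
fMRI work, end to end, on synthetic cohorts with known ground truth:

1. **Behavioral**: does ipsilateral activation predict better (faster,
   less variable) reaction times increasingly with age?  Robust
   regression of RT summaries on standardized age (linear + quadratic),
   ipsilateral activation and their interaction, with JZS Bayes factors
   quantifying evidence for the null.
2. **Multivariate Bayes (MVB)**: does adding ipsilateral voxels to a
   contralateral decoding model *boost* the log model evidence for
   predicting action performance?  Per participant,
   Δ = F(bilateral) − F(contralateral); Δ > 3 nats (Bayes factor
   e³ ≈ 20) is a boost, Δ < −3 a reduction.  Unreliable decoders are
   excluded via phase-shuffled reference fits; boost categories are
   regressed on age by proportional-odds ordinal regression (odds ratio
   per SD of age), with a directional Bayes factor against
   "age effect > 0".
3. **MVPA**: does adding ipsilateral voxels improve four-finger
   decoding accuracy (one-vs-one linear SVM, balanced accuracy, fourfold
   CV) increasingly with age?

Under the hood: a seeded synthetic-cohort generator for the two designs
(sensorimotor detection, 120 bimodal trials, SOA 2–26 s, TR 1.97 s;
free selection, 240 trials over four fingers in blocks of 20), a
first-level GLM engine (canonical double-gamma HRF ± derivatives,
1/128 Hz cosine high-pass, grand-mean scaling to 100, AR(1)+white ReML
prewhitening, least-squares-separate trial betas), statistic-map ROI
tools (10 mm smoothing for definition, top-70 rank selection near a
landmark, mirror flip across x = 0), and a from-scratch MVB decoder
(sparse voxel prior, greedy nested-subset search maximizing the
empirical-Bayes free energy).

The generator embeds or withholds *true* compensation, so the pipeline
is validated both ways: on `compensation` cohorts the boost odds ratio
exceeds 1 and the RT coupling is detected with high power; on
`haroldnull` cohorts (univariate HAROLD present, ipsilateral patterns
redundant) every compensation test stays calibrated at its nominal
error rate.

## Worked example

```python
from harold import pipeline

config = pipeline.make_fixture("tiny")   # 12 subjects, 16 voxels/ROI
bundle = pipeline.run_experiment(config)
print(bundle["boost_main"]["report"]["summary"])
```

prints (abridged):

```
{'mode': 'main', 'n': 12, 'n_included': 12,
 'category_counts': {'reduction': 1, 'ambiguous': 8, 'boost': 3},
 'group_reliability': {'mean_margin': 42.87, 't': 9.43, 'p': 6.6e-07, 'df': 11}}
```

All twelve synthetic participants pass the phase-shuffling reliability
filter (their bilateral decoder beats shuffled targets by a mean margin
of 42.9 nats, far above the 3-nat criterion); their
bilateral-vs-contralateral evidence differences then split into boost /
ambiguous / reduction categories, which downstream ordinal regression
relates to age.  The same bundle carries the univariate age-effect
table — the ipsilateral ROI shows its built-in HAROLD rise (F = 16.7,
p = 9.5e-4 on this fixture) — and the behavioral interaction table with
its Bayes factor for the null (p = 0.87, BF01 = 2.2 on this fixture,
correctly favouring no compensation in the null scenario).

The `examples/` directory holds one short narrative script per
capability (cohort simulation, GLM, ROI tools, MVB boost, MVPA,
lifespan statistics, full pipeline); each prints the numbers it computes
and says what they mean.  A thin CLI wraps the same code:
`harold simulate|boost|run|stats-tables --seed S --out DIR`.

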