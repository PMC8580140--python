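"""Run the full experiment pipeline on the tiny packaged fixture.

Wires cohort generation, GLM, MVB boost comparison and lifespan
statistics into one report bundle (12 participants, 16 voxels/ROI,
120-scan runs) and prints the headline entries.  The same call with
``make_fixture("standard")`` reproduces the full-size study conditions.
"""

from harold import pipeline

config = pipeline.make_fixture("tiny")
bundle = pipeline.run_experiment(config)

summary = bundle["boost_main"]["report"]["summary"]
print(f"participants: {summary['n']} "
      f"(included after reliability filter: {summary['n_included']})")
print(f"boost categories: {summary['category_counts']}")
rel = summary["group_reliability"]
print(f"group reliability (margin > 3 nats): t({rel['df']})={rel['t']:.1f}, "
      f"p={rel['p']:.2g}")

uni = bundle["univariate"]["univariate_ipsilateral"]
print(f"\nipsilateral univariate age effect: F={uni['F']:.1f}, "
      f"p={uni['p']:.3g} (HAROLD pattern reproduced)")

beh = bundle["behavioral"]["rt_sd"]["interaction"]
print(f"age x ipsilateral interaction on RT variability: p={beh['p']:.2f}, "
      f"BF01={beh['bf01']:.1f}")

print(f"\nstage timings (s): {bundle['manifest']['timing_s']}")
print("every seed and threshold used is recorded in the manifest, so the "
      "bundle is exactly reproducible")
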