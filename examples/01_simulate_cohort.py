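"""Simulate a longitudinal cfRNA case/control cohort.

Draws a negative-binomial count matrix for participants sampled at
<=12, 13-20 and >=23 weeks of gestation plus post-partum, with planted
preeclampsia fold-change trends, and prints the cohort's shape and the
planted structure a recovery analysis should find.
"""

from cfrna import simulate

design = simulate.SimulationDesign(cohorts={"discovery": (20, 10)}, n_genes=1000, seed=1)
counts, meta, truth = simulate.simulate_cohort(design)

print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(meta.groupby(["window", "outcome"]).size().unstack(fill_value=0))
n_g1 = sum(1 for s in truth.deg_trends.values() if s == simulate.GROUP1)
n_g2 = len(truth.deg_trends) - n_g1
print(f"planted differential genes: {n_g1} falling (V-shape), {n_g2} early-peak")
print(f"housekeeping (null) genes: {len(truth.housekeeping_genes)}")
# The planted genes carry log2 fold changes near -0.6 / +0.8 in early
# gestation; everything else differs only by noise between the arms.
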