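"""Paralog-buffering screen: dependency-expression correlation.

The generator ties the query gene's dependency to its partner's expression
(low partner expression -> deeper dependency), mimicking paralog
redundancy. The screen selects lines dependent on an anchor gene (score
< -0.3), then Pearson-correlates the query's dependency with every
expressed gene's expression across those lines; the redundant partner
should rank first, and the single-pair F-test (F = t^2) agrees with the
correlation p.
"""

from complexdep import (
    ParalogPair,
    ScreenConfig,
    expression_dependency_screen,
    linear_association_ftest,
    select_dependent_lines,
)
from complexdep import generate_screen

# the pair is two non-essential genes from the generated universe
cfg = ScreenConfig(
    n_genes=500,
    n_common_essential=100,
    paralog_pairs=(ParalogPair("GENE0001", "GENE0002", slope=0.25),),
    seed=2,
)
bundle = generate_screen(cfg)

# anchor on a common-essential gene: every line depends on it
lines = select_dependent_lines(bundle.dependency, "ESS0000", threshold=-0.3)
print(f"lines dependent on anchor: {len(lines)} / {bundle.dependency.shape[1]}")

hits = expression_dependency_screen(
    bundle.dependency, bundle.expression, "GENE0001", lines
)
top = [h for h in hits if h.skipped is None][:3]
print("top correlations with GENE0001 dependency:")
for h in top:
    print(f"  {h.gene:10s} r {h.r:+.3f}  t {h.t:+.2f}  p {h.p:.2e}  q {h.q:.2e}")

best = top[0]
x = bundle.expression.loc[best.gene, lines].to_numpy()
y = bundle.dependency.loc["GENE0001", lines].to_numpy()
slope, F, p = linear_association_ftest(x, y)
print(f"\nF-test on the top pair: slope {slope:+.3f}, F {F:.1f}, p {p:.2e} "
      f"(= t^2 of the Pearson t: {best.t**2:.1f})")
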