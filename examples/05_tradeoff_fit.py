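"""Fit the defense/adaptive-trait trade-off.

The upper envelope (max ARG count at each defense-system count x) follows
y = a / (1 + e^{b(x-c)}); the fit recovers the planted (a, b, c).
"""

from defensome import (CohortParams, build_envelope, category_correlations,
                       fit_sigmoid, generate_cohort, FIRST_LINE_NAMED)
from defensome.simulate import sparse_params

cohort, truth = generate_cohort(sparse_params(CohortParams(
    n_genomes=2000, seed=9)))

env = build_envelope(cohort, "ARG")
fit = fit_sigmoid(env, seed=9)
a, b, c = truth.tradeoff_params
print(f"planted:   a={a:.1f}  b={b:.2f}  c={c:.1f}")
print(f"recovered: a={fit.a:.1f}  b={fit.b:.2f}  c={fit.c:.1f}  "
      f"R^2={fit.r_squared:.3f}")

corr = category_correlations(cohort, "ARG", frozenset(FIRST_LINE_NAMED))
print("\nSpearman of ARG count vs defense-system count:")
print(corr.to_string(index=False))
# The negative correlations and the recovered logistic ceiling quantify
# the inverse relationship between immunity and adaptive gene cargo.
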