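"""Nonparametric tests and their effect sizes on per-subject summaries.

Shows the Wilcoxon signed-rank effect size r = |Z|/sqrt(N) and the
Kruskal-Wallis eta^2 = H/(N-1) on small made-up per-subject vectors of
the kind the cohort report feeds them.
"""

import numpy as np

from clckit import kruskal_wallis_groups, wilcoxon_paired, friedman_blocks

rng = np.random.default_rng(0)

# paired: observed vs null band probability for 16 subjects
null_p = rng.uniform(0.2, 0.3, size=16)
observed_p = null_p + rng.normal(0.10, 0.03, size=16)
res = wilcoxon_paired(observed_p, null_p)
print(f"Wilcoxon: statistic={res.statistic:.1f} p={res.p_value:.2e} "
      f"r={res.effect_size:.2f} (N={res.n})")

# groups: median coupling ratio, older vs younger subjects
older = [0.99, 0.97, 1.00, 0.98, 0.96]
young = [0.92, 0.90, 0.93, 0.91, 0.94, 0.89]
kw = kruskal_wallis_groups([older, young])
print(f"Kruskal-Wallis: H={kw.statistic:.2f} p={kw.p_value:.4f} "
      f"eta^2={kw.effect_size:.2f} (N={kw.n})")

# blocks: same 6 subjects under 3 coupling conditions
matrix = np.column_stack([rng.normal(40, 5, 6), rng.normal(55, 5, 6),
                          rng.normal(75, 5, 6)])
fr = friedman_blocks(matrix)
print(f"Friedman: chi2={fr.statistic:.2f} p={fr.p_value:.4f} (N={fr.n})")

# r near 1 means the paired shift is about as large as it can be for the
# sample size; eta^2 close to 1 means group membership explains almost all
# of the rank variance.  The Friedman test asks whether the within-subject
# condition profiles are flat.
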