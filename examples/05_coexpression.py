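"""Signed-hybrid co-expression network, TOM modules and module overlap.

Part 1 screens soft powers on a modular expression matrix and picks the
smallest one whose connectivity distribution fits a scale-free topology.
Part 2 builds TOM modules at power 6 (the conventional choice at this
network size) in two matrices sharing one planted module, and measures the
overlap of the module containing a target gene against a size-matched
random baseline.
"""

import numpy as np
import pandas as pd

from promdiverge.coexpression import (CoexpressionConfig, adjacency_tom,
                                      detect_modules, module_overlap,
                                      pick_soft_threshold)

rng = np.random.default_rng(3)

# -- part 1: soft-power selection ------------------------------------------
factors = rng.normal(size=(4, 30))
rows = []
for b in range(4):
    for _ in range(30):
        lam = rng.uniform(0.3, 0.95)
        rows.append(np.sqrt(lam) * factors[b]
                    + np.sqrt(1 - lam) * rng.normal(size=30))
screen_expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(120)])
beta, diag = pick_soft_threshold(screen_expr)
print(f"soft power chosen: beta = {beta} "
      f"(scale-free fit R^2 = {float(diag[diag.beta == beta].rsq.iloc[0]):.2f}, "
      f"target 0.85)")

# -- part 2: modules and cross-matrix overlap ------------------------------
rng = np.random.default_rng(1)


def make_expression(shared_factor, n_other=2):
    rows, names = [], []
    blocks = [shared_factor] + [rng.normal(size=shared_factor.size)
                                for _ in range(n_other)]
    for b, f in enumerate(blocks):
        for g in range(40):
            lam = rng.uniform(0.6, 0.95)
            rows.append(np.sqrt(lam) * f
                        + np.sqrt(1 - lam) * rng.normal(size=f.size))
            names.append(f"block{b}_g{g}")
    return pd.DataFrame(rows, index=names)


shared = rng.normal(size=40)
expr_a, expr_b = make_expression(shared), make_expression(shared)
cfg = CoexpressionConfig()
mods_a = detect_modules(adjacency_tom(expr_a, 6), cfg, target_gene="block0_g0")
mods_b = detect_modules(adjacency_tom(expr_b, 6), cfg, target_gene="block0_g0")
print(f"matrix A: {len([m for m in mods_a.sizes if m])} modules "
      f"(sizes {dict(sorted(mods_a.sizes.items()))}); "
      f"target gene in module {mods_a.target_module}")

universe = sorted(set(expr_a.index) | set(expr_b.index))
ov = module_overlap(mods_a.genes_in(mods_a.target_module),
                    mods_b.genes_in(mods_b.target_module), universe,
                    n_draws=2000, seed=1)
print(f"target-module overlap: {ov['overlap']} genes "
      f"(hypergeometric p = {ov['p']:.3g}; random modules of the same size "
      f"share {ov['null_mean_overlap']:.1f} on average)")
print("\nThe shared latent factor makes the two target modules overlap far")
print("beyond the random baseline — the signature of a conserved module.")
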