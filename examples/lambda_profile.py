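"""Pagel's λ: simulation, profile likelihood, and maximum-likelihood recovery.

Simulates a trait under λ-transformed Brownian motion (λ = 0.5) on a 60-tip
pure-birth tree, profiles the PGLS log-likelihood over λ on a grid, and
compares the grid optimum with the bounded-search ML estimate.
"""

import numpy as np
import pandas as pd

from aposignal import lambda_transform, pgls_fit, phylo_covariance, simulate_bm
from aposignal.phylo import simulate_tree

tree = simulate_tree(60, seed=11)
y = simulate_bm(tree, sigma2=1.0, lam=0.5, mu=0.0, seed=11)

fit = pgls_fit(y, pd.DataFrame(index=y.index), tree=tree, mode="ml")
print(f"true lambda = 0.5   ML estimate = {fit.lam:.3f}   logL = {fit.loglik:.2f}")

C = phylo_covariance(tree, taxa=list(y.index))
grid = np.linspace(0, 1, 11)
print("\nprofile log-likelihood over lambda:")
for lam in grid:
    f = pgls_fit(y, pd.DataFrame(index=y.index), C=C, mode="fixed", lam=float(lam))
    marker = " <- ML neighbourhood" if abs(lam - fit.lam) <= 0.05 else ""
    print(f"  lambda={lam:.1f}  logL={f.loglik:8.2f}{marker}")
print("\nThe ML estimate sits where the profile peaks; at lambda=0 the model is")
print("ordinary least squares, at lambda=1 pure Brownian motion.")
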