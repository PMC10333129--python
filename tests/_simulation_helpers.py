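"""Shared simulation designs used by more than one test module."""

import numpy as np

from symphy import cophylogeny, synth


def planted_interaction_dataset(rep, sd=1.8):
    """Full combination grid with a pure (doubly centred) co-evolutionary
    interaction field planted on the [hs] covariance."""
    host = synth.sim_tree(12, seed=41 + rep)
    sym, links, _ = synth.sim_host_symbiont(host, signal=0.5, seed=142 + rep)
    grid = cophylogeny.combination_grid(host, sym, links)
    tab, terms = cophylogeny.interaction_random_terms(host, sym, grid)
    rng = np.random.default_rng(43 + rep)
    if sd > 0:
        hs_cov = next(t for t in terms if t.name == "[hs]").covariance
        L = np.linalg.cholesky(hs_cov.matrix + 1e-8 * np.eye(len(grid)))
        F = (L @ rng.standard_normal(len(grid))).reshape(12, 12)
        # remove host/symbiont main effects: plant interaction only
        F = (F - F.mean(axis=1, keepdims=True)
             - F.mean(axis=0, keepdims=True) + F.mean())
        eta = -1.0 + F.ravel() / F.std() * sd
    else:
        eta = np.full(len(grid), -1.0)
    n = 5 + rng.poisson(5.0, len(grid))
    k = rng.binomial(n, 1 / (1 + np.exp(-eta)))
    return tab.assign(k=k, n=n), terms
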