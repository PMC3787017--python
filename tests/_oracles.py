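"""Independent oracles used only by the test suite.

Kept deliberately separate from the package: brute-force implementations
against which the library's optimised paths are checked.
"""

import numpy as np


def grid_search_ed50(
    doses,
    pct,
    log_lo=-2.0,
    log_hi=2.0,
    log_step=0.001,
    hill_max=5.0,
    hill_step=0.01,
):
    """Exhaustive grid search of the constrained sigmoid least-squares fit.

    Returns (sse, log_ed50, hill) at the best grid point.
    """
    logd = np.log10(np.asarray(doses, dtype=float))
    y = np.asarray(pct, dtype=float)
    log_grid = np.arange(log_lo, log_hi + log_step / 2, log_step)
    best_sse, best_le, best_h = np.inf, None, None
    for h in np.arange(hill_step, hill_max + hill_step / 2, hill_step):
        pred = 100.0 / (1.0 + 10.0 ** (h * (log_grid[:, None] - logd[None, :])))
        sse = ((pred - y[None, :]) ** 2).sum(axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best_sse:
            best_sse, best_le, best_h = float(sse[i]), float(log_grid[i]), float(h)
    return best_sse, best_le, best_h


def mc_additive_ci(f, ed50_a, se_a, ed50_b, se_b, n_draws=100_000, seed=0):
    """Monte-Carlo 95% interval for Z_add = f*A + (1-f)*B, A, B independent normals."""
    rng = np.random.default_rng(seed)
    z = f * rng.normal(ed50_a, se_a, n_draws) + (1 - f) * rng.normal(ed50_b, se_b, n_draws)
    return tuple(np.percentile(z, [2.5, 97.5]))
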