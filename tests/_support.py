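"""Shared independent oracles for the test suite."""

import numpy as np


def brute_force_pi(G: np.ndarray) -> float:
    """Average expected difference between a random allele copy from
    individual i and one from individual j, over ALL ordered pairs (self
    pairs included), normalized by n(n-1) -- the estimator's algebra."""
    n, L = G.shape
    total = 0.0
    for j in range(L):
        p_hat = G[:, j] / 2.0
        for a in range(n):
            for b in range(n):
                total += p_hat[a] * (1 - p_hat[b]) + p_hat[b] * (1 - p_hat[a])
    return total / (n * (n - 1)) / L
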