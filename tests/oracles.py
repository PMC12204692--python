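"""Independent brute-force oracles for small HMM instances.

Everything here recomputes quantities from first principles —
emissions by direct trapezoidal integration, likelihoods and best
paths by explicit enumeration over all N^K state sequences — and
shares no code path with the package's recursions.
"""

import itertools

import numpy as np


def oracle_emissions(series, model):
    """(K, N) emission pseudo-likelihoods by direct integration."""
    t = series.grid.points
    out = np.empty((len(series), model.n_states))
    for k, curve in enumerate(series.curves):
        for i, mu in enumerate(model.centroids):
            d2 = np.trapezoid((curve.values - mu.values) ** 2, t)
            out[k, i] = 1.0 / (d2 + model.emission_epsilon)
    return out


def path_score(states, B, nu, A):
    """Unnormalised pseudo-likelihood of one explicit state path."""
    s = nu[states[0]] * B[0, states[0]]
    for k in range(1, len(states)):
        s *= A[states[k - 1], states[k]] * B[k, states[k]]
    return s


def brute_force_log_likelihood(B, nu, A):
    """log of the sum of path scores over all N^K paths."""
    K, N = B.shape
    total = 0.0
    for states in itertools.product(range(N), repeat=K):
        total += path_score(states, B, nu, A)
    return np.log(total)


def brute_force_viterbi(B, nu, A):
    """(best path, best log score) by enumeration; ties toward the
    lexicographically smallest path."""
    K, N = B.shape
    best, best_score = None, -np.inf
    for states in itertools.product(range(N), repeat=K):
        s = path_score(states, B, nu, A)
        logs = np.log(s) if s > 0 else -np.inf
        if logs > best_score:
            best, best_score = states, logs
    return np.array(best), best_score
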