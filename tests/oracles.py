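"""Independent brute-force oracles shared across test modules."""

import numpy as np


def dense_person_loglik(y, stacked, model, nodes, log_w):
    """One person's marginal log-likelihood on a fixed quadrature grid.

    Deliberately plain (per-item loop, no shared code with the package
    internals) so it can serve as a finite-difference oracle for the
    analytic casewise scores.
    """
    per = 2 if model == "2PL" else 3
    J = y.size
    total = np.exp(log_w).copy()
    for j in range(J):
        a, d = stacked[j * per], stacked[j * per + 1]
        c = stacked[j * per + 2] if model == "3PL" else 0.0
        p = c + (1 - c) / (1 + np.exp(-(a * nodes + d)))
        total *= p if y[j] == 1 else (1 - p)
    return np.log(total.sum())
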