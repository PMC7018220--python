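"""Standalone brute-force oracles shared by the acceptance suite."""

import numpy as np

MISSING = -1


def wc_two_pop_oracle(g1, g2):
    """Two-population Weir-Cockerham theta-hat per site, written directly
    from the a/b/c variance-component definitions."""
    thetas = []
    for s in range(g1.shape[0]):
        x1 = g1[s][g1[s] != MISSING]
        x2 = g2[s][g2[s] != MISSING]
        n1, n2 = len(x1), len(x2)
        p1, p2 = x1.sum() / (2 * n1), x2.sum() / (2 * n2)
        h1, h2 = np.mean(x1 == 1), np.mean(x2 == 1)
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        thetas.append(np.nan if a + b + c == 0 else a / (a + b + c))
    return np.array(thetas)
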