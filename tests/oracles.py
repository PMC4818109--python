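"""Independent brute-force oracles used to validate the vectorized likelihood.

These deliberately re-derive everything cell by cell from the processing-tree
paths (know the key / guess True / guess False / decline), without reusing
any package internals beyond the cell codes.
"""

import math

from condorcet.data import DONT_KNOW, FALSE, MISSING, TRUE


def tree_category_probs(z: int, d: float, b: float, g: float) -> dict[int, float]:
    """Enumerate the processing-tree paths and accumulate per-category mass."""
    paths = [
        (d, TRUE if z == 1 else FALSE),  # knows the consensus, reports it
        ((1.0 - d) * b * g, TRUE),  # does not know, guesses "True"
        ((1.0 - d) * b * (1.0 - g), FALSE),  # does not know, guesses "False"
        ((1.0 - d) * (1.0 - b), DONT_KNOW),  # does not know, declines to guess
    ]
    out = {TRUE: 0.0, FALSE: 0.0, DONT_KNOW: 0.0}
    for mass, category in paths:
        out[category] += mass
    return out


def loglik_brute_force(values, key, ability, difficulty, willingness, guess_bias) -> float:
    """Cell-wise log-likelihood by direct path enumeration (missing skipped)."""
    total = 0.0
    n, m = values.shape
    for i in range(n):
        for k in range(m):
            y = values[i, k]
            if y == MISSING:
                continue
            d = 1.0 / (1.0 + math.exp(-(ability[i] - difficulty[k])))
            p = tree_category_probs(int(key[k]), d, willingness[i], guess_bias[i])[y]
            total += math.log(p)
    return total
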