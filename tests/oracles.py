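"""Independent brute-force oracles for the Bayesian engine.

Deliberately written as plain element-wise loops over flattened grids, with
no code shared with the package's vectorized implementations.
"""

import math


def brute_bayes_update(mass_flat, p_hit_flat, outcome_is_hit):
    """Element-wise multiply-and-normalize over the flattened grid."""
    out = []
    for m, p in zip(mass_flat, p_hit_flat):
        like = p if outcome_is_hit else 1.0 - p
        out.append(m * like)
    total = sum(out)
    return [v / total for v in out]


def brute_entropy_bits(mass_flat):
    h = 0.0
    for m in mass_flat:
        if m > 0:
            h -= m * math.log2(m)
    return h


def brute_expected_entropy(mass_flat, p_hit_flat):
    """p(Hit)*H(post|Hit) + p(Miss)*H(post|Miss), via explicit updates."""
    p_hit_pred = sum(m * p for m, p in zip(mass_flat, p_hit_flat))
    post_hit = brute_bayes_update(mass_flat, p_hit_flat, True)
    post_miss = brute_bayes_update(mass_flat, p_hit_flat, False)
    return p_hit_pred * brute_entropy_bits(post_hit) + (
        1.0 - p_hit_pred
    ) * brute_entropy_bits(post_miss)


def brute_select(mass_flat, table):
    """Exhaustive scan over all stimulus rows; returns (index, entropies)."""
    ents = [brute_expected_entropy(mass_flat, row) for row in table]
    best = min(range(len(ents)), key=lambda i: ents[i])
    return best, ents


def rectangle_aucsf(gmax, f_lo, f_hi):
    """Closed-form area of a flat CSF in log-log space."""
    return math.log10(gmax) * (math.log10(f_hi) - math.log10(f_lo))
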