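"""Naive per-element loop implementations of every loss, used as independent
oracles by the test suite.  Deliberately scalar Python: no vectorization, no
shared code with the package implementation."""

import math


def oracle_dice(pred, truth, eps):
    fg_num = fg_den = bg_num = bg_den = 0.0
    for y, p in zip(truth, pred):
        fg_num += y * p
        fg_den += y + p
        bg_num += (1 - y) * (1 - p)
        bg_den += 2 - y - p
    return 1 - (fg_num + eps) / (fg_den + eps) - (bg_num + eps) / (bg_den + eps)


def oracle_focal(pred, truth, delta):
    total = 0.0
    for y, p in zip(truth, pred):
        yt = p if y == 1 else 1 - p
        yt = min(max(yt, delta), 1.0)
        total += -((1 - yt) ** 2) * math.log(yt)
    return total


def oracle_bce(pred, truth, delta):
    total = 0.0
    for y, p in zip(truth, pred):
        p = min(max(p, delta), 1 - delta)
        total += -(y * math.log(p) + (1 - y) * math.log(1 - p))
    return total


def oracle_mce(probs, delta):
    return sum(-math.log(min(max(p, delta), 1.0)) for p in probs)


def random_case(rng, n):
    pred = rng.random(n)
    truth = (rng.random(n) < rng.uniform(0.05, 0.95)).astype(float)
    return pred, truth
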