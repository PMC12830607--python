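"""Independent brute-force reimplementations of every profile metric.

Deliberately written with plain Python loops and the ``statistics``
module so they share no code path with the package; used as oracles in
the property and acceptance tests.
"""

from __future__ import annotations

import math
import statistics


def naive_mean(xs):
    return sum(xs) / len(xs)


def naive_pop_sd(xs):
    m = naive_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))


def naive_zscores(xs):
    m = naive_mean(xs)
    s = naive_pop_sd(xs)
    if s == 0:
        return [0.0 for _ in xs]
    return [(x - m) / s for x in xs]


def naive_ra(zs):
    m = naive_mean(zs)
    return naive_mean([abs(z - m) for z in zs])


def naive_rz(zs):
    return max(zs) - min(zs)


def naive_rolling_sd(xs, window):
    return [
        statistics.stdev(xs[i: i + window])
        for i in range(len(xs) - window + 1)
    ]


def naive_skewness(xs):
    m = naive_mean(xs)
    m2 = naive_mean([(x - m) ** 2 for x in xs])
    m3 = naive_mean([(x - m) ** 3 for x in xs])
    return m3 / m2**1.5


def naive_exceedance(zs, k):
    return sum(1 for z in zs if abs(z) > k) / len(zs)


def naive_smooth(xs, window):
    half = window // 2
    out = []
    for i in range(len(xs)):
        lo = max(0, i - half)
        hi = min(len(xs), i + half + 1)
        out.append(naive_mean(xs[lo:hi]))
    return out


def naive_paired_t(a, b):
    diffs = [x - y for x, y in zip(a, b)]
    n = len(diffs)
    mean_d = naive_mean(diffs)
    sd = statistics.stdev(diffs)
    return mean_d / (sd / math.sqrt(n))
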