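"""Independent brute-force implementations of the pooling closed forms.

Plain-Python loops, no numpy vectorisation and no reuse of the package's
internals, so they can stand as oracles for the library's linear-algebra
paths.
"""

import math

from scipy import stats


def fe_pool(ys, ses):
    """Fixed-effect weighted mean and its standard error."""
    num = den = 0.0
    for y, s in zip(ys, ses):
        w = 1.0 / (s * s)
        num += w * y
        den += w
    return num / den, math.sqrt(1.0 / den)


def q_stat(ys, ses):
    """Cochran's Q by direct summation."""
    mu, _ = fe_pool(ys, ses)
    q = 0.0
    for y, s in zip(ys, ses):
        q += (y - mu) ** 2 / (s * s)
    return q


def dl_tau2(ys, ses):
    """DerSimonian-Laird tau^2 from the method-of-moments closed form."""
    k = len(ys)
    q = q_stat(ys, ses)
    sw = sw2 = 0.0
    for s in ses:
        w = 1.0 / (s * s)
        sw += w
        sw2 += w * w
    c = sw - sw2 / sw
    return max(0.0, (q - (k - 1)) / c)


def re_pool(ys, ses):
    """Random-effects pooled mean and standard error with DL weights."""
    t2 = dl_tau2(ys, ses)
    num = den = 0.0
    for y, s in zip(ys, ses):
        w = 1.0 / (s * s + t2)
        num += w * y
        den += w
    return num / den, math.sqrt(1.0 / den)


def egger(ys, ses):
    """Closed-form OLS of y/se on 1/se: intercept, its SE and t-test p."""
    k = len(ys)
    xs = [1.0 / s for s in ses]
    zs = [y / s for y, s in zip(ys, ses)]
    xbar = sum(xs) / k
    zbar = sum(zs) / k
    sxx = sum((x - xbar) ** 2 for x in xs)
    sxz = sum((x - xbar) * (z - zbar) for x, z in zip(xs, zs))
    slope = sxz / sxx
    intercept = zbar - slope * xbar
    rss = sum((z - intercept - slope * x) ** 2 for x, z in zip(xs, zs))
    s2 = rss / (k - 2)
    se_int = math.sqrt(s2 * (1.0 / k + xbar**2 / sxx))
    t = intercept / se_int
    p = 2.0 * stats.t.sf(abs(t), k - 2)
    return intercept, se_int, p
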