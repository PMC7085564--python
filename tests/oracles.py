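"""Independent brute-force reference implementations used as test oracles.

Deliberately written with pure Python (``math``, ``sorted``) rather than
numpy so they share no code path with the implementation under test.
"""

import math


def brute_quantile(values, q):
    """Linear interpolation at position q*(n-1) on the sorted values."""
    s = sorted(values)
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def brute_axis_features(values):
    """All 17 window statistics, from first principles."""
    n = len(values)
    mean = sum(values) / n
    mx = max(values)
    mn = min(values)
    sq = sum(v * v for v in values)
    total = sum(values)
    sum_abs = sum(abs(v) for v in values)
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    std = math.sqrt(m2 * n / (n - 1)) if n > 1 else 0.0
    if mx == mn:
        skew = kurt = 0.0
    else:
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2 - 3.0
    med = brute_quantile(values, 0.5)
    return {
        "mean": mean,
        "std": std,
        "max": mx,
        "min": mn,
        "energy": sq / n,
        "kurtosis": kurt,
        "skewness": skew,
        "rms": math.sqrt(sq / n),
        "rss": math.sqrt(sq),
        "sum": total,
        "sum_abs": sum_abs,
        "mean_abs": sum_abs / n,
        "range": mx - mn,
        "median": med,
        "upper_quartile": brute_quantile(values, 0.75),
        "lower_quartile": brute_quantile(values, 0.25),
        "mad": brute_quantile([abs(v - med) for v in values], 0.5),
    }


def brute_window_starts(n, window_len, step):
    """Enumerate window start indices: keep tails of at least ``step``."""
    starts = []
    i = 0
    while n - i >= step:
        starts.append(i)
        i += step
    return starts
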