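"""Independent brute-force oracles used to cross-check the extractors.

Everything here is written from the mathematical definition (direct
summation, explicit loops), deliberately avoiding the package's own code
paths and numpy's transform routines.
"""

import math


def moments_oracle(x):
    """Mean, n-1 variance/SD and population excess kurtosis by summation."""
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1) if n > 1 else 0.0
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else float("nan")
    return {
        "mean": mean,
        "sum": sum(x),
        "minimum": min(x),
        "maximum": max(x),
        "std": math.sqrt(var),
        "variance": var,
        "kurtosis": kurt,
    }


def dft_magnitude_oracle(x, k):
    """|k-th DFT coefficient| by direct summation."""
    n = len(x)
    re = sum(x[j] * math.cos(-2 * math.pi * j * k / n) for j in range(n))
    im = sum(x[j] * math.sin(-2 * math.pi * j * k / n) for j in range(n))
    return math.hypot(re, im)


def ricker_oracle(points, a):
    amp = 2.0 / (math.sqrt(3.0 * a) * math.pi**0.25)
    out = []
    for i in range(points):
        t = i - (points - 1) / 2.0
        out.append(amp * (1.0 - t**2 / a**2) * math.exp(-(t**2) / (2 * a**2)))
    return out


def cwt_center_oracle(x, width):
    """Central 'same'-mode convolution coefficient with the Ricker kernel,
    by explicit double loop (numpy.convolve semantics rebuilt by hand)."""
    n = len(x)
    kernel = ricker_oracle(min(10 * int(width), n), width)
    m = len(kernel)
    full = [0.0] * (n + m - 1)
    for i in range(n):
        for j in range(m):
            full[i + j] += x[i] * kernel[j]
    start = (m - 1) // 2  # numpy 'same': centered slice of the full product
    center = n // 2
    return full[start + center]


def rank_auc_oracle(scores, labels):
    """AUC as the tie-averaged Mann-Whitney probability by pair counting."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
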