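"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they cross-check:
full-sort medians, even-odd ray casting, the Moore-Penrose pseudo-inverse
and the textbook Pearson formula.
"""

import numpy as np


def sort_median(values):
    """Middle element (or mean of the central pair) after a full sort."""
    s = sorted(float(v) for v in values)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return (s[n // 2 - 1] + s[n // 2]) / 2


def ray_casting_contains(poly_coords, x, y):
    """Even-odd ray casting with the half-open edge convention on y."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xi:
                inside = not inside
    return inside


def pinv_coefficients(X, y):
    """Least-squares coefficients via the Moore-Penrose pseudo-inverse."""
    return np.linalg.pinv(np.asarray(X, float)) @ np.asarray(y, float)


def direct_pearson(a, b):
    """Pearson product-moment correlation by the definition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac, bc = a - a.mean(), b - b.mean()
    return float((ac * bc).sum() / np.sqrt((ac ** 2).sum() * (bc ** 2).sum()))
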