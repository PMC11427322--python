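"""Independent brute-force reference implementations used as oracles.

Everything here is written with naive Python loops, deliberately avoiding the
vectorised code paths of the package, so agreement is evidence of
correctness rather than shared bugs.
"""

from __future__ import annotations

import cmath
import math


def loglog_slope(sizes, counts):
    xs = [-math.log(s) for s in sizes]
    ys = [math.log(c) for c in counts]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = sum((x - mx) ** 2 for x in xs)
    return num / den


def naive_box_count(mask, sizes):
    """Occupied-box counts per size; grid anchored top-left, partial boxes kept."""
    h = len(mask)
    w = len(mask[0])
    counts = []
    for s in sizes:
        n = 0
        for by in range((h + s - 1) // s):
            for bx in range((w + s - 1) // s):
                hit = False
                for y in range(by * s, min((by + 1) * s, h)):
                    for x in range(bx * s, min((bx + 1) * s, w)):
                        if mask[y][x]:
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    n += 1
        counts.append(n)
    return counts


def naive_dbc_counts(values, sizes):
    """Differential box counts: sum over cells of ceil((max-min)/h) + 1."""
    h = len(values)
    w = len(values[0])
    side = min(h, w)
    counts = []
    for s in sizes:
        hbox = s / side
        total = 0.0
        for by in range((h + s - 1) // s):
            for bx in range((w + s - 1) // s):
                mx = -1e300
                mn = 1e300
                for y in range(by * s, min((by + 1) * s, h)):
                    for x in range(bx * s, min((bx + 1) * s, w)):
                        v = values[y][x]
                        mx = max(mx, v)
                        mn = min(mn, v)
                total += math.ceil((mx - mn) / hbox) + 1
        counts.append(total)
    return counts


def naive_color_counts(pixels, sizes):
    """Occupied 5-D (x, y, R, G, B) boxes with matched relative edge sizes."""
    h = len(pixels)
    w = len(pixels[0])
    side = min(h, w)
    counts = []
    for s in sizes:
        c_edge = 256.0 * s / side
        boxes = set()
        for y in range(h):
            for x in range(w):
                r, g, b = pixels[y][x]
                boxes.add(
                    (
                        y // s,
                        x // s,
                        math.floor(r / c_edge),
                        math.floor(g / c_edge),
                        math.floor(b / c_edge),
                    )
                )
        counts.append(len(boxes))
    return counts


def naive_spectral_exponent(values, n_bins):
    """Radially averaged power-spectrum slope via a direct O(N^4) DFT."""
    h = len(values)
    w = len(values[0])
    mean = sum(sum(row) for row in values) / (h * w)
    power = [[0.0] * w for _ in range(h)]
    for ky in range(h):
        for kx in range(w):
            acc = 0j
            for y in range(h):
                for x in range(w):
                    acc += (values[y][x] - mean) * cmath.exp(
                        -2j * cmath.pi * (ky * y / h + kx * x / w)
                    )
            power[ky][kx] = abs(acc) ** 2

    def freq(k, n):
        return k / n if k <= n // 2 - (0 if n % 2 else 1) else (k - n) / n

    f_lo = 2.0 / min(h, w)
    f_hi = 0.25
    lg_lo = math.log10(f_lo)
    lg_hi = math.log10(f_hi)
    edges = [10.0 ** (lg_lo + i * (lg_hi - lg_lo) / n_bins) for i in range(n_bins + 1)]
    edges[0] = f_lo  # exact endpoints, matching geometric spacing conventions
    edges[-1] = f_hi
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for ky in range(h):
        for kx in range(w):
            fy = freq(ky, h)
            fx = freq(kx, w)
            f = math.sqrt(fx * fx + fy * fy)
            if f < edges[0] or f > edges[-1]:
                continue
            b = n_bins - 1
            for i in range(n_bins):
                if f < edges[i + 1]:
                    b = i
                    break
            sums[b] += power[ky][kx]
            counts[b] += 1
    xs, ys = [], []
    for i in range(n_bins):
        if counts[i]:
            center = math.sqrt(edges[i] * edges[i + 1])
            xs.append(math.log(center))
            ys.append(math.log(sums[i] / counts[i]))
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = sum((x - mx) ** 2 for x in xs)
    return -(num / den) / 2.0


def naive_vif_from_correlation(X):
    """VIFs as the diagonal of the inverse correlation matrix (pure python)."""
    import numpy as np

    corr = np.corrcoef(np.asarray(X, dtype=float), rowvar=False)
    return np.diag(np.linalg.inv(corr))
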