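"""Independent brute-force reference implementations used only by the tests.

Every function here is a direct transcription of a definition as nested
loops or direct summation, kept deliberately free of the vectorized code
paths it checks.
"""

import numpy as np


def mlv_brute(img):
    """Max absolute 8-neighbor difference per pixel, replicate padding."""
    img = np.asarray(img, dtype=float)
    m, n = img.shape
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            best = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    x = min(max(i + di, 0), m - 1)
                    y = min(max(j + dj, 0), n - 1)
                    best = max(best, abs(img[i, j] - img[x, y]))
            out[i, j] = best
    return out


def total_variation_brute(block):
    """Sum over all pixels of |diff| to each 8-neighbor, / 255."""
    block = np.asarray(block, dtype=float)
    m, n = block.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    x = min(max(i + di, 0), m - 1)
                    y = min(max(j + dj, 0), n - 1)
                    total += abs(block[i, j] - block[x, y])
    return total / 255.0


def spatial_block_score_brute(block):
    """Max over all 2x2 sub-blocks of the 6-pair absolute-difference sum / 4."""
    block = np.asarray(block, dtype=float)
    m, n = block.shape
    best = 0.0
    for i in range(m - 1):
        for j in range(n - 1):
            px = [block[i, j], block[i, j + 1], block[i + 1, j],
                  block[i + 1, j + 1]]
            v = sum(abs(px[a] - px[b])
                    for a in range(4) for b in range(a + 1, 4)) / 255.0
            best = max(best, v)
    return best / 4.0


def plcc_brute(x, y):
    """Pearson correlation by direct summation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    num = np.sum((x - xm) * (y - ym))
    den = np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2))
    return num / den


def ranks_brute(v):
    """Average ranks (1-based) by all-pairs comparison."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    r = np.empty(n)
    for i in range(n):
        less = sum(1 for j in range(n) if v[j] < v[i])
        equal = sum(1 for j in range(n) if v[j] == v[i])
        r[i] = less + (equal + 1) / 2.0
    return r


def srocc_brute(x, y):
    """Spearman rank correlation via the rank-difference formula."""
    rx = ranks_brute(x)
    ry = ranks_brute(y)
    n = len(rx)
    return 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n * n - 1.0))


def radial_bins_brute(block):
    """Windowed DFT magnitude collapsed onto nearest radial bins.

    Returns (freqs, mean magnitude per bin) excluding the DC bin, by
    explicit per-sample assignment.
    """
    block = np.asarray(block, dtype=float)
    m = block.shape[0]
    w = np.hanning(m)
    windowed = (block - block.mean()) * np.outer(w, w)
    mag = np.abs(np.fft.fftshift(np.fft.fft2(windowed)))
    half = m / 2.0
    sums, counts = {}, {}
    for i in range(m):
        for j in range(m):
            u, v = i - m // 2, j - m // 2
            f = np.sqrt((u / half) ** 2 + (v / half) ** 2)
            k = int(round(f * half))
            if k == 0:
                continue
            sums[k] = sums.get(k, 0.0) + mag[i, j]
            counts[k] = counts.get(k, 0) + 1
    ks = sorted(sums)
    return (np.array([k / half for k in ks]),
            np.array([sums[k] / counts[k] for k in ks]))
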