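"""Independent brute-force oracles for the edge/boundary/metric operators.

Deliberately written against the mathematical definitions (clamped-index
neighborhoods, explicit distance sets) rather than reusing any library
or package code path under test.
"""

import numpy as np


def naive_sobel_magnitude(x):
    """Direct nested-loop Sobel with replicate (clamped-index) padding."""
    sx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    sy = sx.T
    x = np.asarray(x, float)
    if x.ndim == 2:
        x = x[..., None]
    h, w, c = x.shape
    out = np.zeros((h, w))
    for ch in range(c):
        mag = np.zeros((h, w))
        for i in range(h):
            for j in range(w):
                gx = gy = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii = min(max(i + di, 0), h - 1)
                        jj = min(max(j + dj, 0), w - 1)
                        gx += sx[di + 1, dj + 1] * x[ii, jj, ch]
                        gy += sy[di + 1, dj + 1] * x[ii, jj, ch]
                mag[i, j] = np.hypot(gx, gy)
        out += mag
    return out / c


def clamped_erosion(mask):
    """3x3 erosion with out-of-bounds neighbors clamped to the edge."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            vals = [mask[min(max(i + di, 0), h - 1), min(max(j + dj, 0), w - 1)]
                    for di in (-1, 0, 1) for dj in (-1, 0, 1)]
            out[i, j] = min(vals)
    return out


def clamped_dilation(mask):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            vals = [mask[min(max(i + di, 0), h - 1), min(max(j + dj, 0), w - 1)]
                    for di in (-1, 0, 1) for dj in (-1, 0, 1)]
            out[i, j] = max(vals)
    return out


def border_set(mask):
    return (mask ^ clamped_erosion(mask)).astype(bool)


def brute_boundary_band(mask, radius=3):
    """All pixels within Chebyshev distance ``radius`` of a border pixel."""
    border = np.argwhere(border_set(mask))
    out = np.zeros_like(mask)
    if len(border) == 0:
        return out
    h, w = mask.shape
    ii, jj = np.mgrid[0:h, 0:w]
    cheb = np.maximum(
        np.abs(ii[..., None] - border[:, 0]),
        np.abs(jj[..., None] - border[:, 1]),
    ).min(axis=-1)
    return (cheb <= radius).astype(np.uint8)


def brute_edge_target(mask):
    return (clamped_dilation(mask) & ~clamped_erosion(mask).astype(bool)
            ).astype(np.uint8)


def brute_hd95(y, p):
    """95th percentile of pooled all-pairs nearest border distances."""
    by = np.argwhere(border_set(y)).astype(float)
    bp = np.argwhere(border_set(p)).astype(float)
    if len(by) == 0 and len(bp) == 0:
        return 0.0
    if len(by) == 0 or len(bp) == 0:
        return float(np.hypot(*y.shape))
    d2 = ((by[:, None, :] - bp[None, :, :]) ** 2).sum(-1)
    d = np.sqrt(d2)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95))


def naive_conv_same_replicate(x, w, b):
    """'Same' cross-correlation with clamped indices; w: (k,k,Cin,Cout)."""
    x = np.asarray(x, float)
    if x.ndim == 2:
        x = x[..., None]
    h, wd, cin = x.shape
    k, _, _, cout = w.shape
    r = k // 2
    out = np.zeros((h, wd, cout))
    for o in range(cout):
        for i in range(h):
            for j in range(wd):
                acc = 0.0
                for di in range(-r, r + 1):
                    for dj in range(-r, r + 1):
                        ii = min(max(i + di, 0), h - 1)
                        jj = min(max(j + dj, 0), wd - 1)
                        for c in range(cin):
                            acc += w[di + r, dj + r, c, o] * x[ii, jj, c]
                out[i, j, o] = acc + b[o]
    return out
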