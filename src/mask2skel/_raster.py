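"""Numba rasterization kernels for Gaussian silhouette splatting.

Forward accumulates, per pixel, the log of the transmittance product
``sum_g log(1 - o_g * G_g)`` (or ``-o_g * G_g`` for the exponential response
variant); the silhouette is ``alpha = 1 - exp(acc)``. Backward distributes a
per-pixel upstream gradient dL/dalpha to each splat's 2D mean, 2D std and
opacity.

Each splat touches the square patch of pixels within ``cutoff`` standard
deviations of its projected mean. To keep the rendering a continuous (hence
finite-difference-consistent) function of the splat parameters, the Gaussian
is multiplied by a C1 smoothstep window in u = d^2 / sigma^2 that equals 1
inside (cutoff - 1) sigma and falls to exactly 0 at the cutoff radius, so a
patch sliding across the pixel grid never introduces jumps. At a splat's
center the window is 1 and the compositing closed forms are exact.
"""

import numpy as np
from numba import njit

VARIANT_PRODUCT = 0
VARIANT_EXPONENTIAL = 1


@njit(cache=True, fastmath=False)
def _window(u, u0, u1):
    """C1 smoothstep from 1 (u <= u0) to 0 (u >= u1); returns (w, dw/du)."""
    if u <= u0:
        return 1.0, 0.0
    if u >= u1:
        return 0.0, 0.0
    s = (u1 - u) / (u1 - u0)
    w = s * s * (3.0 - 2.0 * s)
    dw = -(6.0 * s - 6.0 * s * s) / (u1 - u0)
    return w, dw


@njit(cache=True)
def splat_forward(mx, my, sp, op, acc, cutoff, variant):
    h, w = acc.shape
    m = mx.shape[0]
    u1 = cutoff * cutoff
    u0 = (cutoff - 1.0) ** 2 if cutoff > 1.0 else 0.0
    for g in range(m):
        s = sp[g]
        o = op[g]
        r = cutoff * s
        x0 = max(int(np.floor(mx[g] - r)), 0)
        x1 = min(int(np.ceil(mx[g] + r)), w - 1)
        y0 = max(int(np.floor(my[g] - r)), 0)
        y1 = min(int(np.ceil(my[g] + r)), h - 1)
        inv_s2 = 1.0 / (s * s)
        for y in range(y0, y1 + 1):
            dy = y + 0.5 - my[g]
            for x in range(x0, x1 + 1):
                dx = x + 0.5 - mx[g]
                u = (dx * dx + dy * dy) * inv_s2
                if u >= u1:
                    continue
                win, _ = _window(u, u0, u1)
                a = o * np.exp(-0.5 * u) * win
                if variant == VARIANT_PRODUCT:
                    if a > 1.0 - 1e-12:
                        a = 1.0 - 1e-12
                    acc[y, x] += np.log1p(-a)
                else:
                    acc[y, x] += -a
    return acc


@njit(cache=True)
def splat_backward(mx, my, sp, op, prod, dlda, cutoff, variant,
                   dmx, dmy, dsp, dop):
    h, w = prod.shape
    m = mx.shape[0]
    u1 = cutoff * cutoff
    u0 = (cutoff - 1.0) ** 2 if cutoff > 1.0 else 0.0
    for g in range(m):
        s = sp[g]
        o = op[g]
        r = cutoff * s
        x0 = max(int(np.floor(mx[g] - r)), 0)
        x1 = min(int(np.ceil(mx[g] + r)), w - 1)
        y0 = max(int(np.floor(my[g] - r)), 0)
        y1 = min(int(np.ceil(my[g] + r)), h - 1)
        inv_s2 = 1.0 / (s * s)
        for y in range(y0, y1 + 1):
            dy = y + 0.5 - my[g]
            for x in range(x0, x1 + 1):
                up = dlda[y, x]
                if up == 0.0:
                    continue
                dx = x + 0.5 - mx[g]
                d2 = dx * dx + dy * dy
                u = d2 * inv_s2
                if u >= u1:
                    continue
                win, dwin = _window(u, u0, u1)
                gg = np.exp(-0.5 * u)
                val = gg * win  # windowed Gaussian response
                a = o * val
                if variant == VARIANT_PRODUCT:
                    if a > 1.0 - 1e-12:
                        a = 1.0 - 1e-12
                    # d alpha / d a = prod_{h != g}(1 - a_h) = prod / (1 - a)
                    c = up * prod[y, x] / (1.0 - a)
                else:
                    # alpha = 1 - exp(-sum a): d alpha / d a = prod
                    c = up * prod[y, x]
                dop[g] += c * val
                # d val / d u, then u = d2 / s^2
                dval_du = gg * (-0.5 * win + dwin)
                co = c * o
                dmx[g] += co * dval_du * (-2.0 * dx * inv_s2)
                dmy[g] += co * dval_du * (-2.0 * dy * inv_s2)
                dsp[g] += co * dval_du * (-2.0 * d2 * inv_s2 / s)
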