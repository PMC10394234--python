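"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: the single-sphere
potential is the textbook closed form, the ANOVA is the raw
sum-of-squares decomposition, and the peak detector is a brute-force
scan.
"""

from __future__ import annotations

import numpy as np


def single_sphere_potential(radius, conductivity, dip_loc, dip_moment, positions):
    """Closed-form surface potential of a dipole in a homogeneous
    conducting sphere with an insulating exterior.

    Derived from the Legendre generating functions
    sum (2n+1) f^(n-1) P_n        = 2 (x - f)/g^3 + (1/g - 1)/f
    sum (2n+1)/n f^(n-1) P_n^1    = sqrt(1-x^2) [2/g^3 + (g+1)/(g u)]
    with g = sqrt(1 - 2 f x + f^2), u = 1 - f x + g.  Moments in nAm,
    output µV, raw (unreferenced) potentials.
    """
    R = radius
    loc = np.asarray(dip_loc, float)
    m = np.asarray(dip_moment, float)
    b = np.linalg.norm(loc)
    if b == 0:
        raise ValueError("oracle requires an off-centre dipole")
    f = b / R
    rhat = loc / b
    pos = np.atleast_2d(positions)
    ehat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    x = np.clip(ehat @ rhat, -1.0, 1.0)
    sin_g = np.sqrt(np.maximum(0.0, 1.0 - x**2))
    that = ehat - x[:, None] * rhat[None, :]
    that /= np.where(sin_g > 1e-12, sin_g, 1.0)[:, None]
    m_r = float(m @ rhat)
    m_t = np.where(sin_g > 1e-12, that @ m, 0.0)
    g = np.sqrt(1.0 - 2.0 * f * x + f * f)
    u = 1.0 - f * x + g
    s_rad = 2.0 * (x - f) / g**3 + (1.0 / g - 1.0) / f
    s_tan = sin_g * (2.0 / g**3 + (g + 1.0) / (g * u))
    v = (m_r * s_rad + m_t * s_tan) / (4.0 * np.pi * conductivity * R**2)
    return v * 1e-3  # nAm -> Am and V -> µV


def anova_f_bruteforce(values, groups):
    """One-way ANOVA F from explicit sums of squares."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    grand = values.mean()
    ssb = ssw = 0.0
    labels = list(dict.fromkeys(groups))
    for g in labels:
        v = values[groups == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    dfb = len(labels) - 1
    dfw = len(values) - len(labels)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def peak_bruteforce(waveform, time_ms, lo, hi):
    """Most negative sample in the closed window by exhaustive scan."""
    best_val, best_t = None, None
    for v, t in zip(waveform, time_ms):
        if lo <= t <= hi and (best_val is None or v < best_val):
            best_val, best_t = float(v), float(t)
    return best_val, best_t


def pearson_bruteforce(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd, yd = x - x.mean(), y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))
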