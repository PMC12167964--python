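"""Independent oracles and small utilities shared across tests.

The oracles deliberately avoid the code paths they check: the chemistry
oracle locates the pH root by dense grid scan rather than Newton/Brent,
and the decay-fit oracle minimizes anchor misfit over a brute-force
(a, k) parameter grid.
"""

from __future__ import annotations

import math

import numpy as np

from reefcarb.carbchem import EquilibriumConstants


def alk_residual_grid(ph: np.ndarray, dic: float, alk: float, ks: EquilibriumConstants):
    h = 10.0 ** (-ph)
    denom = h * h + ks.k1 * h + ks.k1 * ks.k2
    carb = dic * (ks.k1 * h + 2.0 * ks.k1 * ks.k2) / denom
    borate = ks.bt * ks.kb / (ks.kb + h)
    return carb + borate + ks.kw / h - h - alk


def grid_scan_pco2(dic: float, alk: float, ks: EquilibriumConstants) -> float:
    """Brute-force pH grid scan at 1e-5 resolution; pCO2 in uatm.

    Coarse pass over pH in [2, 12] at 1e-3, refined to 1e-5 around the
    minimum-|residual| node.  Inputs in mol kg-1.
    """
    ph = np.arange(2.0, 12.0, 1e-3)
    res = np.abs(alk_residual_grid(ph, dic, alk, ks))
    best = ph[int(np.argmin(res))]
    fine = np.arange(best - 2e-3, best + 2e-3, 1e-5)
    res = np.abs(alk_residual_grid(fine, dic, alk, ks))
    ph_star = fine[int(np.argmin(res))]
    h = 10.0 ** (-ph_star)
    co2 = dic * h * h / (h * h + ks.k1 * h + ks.k1 * ks.k2)
    return co2 / ks.k0 * 1e6


def grid_scan_decay_fit(anchors, a_range, k_range, n_a=2001, n_k=2001):
    """Brute-force (a, k) scan minimizing squared anchor misfit.

    For each (a, k), b is fixed by the first anchor (b = y0 - a); returns
    the (a, b, k) with minimum summed squared misfit at the other anchors.
    """
    (t0, y0), (t1, y1), (t2, y2) = anchors.points
    a = np.linspace(*a_range, n_a)[:, None]
    k = np.linspace(*k_range, n_k)[None, :]
    b = y0 - a
    m1 = a + b * np.exp(-k * (t1 - t0)) - y1
    m2 = a + b * np.exp(-k * (t2 - t0)) - y2
    cost = m1 * m1 + m2 * m2
    i, j = np.unravel_index(int(np.argmin(cost)), cost.shape)
    return float(a[i, 0]), float(y0 - a[i, 0]), float(k[0, j])


def round_sig(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)
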