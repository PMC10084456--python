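"""Deviation statistics and method comparison.

AD is the absolute deviation of a computed isotropic shielding from its
reference value; the MAD of an element within a molecule is the mean of the
ADs over all nuclei of that element.  Two methods are compared by the
classical two-sample variance-ratio F test on their MAD sets (larger variance
in the numerator, two-sided p from the F distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["DeviationStats", "absolute_deviation", "mad_by_element", "median_mad", "f_test"]


def absolute_deviation(sigma: float, lam_ref: float) -> float:
    """AD = |sigma - lambda| in ppm."""
    if not (np.isfinite(sigma) and np.isfinite(lam_ref)):
        raise ValueError("shielding and reference must be finite")
    return abs(sigma - lam_ref)


def mad_by_element(devs, elements) -> dict[str, float]:
    """Mean AD per element group (the per-molecule MAD convention)."""
    devs = np.asarray(list(devs), dtype=float)
    elements = list(elements)
    if len(devs) == 0 or len(devs) != len(elements):
        raise ValueError("need matching, nonempty AD and element sequences")
    out: dict[str, list[float]] = {}
    for d, e in zip(devs, elements):
        out.setdefault(e, []).append(float(d))
    return {e: float(np.mean(v)) for e, v in out.items()}


def median_mad(mads) -> float:
    """Median of per-molecule MADs."""
    m = np.asarray(list(mads), dtype=float)
    if m.size == 0:
        raise ValueError("empty MAD set")
    return float(np.median(m))


@dataclass
class DeviationStats:
    ads: np.ndarray
    elements: tuple[str, ...]

    @property
    def mads(self) -> dict[str, float]:
        return mad_by_element(self.ads, self.elements)


def f_test(mads_a, mads_b, level: float = 0.01):
    """Variance-ratio F test between two MAD sets.

    Returns (F, p, significant) with the larger sample variance in the
    numerator and a two-sided p-value; symmetric in the argument order.
    """
    a = np.asarray(list(mads_a), dtype=float)
    b = np.asarray(list(mads_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each MAD set needs at least 2 entries")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both samples have zero variance; F statistic undefined")
    if va >= vb:
        F, dfn, dfd = (va / vb if vb > 0 else np.inf), a.size - 1, b.size - 1
    else:
        F, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = float(min(1.0, 2.0 * sps.f.sf(F, dfn, dfd))) if np.isfinite(F) else 0.0
    return float(F), p, p < level
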