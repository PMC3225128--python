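"""Global histogram thresholding: Otsu, IsoData, Li, Huang, Yen, Renyi.

All six methods operate on the pooled histogram of the whole stack and
return one integer threshold ``theta`` under the convention that a voxel is
foreground iff its intensity is strictly greater than ``theta`` (the
ImageJ Auto_Threshold convention). Criterion plateaus break ties toward the
smallest optimal threshold.

The per-method numerics follow the de-facto reference implementations:

* ``otsu``    — between-class variance maximisation.
* ``isodata`` — Ridler-Calvard fixed-point iteration from the global mean.
* ``li``     — iterative minimum cross entropy.
* ``huang``  — minimum Shannon fuzziness of the membership function
  ``u(i) = 1 / (1 + |i - mu_class| / C)`` with ``C`` the dynamic range.
* ``yen``    — maximum entropic-correlation criterion.
* ``renyi``  — Sahoo's combination of the thresholds at Renyi orders
  ``rho -> 1`` (Shannon), ``rho = 0.5`` and ``rho = 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateHistogramError, ValidationError
from .stack_io import BinaryMask, IntensityStack

METHODS = ("otsu", "isodata", "li", "huang", "yen", "renyi")

_EPS = 2.220446049250313e-16


@dataclass
class Histogram:
    """Intensity histogram of a whole stack (one bin per grey level)."""

    counts: np.ndarray
    bit_depth: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValidationError("histogram counts must be a 1D array")
        if self.counts.size and int(self.counts.min()) < 0:
            raise ValidationError("histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ThresholdResult:
    """Chosen threshold; foreground rule is intensity > theta."""

    method: str
    theta: int


def stack_histogram(stack: IntensityStack) -> Histogram:
    """Pooled histogram over every slice: 256 bins at 8-bit, 65536 at 16."""
    nbins = 1 << stack.bit_depth
    counts = np.bincount(stack.voxels.ravel().astype(np.int64), minlength=nbins)
    return Histogram(counts=counts, bit_depth=stack.bit_depth)


def auto_threshold(hist: Histogram, method: str) -> ThresholdResult:
    """Compute a global threshold from a histogram by the named method."""
    method = method.lower()
    if method not in METHODS:
        raise ValidationError(f"unknown threshold method {method!r}; choose from {METHODS}")
    if np.count_nonzero(hist.counts) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two populated bins; no threshold separates it"
        )
    theta = _DISPATCH[method](hist.counts)
    return ThresholdResult(method=method, theta=int(theta))


def threshold_stack(stack: IntensityStack, method: str) -> ThresholdResult:
    """Convenience wrapper: histogram the stack, then threshold it."""
    return auto_threshold(stack_histogram(stack), method)


def apply_threshold_result(stack: IntensityStack, result: ThresholdResult) -> BinaryMask:
    """Foreground mask under the strict > theta rule."""
    return BinaryMask(
        mask=(stack.voxels > result.theta).astype(np.uint8), calibration=stack.calibration
    )


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def otsu_criterion(counts: np.ndarray) -> np.ndarray:
    """Between-class variance for every candidate threshold t (background <= t).

    Invalid candidates (one class empty) get -inf.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    p = counts / total
    idx = np.arange(counts.size, dtype=np.float64)
    omega = np.cumsum(p)
    mu = np.cumsum(idx * p)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    sigma_b[(omega <= 0) | (omega >= 1)] = -np.inf
    return sigma_b


def _otsu(counts: np.ndarray) -> int:
    return int(np.argmax(otsu_criterion(counts)))


def _isodata(counts: np.ndarray) -> int:
    counts = np.asarray(counts, dtype=np.float64)
    idx = np.arange(counts.size, dtype=np.float64)
    total = counts.sum()
    nz = np.flatnonzero(counts)
    first, last = int(nz[0]), int(nz[-1])
    t = int(round(float((idx * counts).sum() / total)))
    t = min(max(t, first), last - 1)
    seen = set()
    while t not in seen:
        seen.add(t)
        n_below = counts[: t + 1].sum()
        n_above = counts[t + 1 :].sum()
        if n_below == 0:
            t += 1
            continue
        if n_above == 0:
            t -= 1
            continue
        mu_below = (idx[: t + 1] * counts[: t + 1]).sum() / n_below
        mu_above = (idx[t + 1 :] * counts[t + 1 :]).sum() / n_above
        t_new = int(round((mu_below + mu_above) / 2.0))
        t_new = min(max(t_new, first), last - 1)
        if t_new == t:
            break
        t = t_new
    return t


def _li(counts: np.ndarray) -> int:
    counts = np.asarray(counts, dtype=np.float64)
    idx = np.arange(counts.size, dtype=np.float64)
    total = counts.sum()
    tolerance = 0.5
    t_new = float((idx * counts).sum() / total)
    threshold = int(t_new + 0.5)
    t_old = -2.0 * tolerance  # force at least one iteration
    while abs(t_new - t_old) > tolerance:
        t_old = t_new
        threshold = int(t_old + 0.5)
        n_back = counts[: threshold + 1].sum()
        n_obj = counts[threshold + 1 :].sum()
        mean_back = (idx[: threshold + 1] * counts[: threshold + 1]).sum() / n_back if n_back else 0.0
        mean_obj = (idx[threshold + 1 :] * counts[threshold + 1 :]).sum() / n_obj if n_obj else 0.0
        log_back = math.log(mean_back) if mean_back > 0 else -math.inf
        log_obj = math.log(mean_obj) if mean_obj > 0 else -math.inf
        if log_back == log_obj:
            break
        diff = log_back - log_obj
        if math.isinf(diff):
            temp = 0.0
        else:
            temp = (mean_back - mean_obj) / diff
        t_new = float(int(temp - 0.5)) if temp < -_EPS else float(int(temp + 0.5))
    return threshold


def _fuzzy_entropy(u: np.ndarray) -> np.ndarray:
    """Shannon entropy of membership values; saturated memberships give 0."""
    out = np.zeros_like(u)
    interior = (u > 1e-6) & (u < 1.0 - 1e-6)
    ui = u[interior]
    out[interior] = -ui * np.log(ui) - (1.0 - ui) * np.log(1.0 - ui)
    return out


def huang_criterion(counts: np.ndarray) -> np.ndarray:
    """Huang-Wang fuzziness for every candidate threshold; invalid -> +inf."""
    counts = np.asarray(counts, dtype=np.float64)
    idx = np.arange(counts.size, dtype=np.float64)
    nz = np.flatnonzero(counts)
    first, last = int(nz[0]), int(nz[-1])
    c_range = float(last - first)
    crit = np.full(counts.size, np.inf)
    nz_idx = idx[nz]
    nz_counts = counts[nz]
    for t in range(first, last):
        back = nz_idx <= t
        fore = ~back
        n_back = nz_counts[back].sum()
        n_fore = nz_counts[fore].sum()
        if n_back == 0 or n_fore == 0:
            continue
        mu_back = (nz_idx[back] * nz_counts[back]).sum() / n_back
        mu_fore = (nz_idx[fore] * nz_counts[fore]).sum() / n_fore
        u_back = 1.0 / (1.0 + np.abs(nz_idx[back] - mu_back) / c_range)
        u_fore = 1.0 / (1.0 + np.abs(nz_idx[fore] - mu_fore) / c_range)
        crit[t] = (nz_counts[back] * _fuzzy_entropy(u_back)).sum() + (
            nz_counts[fore] * _fuzzy_entropy(u_fore)
        ).sum()
    return crit


def _huang(counts: np.ndarray) -> int:
    return int(np.argmin(huang_criterion(counts)))


def yen_criterion(counts: np.ndarray) -> np.ndarray:
    """Yen's entropic-correlation criterion; invalid candidates get -inf."""
    counts = np.asarray(counts, dtype=np.float64)
    p = counts / counts.sum()
    p1 = np.cumsum(p)
    p1_sq = np.cumsum(p * p)
    p2_sq = p1_sq[-1] - p1_sq
    crit = np.full(counts.size, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(p1_sq * p2_sq > 0, -np.log(p1_sq * p2_sq), 0.0)
        term2 = np.where(p1 * (1.0 - p1) > 0, 2.0 * np.log(p1 * (1.0 - p1)), 0.0)
    valid = (p1 > 0) & (p1 < 1)
    crit[valid] = (term1 + term2)[valid]
    return crit


def _yen(counts: np.ndarray) -> int:
    return int(np.argmax(yen_criterion(counts)))


def renyi_criterion(counts: np.ndarray, rho: float) -> np.ndarray:
    """Sum of background and foreground Renyi entropies of order ``rho``.

    ``rho = 1`` is the Shannon (Kapur) limit. Invalid candidates get -inf.
    """
    counts = np.asarray(counts, dtype=np.float64)
    p = counts / counts.sum()
    p1 = np.cumsum(p)
    crit = np.full(counts.size, -np.inf)
    valid = (p1 > 0) & (p1 < 1)
    if rho == 1.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        cum_plogp = np.cumsum(plogp)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_back = np.log(p1) - cum_plogp / p1
            h_fore = np.log(1.0 - p1) - (cum_plogp[-1] - cum_plogp) / (1.0 - p1)
    else:
        prho = np.cumsum(p**rho)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_back = (np.log(prho) - rho * np.log(p1)) / (1.0 - rho)
            h_fore = (np.log(prho[-1] - prho) - rho * np.log(1.0 - p1)) / (1.0 - rho)
    total = h_back + h_fore
    crit[valid] = total[valid]
    crit[~np.isfinite(crit)] = -np.inf
    return crit


def _renyi(counts: np.ndarray) -> int:
    counts = np.asarray(counts, dtype=np.float64)
    p = counts / counts.sum()
    p1 = np.cumsum(p)
    t_half = int(np.argmax(renyi_criterion(counts, 0.5)))
    t_one = int(np.argmax(renyi_criterion(counts, 1.0)))
    t_two = int(np.argmax(renyi_criterion(counts, 2.0)))
    t1, t2, t3 = sorted((t_half, t_one, t_two))
    # Sahoo-Wilkins-Yeager combination weights, as in the reference plugin.
    if abs(t1 - t2) <= 5:
        if abs(t2 - t3) <= 5:
            beta1, beta2, beta3 = 1, 2, 1
        else:
            beta1, beta2, beta3 = 0, 1, 3
    else:
        if abs(t2 - t3) <= 5:
            beta1, beta2, beta3 = 3, 1, 0
        else:
            beta1, beta2, beta3 = 1, 2, 1
    omega = p1[t3] - p1[t1]
    opt = (
        t1 * (p1[t1] + 0.25 * omega * beta1)
        + 0.25 * t2 * omega * beta2
        + t3 * (1.0 - p1[t3] + 0.25 * omega * beta3)
    )
    return int(opt)


_DISPATCH = {
    "otsu": _otsu,
    "isodata": _isodata,
    "li": _li,
    "huang": _huang,
    "yen": _yen,
    "renyi": _renyi,
}
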