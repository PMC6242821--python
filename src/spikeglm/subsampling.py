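"""Hidden-input (subsampling) account of over-dispersed spike counts.

Unrecorded neurons contribute a fluctuating current h_hid to each observed
neuron; marginalizing a conditionally-Poisson generator over p(h_hid),

    p(S | H) = ∫ Poisson(S | f[H + h_hid]) p(h_hid) dh_hid,

yields super-Poisson counts.  The integral is evaluated by Monte Carlo with
h_hid drawn either from a Gaussian or from a scaled-and-shifted resampling
of empirical currents, and the (shift, scale) pair can be fitted so the
mixture's first two count moments match a target (e.g. a negative
binomial's), for comparison by total-variation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .distributions import transfer


@dataclass
class HiddenInputSpec:
    """Distribution of the hidden input current.

    family "gaussian": h_hid = shift + scale·z, z ~ N(0, 1).
    family "scaled_empirical": h_hid = shift + scale·H_k with H_k resampled
    from ``source`` (empirical current samples).
    """

    family: str = "gaussian"
    shift: float = 0.0
    scale: float = 1.0
    source: np.ndarray = field(default=None, repr=False)
    n_mc: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("gaussian", "scaled_empirical"):
            raise ValueError(f"unknown hidden-input family {self.family!r}")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if self.n_mc < 1:
            raise ValueError("n_mc must be at least 1")
        if self.family == "scaled_empirical":
            if self.source is None or len(np.atleast_1d(self.source)) == 0:
                raise ValueError("scaled_empirical requires non-empty source samples")
            self.source = np.asarray(self.source, float)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        if self.family == "gaussian":
            return self.shift + self.scale * rng.standard_normal(self.n_mc)
        picks = rng.choice(self.source, size=self.n_mc, replace=True)
        return self.shift + self.scale * picks


# Truncation of pmf supports: keep mass beyond S_max below this.
TRUNCATION_MASS = 1e-10


def _support(max_lam: float) -> np.ndarray:
    s_max = int(poisson.ppf(1.0 - TRUNCATION_MASS / 10.0, max(max_lam, 1e-3))) + 5
    return np.arange(s_max + 1)


def mixture_count_pmf(H: float, hidden: HiddenInputSpec, variant: str,
                      lambda_inf: float = None, gamma: float = None,
                      rng: np.random.Generator = None):
    """Monte-Carlo marginal count pmf under hidden inputs.

    p(S|H) ≈ (1/n_mc) Σ_k Poisson(S | f[H + h_k]).  Returns (support, pmf);
    the support is truncated where the residual mass is below 1e−10.
    """
    if rng is None:
        rng = np.random.default_rng(hidden.seed)
    lam = transfer(H + hidden.draw(rng), variant, lambda_inf, gamma)
    support = _support(float(lam.max()))
    # average Poisson pmfs over the MC rate sample, batched over support
    pmf = poisson.pmf(support[:, None], lam[None, :]).mean(axis=1)
    return support, pmf


def mixture_moments(H: float, hidden: HiddenInputSpec, variant: str,
                    lambda_inf: float = None, gamma: float = None,
                    rng: np.random.Generator = None):
    """Mean and variance of the mixture counts, computed from the rate
    sample (law of total variance: Var S = E λ + Var λ)."""
    if rng is None:
        rng = np.random.default_rng(hidden.seed)
    lam = transfer(H + hidden.draw(rng), variant, lambda_inf, gamma)
    m = float(lam.mean())
    return m, m + float(lam.var())


def moment_match(family: str, target_mean: float, target_var: float,
                 variant: str = "sig_negbin", lambda_inf: float = 4.0,
                 gamma: float = 1.0, source: np.ndarray = None,
                 n_mc: int = 100_000, seed: int = 0,
                 tol: float = 1e-3, max_iter: int = 60) -> HiddenInputSpec:
    """Fit (shift, scale) of the hidden-input law so the Poisson mixture's
    count mean and variance match targets.

    Requires super-Poisson targets (variance ≥ mean).  Solved by nested
    bisection with common random numbers: for any scale the mixture mean is
    strictly increasing in shift, and at the mean-matched shift the
    variance is increasing in scale.
    """
    if target_var < target_mean * (1.0 - 1e-9):
        raise ValueError("infeasible sub-Poisson targets: variance < mean")
    if target_mean <= 0:
        raise ValueError("target mean must be positive")
    if target_mean >= lambda_inf and variant.startswith("sig"):
        raise ValueError("target mean exceeds the transfer ceiling lambda_inf")
    rng = np.random.default_rng(seed)
    if family == "gaussian":
        base = rng.standard_normal(n_mc)
    else:
        if source is None or len(source) == 0:
            raise ValueError("scaled_empirical requires source samples")
        src = np.asarray(source, float)
        base = rng.choice(src, size=n_mc, replace=True)

    def moments(shift, scale):
        lam = transfer(shift + scale * base, variant, lambda_inf, gamma)
        m = float(lam.mean())
        return m, m + float(lam.var())

    def shift_for_mean(scale):
        lo, hi = -60.0, 60.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if moments(mid, scale)[0] < target_mean:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-12:
                break
        return 0.5 * (lo + hi)

    # bracket the scale
    lo_s, hi_s = 0.0, 1.0
    for _ in range(40):
        sh = shift_for_mean(hi_s)
        if moments(sh, hi_s)[1] >= target_var:
            break
        hi_s *= 2.0
    else:
        raise ValueError("target variance unreachable for this transfer")
    for _ in range(max_iter):
        mid = 0.5 * (lo_s + hi_s)
        sh = shift_for_mean(mid)
        _, v = moments(sh, mid)
        if v < target_var:
            lo_s = mid
        else:
            hi_s = mid
        if hi_s - lo_s < tol * max(hi_s, 1e-9):
            break
    scale = 0.5 * (lo_s + hi_s)
    shift = shift_for_mean(scale)
    return HiddenInputSpec(family=family, shift=shift, scale=scale,
                           source=None if family == "gaussian" else src,
                           n_mc=n_mc, seed=seed)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two pmfs on a common 0..S grid
    (shorter one zero-padded)."""
    n = max(len(p), len(q))
    pp = np.zeros(n); pp[:len(p)] = p
    qq = np.zeros(n); qq[:len(q)] = q
    return 0.5 * float(np.abs(pp - qq).sum())
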