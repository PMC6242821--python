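"""Transfer functions, spike-count distributions and dispersion calibration.

Two current-to-rate transfer functions: exponential f(H) = exp(H), and a
saturating asymmetric sigmoid f(H) = λ∞ / (1 + exp(−H))^γ.  Two count
generators, Poisson and negative binomial (NegBin) with fixed dispersion
r_NB: mean λ, variance λ(1 + λ/r_NB), converging to Poisson as r_NB → ∞.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

# Floor for rates inside log-pmfs; avoids -inf at S > 0 when a rate
# underflows to zero.
LAMBDA_FLOOR = 1e-12

# Cap on exponential-transfer currents; exp(30) counts/bin is far beyond any
# physical rate and prevents overflow during early optimizer epochs.
_EXP_H_MAX = 30.0

VARIANTS = ("exp_poisson", "sig_negbin", "sig_poisson", "exp_negbin")


def is_sigmoid(variant: str) -> bool:
    _check_variant(variant)
    return variant.startswith("sig")


def is_negbin(variant: str) -> bool:
    _check_variant(variant)
    return variant.endswith("negbin")


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")


def log_sigmoid(H):
    """log σ(H) computed without overflow for any H."""
    return -np.logaddexp(0.0, -np.asarray(H, float))


def transfer(H, variant: str, lambda_inf: float = None, gamma: float = None):
    """Expected spike count λ = f(H) for the variant's transfer function.

    Exponential variants: λ = exp(H) (current capped for overflow safety).
    Sigmoid variants: λ = λ∞ σ(H)^γ, bounded in (0, λ∞), with γ > 0 setting
    the asymmetry between the low- and high-input approach to the bounds.
    """
    H = np.asarray(H, float)
    if is_sigmoid(variant):
        if lambda_inf is None or gamma is None:
            raise ValueError("sigmoid transfer requires lambda_inf and gamma")
        if lambda_inf <= 0 or gamma <= 0:
            raise ValueError("lambda_inf and gamma must be positive")
        return lambda_inf * np.exp(gamma * log_sigmoid(H))
    return np.exp(np.minimum(H, _EXP_H_MAX))


def transfer_dH(H, variant: str, lambda_inf: float = None, gamma: float = None):
    """Derivative dλ/dH of the transfer function."""
    H = np.asarray(H, float)
    lam = transfer(H, variant, lambda_inf, gamma)
    if is_sigmoid(variant):
        return lam * gamma * np.exp(log_sigmoid(-H))  # λ γ (1 − σ(H))
    return lam * (H < _EXP_H_MAX)


def poisson_logpmf(S, lam):
    lam = np.maximum(np.asarray(lam, float), LAMBDA_FLOOR)
    S = np.asarray(S, float)
    return S * np.log(lam) - lam - gammaln(S + 1.0)


def negbin_logpmf(S, lam, r: float):
    """Negative binomial log-pmf with mean lam and dispersion r."""
    if r <= 0:
        raise ValueError("r_nb must be positive")
    lam = np.maximum(np.asarray(lam, float), LAMBDA_FLOOR)
    S = np.asarray(S, float)
    return (gammaln(S + r) - gammaln(r) - gammaln(S + 1.0)
            + S * (np.log(lam) - np.log(lam + r))
            + r * (np.log(r) - np.log(lam + r)))


def count_logpmf(S, lam, variant: str, r_nb: float = None):
    """Log-probability of counts under the variant's generator."""
    if is_negbin(variant):
        if r_nb is None:
            raise ValueError("NegBin variants require r_nb")
        return negbin_logpmf(S, lam, r_nb)
    return poisson_logpmf(S, lam)


def count_pmf(S, lam, variant: str, r_nb: float = None):
    S = np.asarray(S)
    if np.any(S < 0) or np.any(S != np.floor(S)):
        raise ValueError("counts must be non-negative integers")
    if np.any(np.asarray(lam, float) < 0):
        raise ValueError("rates must be non-negative")
    return np.exp(count_logpmf(S, lam, variant, r_nb))


def dlogpmf_dlam(S, lam, variant: str, r_nb: float = None):
    """∂ log p(S|λ) / ∂λ; NegBin: S/λ − (S+r)/(λ+r); Poisson: S/λ − 1."""
    lam = np.maximum(np.asarray(lam, float), LAMBDA_FLOOR)
    S = np.asarray(S, float)
    if is_negbin(variant):
        return S / lam - (S + r_nb) / (lam + r_nb)
    return S / lam - 1.0


def sample_counts(lam, variant: str, rng: np.random.Generator,
                  r_nb: float = None):
    """Draw independent counts per entry of lam from the variant's generator."""
    lam = np.asarray(lam, float)
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    if is_negbin(variant):
        if r_nb is None or r_nb <= 0:
            raise ValueError("NegBin sampling requires r_nb > 0")
        p = r_nb / (r_nb + lam)
        return rng.negative_binomial(r_nb, p)
    return rng.poisson(lam)


def calibrate_r_nb(median_count: float, threshold_multiple: float = 5.0,
                   target_ratio: float = 2.0) -> float:
    """Fix the NegBin dispersion from the recording's sparseness.

    With m the median (across neurons) of the time-averaged per-bin spike
    count, the rate threshold separating down-states from bursts is taken at
    ``threshold_multiple``·m, and r_NB is chosen so the variance-to-mean
    ratio at that rate equals ``target_ratio``:

        1 + threshold_multiple·m / r_NB = target_ratio
        ⇒  r_NB = threshold_multiple·m / (target_ratio − 1).

    At the reference sparseness m = 0.037 and defaults this gives
    r_NB = 0.185 ≈ 0.2.
    """
    if median_count <= 0:
        raise ValueError("median count must be positive")
    if target_ratio <= 1:
        raise ValueError("target variance-to-mean ratio must exceed 1")
    return threshold_multiple * median_count / (target_ratio - 1.0)
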