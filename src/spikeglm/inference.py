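"""Maximum-likelihood fitting: log-likelihood, analytic gradients, iRprop+.

The data log-likelihood is evaluated in driven (teacher-forced) mode,

    LL = Σ_u Σ_i log p(S_i(u) | λ_i(u)),    λ_i(u) = f[H_i(u−1 history)],

summing over bins u ≥ M (the first M = 150 ms / dt bins serve as history
context only).  Gradients are fully analytic, including the SFA-timescale
sensitivities, with positivity-constrained parameters (τ, λ∞, γ) optimized
in the log domain.  Optimization uses iRprop+, a sign-based resilient
update with per-parameter step sizes and backtracking on error increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SpikeCountMatrix
from .distributions import (count_logpmf, dlogpmf_dlam, is_sigmoid, log_sigmoid,
                            transfer, transfer_dH)
from .dynamics import current_series, history_regressors, sfa_tau_sensitivity, sfa_trace
from .params import ModelParams, N_SFA, default_params


def count_parameters(variant: str, n_neurons: int) -> int:
    """Number of inferred parameters in the standard accounting.

    Exponential variants fit all kernel coefficients (4 per off-diagonal
    pair, 6 per self-kernel): 4·N(N−1) + 6·N.  Sigmoid variants fit only
    off-diagonal kernels plus 5 SFA gains, 5 SFA timescales, λ∞ and γ:
    4·N(N−1) + 10 + 2.  At N = 60 the difference is 348 (about +2.5%).
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if variant in ("exp_poisson", "exp_negbin"):
        return 4 * n_neurons * (n_neurons - 1) + 6 * n_neurons
    if variant in ("sig_negbin", "sig_poisson"):
        return 4 * n_neurons * (n_neurons - 1) + 10 + 2
    raise ValueError(f"unknown model variant {variant!r}")


@dataclass
class FitConfig:
    """iRprop+ fitting configuration.

    ``trainable`` lists parameter blocks among {"weights", "diag_weights",
    "h", "g_sfa", "log_tau", "log_lambda_inf", "log_gamma"}; None selects
    the variant's standard set.
    """

    variant: str = "sig_negbin"
    trainable: tuple = None
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    step_init: float = 1e-3
    step_min: float = 1e-8
    step_max: float = 1.0
    max_epochs: int = 500
    tol: float = 1e-7          # relative LL change
    patience: int = 10         # epochs below tol before stopping
    seed: int = 0

    def __post_init__(self):
        if not (self.eta_plus > 1.0 > self.eta_minus > 0.0):
            raise ValueError("require eta_plus > 1 > eta_minus > 0")
        if not (self.step_min <= self.step_init <= self.step_max):
            raise ValueError("require step_min <= step_init <= step_max")
        if self.trainable is None:
            self.trainable = default_trainable(self.variant)
        self.trainable = tuple(self.trainable)


@dataclass
class FitResult:
    params: ModelParams
    ll_trace: np.ndarray
    converged: bool
    n_epochs: int = 0
    best_ll: float = field(default=-np.inf)


def default_trainable(variant: str) -> tuple:
    if is_sigmoid(variant):
        return ("weights", "h", "g_sfa", "log_tau", "log_lambda_inf", "log_gamma")
    return ("weights", "diag_weights", "h")


# ---------------------------------------------------------------------------
# likelihood and gradient

def _burn_in(params: ModelParams) -> int:
    return params.n_lags


def _rates(data: SpikeCountMatrix, params: ModelParams, workspace: dict = None):
    S = data.counts
    X_off = X_diag = None
    if workspace is not None:
        X_off = workspace.get("X_off")
        X_diag = workspace.get("X_diag")
    H, c, X_off, X_diag = current_series(S, params, X_off=X_off, X_diag=X_diag,
                                         return_parts=True)
    if workspace is not None:
        workspace["X_off"] = X_off
        if X_diag is not None:
            workspace["X_diag"] = X_diag
    if is_sigmoid(params.variant):
        ls = log_sigmoid(H)  # computed once; λ and dλ/dH both derive from it
        lam = params.lambda_inf * np.exp(params.gamma * ls)
    else:
        ls = None
        lam = transfer(H, params.variant)
    return H, lam, ls, c, X_off, X_diag


def log_likelihood(data: SpikeCountMatrix, params: ModelParams,
                   workspace: dict = None) -> float:
    """Teacher-forced log-likelihood of the counts under the model."""
    if data.dt != params.dt:
        raise ValueError("data and params bin widths differ")
    u0 = _burn_in(params)
    if data.n_bins <= u0:
        raise ValueError(f"need more than {u0} bins of data (150 ms history "
                         "plus at least one evaluable bin)")
    _, lam, _, _, _, _ = _rates(data, params, workspace)
    ll = count_logpmf(data.counts[:, u0:], lam[:, u0:], params.variant,
                      params.r_nb).sum()
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return float(ll)


def grad_log_likelihood(data: SpikeCountMatrix, params: ModelParams,
                        trainable: tuple = None,
                        workspace: dict = None):
    """Analytic gradient of the log-likelihood.

    Returns ``(ll, grads)`` where ``grads`` maps each trainable block name
    to an array shaped like the corresponding parameter block; τ, λ∞ and γ
    gradients are with respect to their logarithms.
    """
    if trainable is None:
        trainable = default_trainable(params.variant)
    u0 = _burn_in(params)
    S = data.counts
    N, T = S.shape
    H, lam, ls, c, X_off, X_diag = _rates(data, params, workspace)
    Sf = S.astype(float)

    dlp = dlogpmf_dlam(Sf, lam, params.variant, params.r_nb)
    ll = count_logpmf(Sf[:, u0:], lam[:, u0:], params.variant, params.r_nb).sum()
    # response r_i(u) = dlogp/dλ · dλ/dH, zeroed on burn-in bins
    if is_sigmoid(params.variant):
        # dλ/dH = λ γ (1−σ(H)) with 1−σ(H) = exp(logσ(H) − H)
        dlam_dH = lam * params.gamma * np.exp(ls - H)
    else:
        dlam_dH = transfer_dH(H, params.variant)
    r = dlp * dlam_dH
    r[:, :u0] = 0.0
    dlp[:, :u0] = 0.0

    grads = {}
    if "weights" in trainable:
        L = params.basis_off_diagonal.n_basis
        X2 = X_off.transpose(1, 0, 2).reshape(N * L, T)
        gw = (r @ X2.T).reshape(N, N, L)
        idx = np.arange(N)
        gw[idx, idx, :] = 0.0
        grads["weights"] = gw
    if "diag_weights" in trainable and not is_sigmoid(params.variant):
        grads["diag_weights"] = np.einsum("iu,liu->il", r, X_diag)
    if "h" in trainable:
        grads["h"] = r.sum(axis=1)
    if "g_sfa" in trainable:
        per_tau = -(r[None, :, :] * c).sum(axis=2)  # (5, N)
        if params.g_sfa.ndim == 1:
            grads["g_sfa"] = per_tau.sum(axis=1)
        else:
            grads["g_sfa"] = per_tau.T
    if "log_tau" in trainable:
        d = sfa_tau_sensitivity(Sf, c, params.tau_sfa, params.dt)
        g = params.g_per_neuron()  # (N, 5)
        # dH/dτ_x = −g_i^(x) d_x,i,u ; chain to log τ
        gt = -np.einsum("iu,ix,xiu->x", r, g, d) * params.tau_sfa
        grads["log_tau"] = gt
    if is_sigmoid(params.variant):
        if "log_lambda_inf" in trainable:
            grads["log_lambda_inf"] = np.array([(dlp * lam).sum()])
        if "log_gamma" in trainable:
            grads["log_gamma"] = np.array([(dlp * lam * ls).sum() * params.gamma])
    if not np.all([np.all(np.isfinite(v)) for v in grads.values()]):
        raise FloatingPointError("non-finite gradient")
    return float(ll), grads


# ---------------------------------------------------------------------------
# parameter vector packing

class ParamPacker:
    """Maps the trainable blocks of a ModelParams to/from a flat vector,
    keeping frozen blocks and structural zeros (diagonal weights) intact."""

    def __init__(self, template: ModelParams, trainable: tuple):
        self.template = template
        n = template.n_neurons
        self.trainable = tuple(t for t in trainable
                               if not (t in ("diag_weights",) and is_sigmoid(template.variant))
                               and not (t in ("g_sfa", "log_tau") and not is_sigmoid(template.variant))
                               and not (t in ("log_lambda_inf", "log_gamma")
                                        and not is_sigmoid(template.variant)))
        self._offdiag = ~np.eye(n, dtype=bool)
        sizes = {}
        L = template.basis_off_diagonal.n_basis
        sizes["weights"] = int(self._offdiag.sum()) * L
        sizes["diag_weights"] = template.diag_weights.size
        sizes["h"] = n
        sizes["g_sfa"] = template.g_sfa.size
        sizes["log_tau"] = N_SFA
        sizes["log_lambda_inf"] = 1
        sizes["log_gamma"] = 1
        self.slices = {}
        start = 0
        for name in self.trainable:
            self.slices[name] = slice(start, start + sizes[name])
            start += sizes[name]
        self.size = start

    def pack(self, params: ModelParams) -> np.ndarray:
        v = np.empty(self.size)
        for name, sl in self.slices.items():
            if name == "weights":
                v[sl] = params.weights[self._offdiag].ravel()
            elif name == "diag_weights":
                v[sl] = params.diag_weights.ravel()
            elif name == "h":
                v[sl] = params.h
            elif name == "g_sfa":
                v[sl] = params.g_sfa.ravel()
            elif name == "log_tau":
                v[sl] = np.log(params.tau_sfa)
            elif name == "log_lambda_inf":
                v[sl] = np.log(params.lambda_inf)
            elif name == "log_gamma":
                v[sl] = np.log(params.gamma)
        return v

    def unpack(self, v: np.ndarray) -> ModelParams:
        p = self.template.copy()
        for name, sl in self.slices.items():
            block = v[sl]
            if name == "weights":
                w = p.weights
                w[self._offdiag] = block.reshape(-1, w.shape[2])
            elif name == "diag_weights":
                p.diag_weights = block.reshape(p.diag_weights.shape)
            elif name == "h":
                p.h = block.copy()
            elif name == "g_sfa":
                p.g_sfa = block.reshape(p.g_sfa.shape)
            elif name == "log_tau":
                p.tau_sfa = np.exp(block)
            elif name == "log_lambda_inf":
                p.lambda_inf = float(np.exp(block[0]))
            elif name == "log_gamma":
                p.gamma = float(np.exp(block[0]))
        return p

    def pack_grads(self, grads: dict) -> np.ndarray:
        v = np.zeros(self.size)
        for name, sl in self.slices.items():
            if name not in grads:
                continue
            g = grads[name]
            if name == "weights":
                v[sl] = g[self._offdiag].ravel()
            else:
                v[sl] = np.ravel(g)
        return v


# ---------------------------------------------------------------------------
# initialization and iRprop+

def initial_params(data: SpikeCountMatrix, variant: str,
                   r_nb: float = 0.22) -> ModelParams:
    """Data-informed starting point: zero couplings, intercepts matching
    each neuron's mean count through the transfer function, small SFA
    gains, log-spaced timescales, λ∞ at twice the maximum observed count."""
    n = data.n_neurons
    p = default_params(variant, n, dt=data.dt, r_nb=r_nb)
    mean_counts = np.maximum(data.counts.mean(axis=1), 1e-4)
    if is_sigmoid(variant):
        p.lambda_inf = max(2.0 * data.counts.max(), 1.0)
        p.gamma = 1.0
        # invert λ = λ∞ σ(h) at γ=1
        q = np.clip(mean_counts / p.lambda_inf, 1e-6, 1 - 1e-6)
        p.h = np.log(q / (1.0 - q))
        p.g_sfa = np.full(N_SFA, 0.01)
    else:
        p.h = np.log(mean_counts)
    return p


def irprop_fit(data: SpikeCountMatrix, config: FitConfig,
               init: ModelParams = None) -> FitResult:
    """Fit a model variant by maximum likelihood with iRprop+.

    Per-parameter step sizes grow by η+ when the gradient sign repeats,
    shrink by η− on a sign flip; on a sign flip that coincides with a
    drop in likelihood the previous update of that parameter is reverted
    (iRprop+ backtracking).  Returns the best-likelihood parameters seen.
    """
    if init is None:
        init = initial_params(data, config.variant)
    if init.variant != config.variant:
        raise ValueError("init variant does not match config")
    packer = ParamPacker(init, config.trainable)
    theta = packer.pack(init)
    step = np.full(packer.size, config.step_init)
    prev_grad = np.zeros(packer.size)
    prev_delta = np.zeros(packer.size)
    workspace = {}

    ll_trace = []
    best_ll, best_theta = -np.inf, theta.copy()
    prev_ll = -np.inf
    stall = 0
    converged = False
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        params = packer.unpack(theta)
        ll, grads = grad_log_likelihood(data, params, packer.trainable, workspace)
        ll_trace.append(ll)
        if ll > best_ll:
            best_ll, best_theta = ll, theta.copy()

        grad = packer.pack_grads(grads)
        prod = grad * prev_grad
        step = np.where(prod > 0, np.minimum(step * config.eta_plus, config.step_max),
                        np.where(prod < 0, np.maximum(step * config.eta_minus,
                                                      config.step_min), step))
        delta = np.sign(grad) * step
        flipped = prod < 0
        if ll < prev_ll:
            delta[flipped] = -prev_delta[flipped]  # backtrack
        else:
            delta[flipped] = 0.0
        grad = np.where(flipped, 0.0, grad)

        theta = theta + delta
        prev_grad, prev_delta = grad, delta

        if np.isfinite(prev_ll):
            rel = abs(ll - prev_ll) / max(abs(ll), 1.0)
            stall = stall + 1 if rel < config.tol else 0
            if stall >= config.patience:
                converged = True
                break
        prev_ll = ll

    return FitResult(params=packer.unpack(best_theta),
                     ll_trace=np.array(ll_trace), converged=converged,
                     n_epochs=epoch, best_ll=best_ll)
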