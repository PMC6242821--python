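"""Network state dynamics: SFA currents, history filtering, input currents.

Time-indexing convention used throughout the package: the rate of bin u is
λ(u) = f[H(u)], where H(u) is computed from spike counts at bins
u−1, …, u−M (lags dt … 150 ms, M = 150 ms / dt) and from the SFA state c(u),
which itself integrates counts through bin u−1:

    c^(x)(u) = c^(x)(u−1)·(1 − dt/τ^(x)) + S(u−1)·(dt/τ^(x)).

Counts in bin u never influence λ(u).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .basis import RaisedCosineBasis
from .params import ModelParams, N_SFA, kernel_matrix
from .distributions import is_sigmoid


@dataclass
class SFAState:
    """Adaptation currents c_i^(x), shape (n_neurons, 5), dimensionless
    leaky integrals of each neuron's own spike counts."""

    c: np.ndarray

    def __post_init__(self):
        self.c = np.asarray(self.c, float)
        if self.c.ndim != 2 or self.c.shape[1] != N_SFA:
            raise ValueError(f"c must have shape (N, {N_SFA})")

    @classmethod
    def zeros(cls, n_neurons: int) -> "SFAState":
        return cls(np.zeros((n_neurons, N_SFA)))


def sfa_step(state: SFAState, S_t: np.ndarray, tau_sfa: np.ndarray,
             dt: float) -> SFAState:
    """One explicit-Euler update of the adaptation currents.

    c'^(x) = c^(x)(1 − dt/τ^(x)) + S·(dt/τ^(x)); requires dt < min(τ) for
    the update to be a stable leaky integration.
    """
    tau_sfa = np.asarray(tau_sfa, float)
    if dt >= tau_sfa.min():
        raise ValueError(f"dt={dt} must be smaller than every SFA timescale "
                         f"(min {tau_sfa.min()})")
    alpha = dt / tau_sfa  # (5,)
    c = state.c * (1.0 - alpha) + np.asarray(S_t, float)[:, None] * alpha
    return SFAState(c)


def sfa_trace(S: np.ndarray, tau_sfa: np.ndarray, dt: float,
              c0: np.ndarray = None) -> np.ndarray:
    """Adaptation traces for a whole count matrix, vectorized over time.

    Parameters
    ----------
    S : (N, T) counts.
    c0 : optional (N, 5) initial state at bin 0 (default zeros).

    Returns
    -------
    c : (5, N, T); ``c[x, :, u]`` is the state *at* bin u, integrating
        counts through bin u−1 (so ``c[:, :, 0] = c0``).
    """
    S = np.asarray(S, float)
    tau_sfa = np.asarray(tau_sfa, float)
    if dt >= tau_sfa.min():
        raise ValueError("dt must be smaller than every SFA timescale")
    N, T = S.shape
    c = np.zeros((N_SFA, N, T))
    for x, tau in enumerate(tau_sfa):
        alpha = dt / tau
        # z[u] = (1-a) z[u-1] + a S[u]  with z[-1] = 0
        z = lfilter([alpha], [1.0, -(1.0 - alpha)], S, axis=1)
        c[x, :, 1:] = z[:, :-1]
        if c0 is not None:
            decay = (1.0 - alpha) ** np.arange(T)
            c[x] += np.asarray(c0, float)[:, x][:, None] * decay[None, :]
    return c


def sfa_tau_sensitivity(S: np.ndarray, c: np.ndarray, tau_sfa: np.ndarray,
                        dt: float) -> np.ndarray:
    """∂c/∂τ per timescale, same shape as ``c``; recursion
    d(u) = (1−α)d(u−1) + (dt/τ²)(c(u−1) − S(u−1)), d(0) = 0."""
    S = np.asarray(S, float)
    d = np.zeros_like(c)
    for x, tau in enumerate(tau_sfa):
        alpha = dt / tau
        w = (dt / tau**2) * (c[x] - S)  # (N, T)
        z = lfilter([1.0], [1.0, -(1.0 - alpha)], w, axis=1)
        d[x, :, 1:] = z[:, :-1]
    return d


def history_regressors(S: np.ndarray, basis: RaisedCosineBasis) -> np.ndarray:
    """Basis-filtered spike histories X[l, j, u] = Σ_m rc_l(m·dt) S_j(u−m).

    Returns shape (n_basis, N, T); the first M bins are computed against
    zero-padded history and are only valid as burn-in context.
    """
    S = np.asarray(S, float)
    X = np.empty((basis.n_basis, *S.shape))
    for l in range(basis.n_basis):
        b = np.concatenate([[0.0], basis.values[l]])  # delay-1 FIR
        X[l] = lfilter(b, [1.0], S, axis=1)
    return X


def current_series(S: np.ndarray, params: ModelParams,
                   c0: np.ndarray = None,
                   X_off: np.ndarray = None, X_diag: np.ndarray = None,
                   return_parts: bool = False):
    """Teacher-forced input currents H_i(u) for every bin of a count matrix.

    H_i(u) = h_i + Σ_j Σ_Δ k_ij(Δ) S_j(u−Δ/dt) − Σ_x g^(x) c_i^(x)(u).

    Precomputed regressors may be passed to avoid refiltering when only
    SFA/transfer parameters change.  With ``return_parts`` also returns the
    SFA trace (5, N, T) and the regressors.
    """
    S = np.asarray(S, float)
    N, T = S.shape
    if X_off is None:
        X_off = history_regressors(S, params.basis_off_diagonal)
    L = params.basis_off_diagonal.n_basis
    # (N, N*L) @ (N*L, T); row-major (j, l) layout on both sides.
    W2 = params.weights.reshape(N, N * L)
    X2 = X_off.transpose(1, 0, 2).reshape(N * L, T)
    H = params.h[:, None] + W2 @ X2
    if not is_sigmoid(params.variant):
        if X_diag is None:
            X_diag = history_regressors(S, params.basis_diagonal)
        H += np.einsum("il,liu->iu", params.diag_weights, X_diag)
    c = sfa_trace(S, params.tau_sfa, params.dt, c0=c0)
    g = params.g_per_neuron()  # (N, 5)
    H -= np.einsum("ix,xiu->iu", g, c)
    if return_parts:
        return H, c, X_off, X_diag
    return H


def input_current(history: np.ndarray, t: int, params: ModelParams,
                  state: SFAState) -> np.ndarray:
    """Input current for predicted bin ``t`` from an explicit history record.

    ``history`` is an (N, ≥t) count array indexed by absolute bin, covering
    at least bins t−M … t−1 (M = n_lags); the SFA ``state`` must already
    integrate counts through bin t−1.  Raises if fewer than M bins of
    history precede t.
    """
    history = np.asarray(history, float)
    M = params.n_lags
    if t < M or history.shape[1] < M:
        raise ValueError(f"need at least {M} bins of history before bin {t}; "
                         "pad or burn in the caller")
    K = kernel_matrix(params)  # (N, N, M), lag m -> Δ=(m+1)dt
    window = history[:, t - M:t]  # columns old -> new; column M-1 is bin t-1
    # lag Δ=(m+1)dt reads column M-1-m of the window
    Kf = K[:, :, ::-1].reshape(params.n_neurons, -1)
    H = params.h + Kf @ window.reshape(-1)
    H -= (params.g_per_neuron() * state.c).sum(axis=1)
    return H
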