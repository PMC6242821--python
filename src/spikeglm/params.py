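"""Model parameter container and kernel expansion."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .basis import RaisedCosineBasis, build_basis
from .distributions import _check_variant, is_sigmoid

N_SFA = 5  # number of adaptation currents per neuron


@dataclass
class ModelParams:
    """All parameters of one model variant.

    Attributes
    ----------
    variant : {"exp_poisson", "sig_negbin", "sig_poisson", "exp_negbin"}
    weights : ndarray, shape (N, N, 4)
        Off-diagonal synaptic-kernel coefficients w_ij^(l) in the
        off-diagonal raised-cosine basis; diagonal entries are identically 0
        for every variant (self-interaction is carried by ``diag_weights``
        in exponential variants and by SFA in sigmoid variants).
    diag_weights : ndarray, shape (N, 6)
        Self-kernel coefficients in the diagonal basis; used (and fitted)
        only by exponential-transfer variants, zero otherwise.
    h : ndarray, shape (N,)
        Constant external currents.
    g_sfa : ndarray, shape (5,) or (N, 5)
        SFA gains per timescale (current units per unit adaptation trace),
        shared across neurons by default; zero for exponential variants.
    tau_sfa : ndarray, shape (5,)
        SFA timescales in seconds, shared across neurons.
    lambda_inf, gamma : float
        Sigmoid transfer parameters (asymptotic counts/bin; asymmetry).
    r_nb : float
        NegBin dispersion, fixed a priori (never inferred).
    dt : float
        Bin width in seconds.
    """

    variant: str
    weights: np.ndarray
    h: np.ndarray
    g_sfa: np.ndarray
    tau_sfa: np.ndarray
    lambda_inf: float = 1.0
    gamma: float = 1.0
    r_nb: float = 0.22
    dt: float = 0.01
    diag_weights: np.ndarray = None
    basis_off_diagonal: RaisedCosineBasis = field(default=None, repr=False)
    basis_diagonal: RaisedCosineBasis = field(default=None, repr=False)

    def __post_init__(self):
        _check_variant(self.variant)
        self.weights = np.asarray(self.weights, float)
        self.h = np.asarray(self.h, float)
        self.g_sfa = np.asarray(self.g_sfa, float)
        self.tau_sfa = np.asarray(self.tau_sfa, float)
        n = self.n_neurons
        if self.basis_off_diagonal is None:
            self.basis_off_diagonal = build_basis("off_diagonal", self.dt)
        if self.basis_diagonal is None:
            self.basis_diagonal = build_basis("diagonal", self.dt)
        if self.diag_weights is None:
            self.diag_weights = np.zeros((n, self.basis_diagonal.n_basis))
        self.diag_weights = np.asarray(self.diag_weights, float)
        if self.weights.shape != (n, n, self.basis_off_diagonal.n_basis):
            raise ValueError(f"weights shape {self.weights.shape} inconsistent "
                             f"with {n} neurons")
        if self.tau_sfa.shape != (N_SFA,):
            raise ValueError(f"tau_sfa must have shape ({N_SFA},)")
        if self.g_sfa.shape not in ((N_SFA,), (n, N_SFA)):
            raise ValueError("g_sfa must have shape (5,) or (N, 5)")
        if np.any(self.tau_sfa <= 0):
            raise ValueError("tau_sfa must be positive")
        if self.lambda_inf <= 0 or self.gamma <= 0 or self.r_nb <= 0:
            raise ValueError("lambda_inf, gamma, r_nb must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        # Variant constraints: the transfer function decides the
        # self-interaction mechanism — sigmoid variants carry it through SFA
        # (diag_weights = 0), exponential variants through diagonal
        # self-kernels (g_sfa = 0).  Off-diagonal weights never have a
        # diagonal component.
        idx = np.arange(n)
        self.weights[idx, idx, :] = 0.0
        if is_sigmoid(self.variant):
            self.diag_weights[:] = 0.0
        else:
            self.g_sfa = np.zeros_like(self.g_sfa)

    @property
    def n_neurons(self) -> int:
        return len(self.h)

    @property
    def n_lags(self) -> int:
        return self.basis_off_diagonal.n_lags

    def g_per_neuron(self) -> np.ndarray:
        """SFA gains broadcast to shape (N, 5)."""
        if self.g_sfa.ndim == 1:
            return np.broadcast_to(self.g_sfa, (self.n_neurons, N_SFA))
        return self.g_sfa

    def copy(self) -> "ModelParams":
        return replace(self, weights=self.weights.copy(), h=self.h.copy(),
                       g_sfa=self.g_sfa.copy(), tau_sfa=self.tau_sfa.copy(),
                       diag_weights=self.diag_weights.copy())

    def kernel_areas(self) -> np.ndarray:
        """Signed area Σ_Δ k_ij(Δ)·dt of each cross-neuron kernel, (N, N)."""
        K = kernel_matrix(self)
        return K.sum(axis=2) * self.dt


def kernel_matrix(params: ModelParams) -> np.ndarray:
    """Expand all cross-neuron kernels onto the lag grid: (N, N, n_lags).

    Lag index m holds the kernel value at Δ = (m+1)·dt.  Self-kernels of
    exponential variants are added on the diagonal (diagonal basis).
    """
    K = np.einsum("ijl,lm->ijm", params.weights, params.basis_off_diagonal.values)
    if not is_sigmoid(params.variant):
        D = params.diag_weights @ params.basis_diagonal.values  # (N, n_lags)
        idx = np.arange(params.n_neurons)
        K[idx, idx, :] += D
    return K


def default_params(variant: str, n_neurons: int, dt: float = 0.01,
                   r_nb: float = 0.22) -> ModelParams:
    """A blank parameter set: zero weights and SFA gains, log-spaced SFA
    timescales in [50 ms, 5 s], unit sigmoid."""
    return ModelParams(
        variant=variant,
        weights=np.zeros((n_neurons, n_neurons, 4)),
        h=np.zeros(n_neurons),
        g_sfa=np.zeros(N_SFA),
        tau_sfa=np.geomspace(0.05, 5.0, N_SFA),
        lambda_inf=1.0, gamma=1.0, r_nb=r_nb, dt=dt,
    )


def save_params(path, params: ModelParams, ll_trace: np.ndarray = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["variant"] = params.variant
        for k in ("lambda_inf", "gamma", "r_nb", "dt"):
            f.attrs[k] = getattr(params, k)
        for k in ("weights", "diag_weights", "h", "g_sfa", "tau_sfa"):
            f.create_dataset(k, data=getattr(params, k))
        if ll_trace is not None:
            f.create_dataset("ll_trace", data=np.asarray(ll_trace))


def load_params(path) -> ModelParams:
    with h5py.File(path, "r") as f:
        return ModelParams(
            variant=str(f.attrs["variant"]),
            weights=f["weights"][()], diag_weights=f["diag_weights"][()],
            h=f["h"][()], g_sfa=f["g_sfa"][()], tau_sfa=f["tau_sfa"][()],
            lambda_inf=float(f.attrs["lambda_inf"]), gamma=float(f.attrs["gamma"]),
            r_nb=float(f.attrs["r_nb"]), dt=float(f.attrs["dt"]),
        )
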