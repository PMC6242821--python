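"""Raised-cosine temporal bases for synaptic kernels.

Kernels are parameterized as linear combinations of log-time-warped
raised-cosine bumps

    rc(Δ) = ½ [1 + cos(a·log(Δ + δ) − φ)]

evaluated on the discrete lag grid Δ ∈ {dt, 2dt, …, 150 ms} and windowed to
the single period a·log(Δ+δ) − φ ∈ [−π, π] (zero outside), with a hard
truncation rc(Δ) = 0 for Δ > 150 ms.  Off-diagonal (cross-neuron) kernels
use 4 basis functions; diagonal (self) kernels, present only in the
exponential-transfer model variants, use 6 narrower ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_LAG_MS = 150.0

# Fixed basis constants: (a, delta_ms, phase offsets in units of pi/2).
_BASIS_CONSTANTS = {
    "off_diagonal": (1.153, 0.2560, (-1, 0, 1, 2)),
    "diagonal": (2.974, 0.3477, (-2, 3, 4, 5, 6, 7)),
}


@dataclass(frozen=True)
class RaisedCosineBasis:
    """A fixed raised-cosine basis expanded over a discrete lag grid.

    Attributes
    ----------
    a : float
        Log-time scaling (dimensionless).
    delta : float
        Time offset in milliseconds.
    phis : ndarray
        Phase offsets φ^(l) in radians, one per basis function.
    max_lag : float
        Hard truncation lag in milliseconds.
    lag_grid : ndarray
        Lags in milliseconds, positive multiples of the bin width.
    values : ndarray, shape (n_basis, n_lags)
        Basis function values on the lag grid, in [0, 1].
    """

    a: float
    delta: float
    phis: np.ndarray
    max_lag: float
    lag_grid: np.ndarray
    values: np.ndarray
    kind: str = field(default="off_diagonal")

    @property
    def n_basis(self) -> int:
        return len(self.phis)

    @property
    def n_lags(self) -> int:
        return len(self.lag_grid)

    def evaluate(self, lags_ms: np.ndarray) -> np.ndarray:
        """Evaluate every basis function at arbitrary lags (ms).

        Returns an array of shape ``(n_basis, len(lags_ms))``.
        """
        return _rc_values(self.a, self.delta, self.phis, np.asarray(lags_ms, float),
                          self.max_lag)


def _rc_values(a: float, delta: float, phis: np.ndarray, lags_ms: np.ndarray,
               max_lag: float) -> np.ndarray:
    u = a * np.log(lags_ms + delta)[None, :] - np.asarray(phis)[:, None]
    vals = 0.5 * (1.0 + np.cos(u))
    vals[np.abs(u) > np.pi] = 0.0          # single-period window
    vals[:, lags_ms > max_lag] = 0.0       # hard truncation
    return vals


def build_basis(kind: str, dt: float) -> RaisedCosineBasis:
    """Construct the fixed raised-cosine basis for a given kernel kind.

    Parameters
    ----------
    kind : {"off_diagonal", "diagonal"}
        Off-diagonal: 4 functions, a=1.153, δ=0.2560 ms, φ = (π/2)·(−1,0,1,2).
        Diagonal: 6 functions, a=2.974, δ=0.3477 ms, φ = (π/2)·(−2,3,4,5,6,7).
    dt : float
        Bin width in seconds; the lag grid is {dt, …, 150 ms}.
    """
    if kind not in _BASIS_CONSTANTS:
        raise ValueError(f"unknown basis kind {kind!r}; "
                         f"expected one of {sorted(_BASIS_CONSTANTS)}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    a, delta, phi_halves = _BASIS_CONSTANTS[kind]
    phis = np.array(phi_halves, float) * (np.pi / 2.0)
    dt_ms = dt * 1000.0
    n_lags = int(np.floor(MAX_LAG_MS / dt_ms + 1e-9))
    if n_lags < 1:
        raise ValueError(f"dt={dt} s leaves no lags below {MAX_LAG_MS} ms")
    lag_grid = dt_ms * np.arange(1, n_lags + 1)
    values = _rc_values(a, delta, phis, lag_grid, MAX_LAG_MS)
    return RaisedCosineBasis(a=a, delta=delta, phis=phis, max_lag=MAX_LAG_MS,
                             lag_grid=lag_grid, values=values, kind=kind)


def synaptic_kernel(w_l: np.ndarray, basis: RaisedCosineBasis) -> np.ndarray:
    """Expand basis coefficients into a synaptic kernel over the lag grid.

    k(Δ) = Σ_l w^(l) rc^(l)(Δ); returns an array over ``basis.lag_grid``.
    """
    w_l = np.asarray(w_l, float)
    if w_l.shape != (basis.n_basis,):
        raise ValueError(f"expected {basis.n_basis} coefficients, got shape {w_l.shape}")
    return w_l @ basis.values
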