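"""Mechanism-direction experiments on planted networks.

Two dynamical roles are probed on toy ground-truth models: the
over-dispersed (negative-binomial) generator destabilizes the high-activity
state of a bistable network, so replacing it with a Poisson generator at
identical parameters lengthens up-state dwell times; and spike-frequency
adaptation imposes post-burst refractoriness, so removing it shifts the
time-to-next-burst distribution toward zero and makes it more variable.
"""

from __future__ import annotations

import numpy as np

from .basis import build_basis
from .bursts import BurstConfig, post_burst_ibi_protocol
from .data import SpikeCountMatrix
from .params import ModelParams, N_SFA
from .simulate import SimProtocol, simulate


def bistable_toy_params(n_neurons: int = 5, recurrent: float = 4.0,
                        lambda_inf: float = 2.0, quiescent: float = 0.02,
                        r_nb: float = 0.22, dt: float = 0.01) -> ModelParams:
    """All-to-all excitatory network with a saturating transfer function,
    tuned to be bistable between a quiescent state and an up state near
    the rate ceiling (mean-field fixed points at ~quiescent and ~λ∞)."""
    basis = build_basis("off_diagonal", dt)
    lag_sums = basis.values.sum(axis=1)
    w = np.zeros((n_neurons, n_neurons, basis.n_basis))
    # carry each pair's kernel mass on the broadest basis function
    w[:, :, 3] = (recurrent / (n_neurons - 1)) / lag_sums[3]
    q = quiescent / lambda_inf
    h = np.log(q / (1.0 - q)) - recurrent * quiescent
    return ModelParams("sig_negbin", w, np.full(n_neurons, h),
                       np.zeros(N_SFA), np.geomspace(0.05, 5.0, N_SFA),
                       lambda_inf=lambda_inf, gamma=1.0, r_nb=r_nb, dt=dt)


def up_state_dwell_times(params: ModelParams, generator: str,
                         rng: np.random.Generator, n_repeats: int = 10,
                         horizon_bins: int = 20_000,
                         up_rate: float = None) -> np.ndarray:
    """Dwell times (s) in the high-activity state under a given generator.

    Each repeat drives the network briefly with up-state activity, releases
    it, and records the time until the population rate stays below a
    quarter of the up-state level for 200 ms.  Censored repeats (still up
    at the horizon) return the horizon.
    """
    N = params.n_neurons
    if up_rate is None:
        up_rate = 0.95 * params.lambda_inf
    down_thresh = 0.25 * N * up_rate
    consec = max(int(round(0.2 / params.dt)), 1)
    dwell = np.empty(n_repeats)
    for rep in range(n_repeats):
        ref = SpikeCountMatrix(rng.poisson(up_rate, size=(N, params.n_lags + 5)),
                               params.dt)
        proto = SimProtocol([("driven", 5), ("free", horizon_bins)],
                            generator_override=generator)
        res = simulate(params, proto, reference=ref, rng=rng)
        pop = res.counts.counts[:, 5:].sum(axis=0)
        low = pop < down_thresh
        run = 0
        t = horizon_bins
        for u, v in enumerate(low):
            run = run + 1 if v else 0
            if run >= consec:
                t = u - consec + 1
                break
        dwell[rep] = t * params.dt
    return dwell


def sfa_removal_next_ibi(params: ModelParams, reference: SpikeCountMatrix,
                         table, burst_index: int, rng_with, rng_without,
                         n_repeats: int = 60, horizon_s: float = 15.0,
                         burst_config: BurstConfig = None,
                         mode_bin_s: float = 1.0) -> dict:
    """Post-burst next-IBI distributions with SFA intact vs removed (g=0).

    Returns both protocol results plus the histogram-mode location (bins of
    ``mode_bin_s``) and CV of each, for the refractoriness comparison.
    """
    stripped = params.copy()
    stripped.g_sfa = np.zeros_like(stripped.g_sfa)
    out = {}
    for label, p, rng in (("with_sfa", params, rng_with),
                          ("without_sfa", stripped, rng_without)):
        res = post_burst_ibi_protocol(p, reference, table, burst_index,
                                      n_repeats=n_repeats, rng=rng,
                                      horizon_s=horizon_s,
                                      burst_config=burst_config)
        edges = np.arange(0.0, horizon_s + mode_bin_s, mode_bin_s)
        hist, _ = np.histogram(res["times"], bins=edges)
        res["mode_s"] = float(edges[np.argmax(hist)])
        out[label] = res
    return out
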