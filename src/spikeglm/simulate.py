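"""Driven (teacher-forced) and free (autonomous) simulation.

Driven mode computes the deterministic one-step-ahead rate trace from a
reference recording — emitted counts never re-enter the dynamics.  Free
mode feeds the sampled counts back as the model's own history.  Protocols
are ordered segment lists and may switch modes mid-run; the SFA state and
the 150 ms history buffer are carried across switches.  A generator
override swaps only the count distribution ("Poisson replay"), leaving the
deterministic current→rate pipeline untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SpikeCountMatrix
from .distributions import is_sigmoid, sample_counts, transfer
from .dynamics import current_series, sfa_trace
from .params import ModelParams, N_SFA, kernel_matrix


@dataclass
class SimProtocol:
    """Ordered simulation segments: (mode, duration in bins).

    ``generator_override`` replaces the variant's count distribution
    ({"poisson", "negbin"}) in every segment without touching the
    deterministic dynamics.
    """

    segments: list
    generator_override: str = None

    def __post_init__(self):
        for mode, dur in self.segments:
            if mode not in ("driven", "free"):
                raise ValueError(f"unknown mode {mode!r}")
            if dur <= 0:
                raise ValueError("segment durations must be positive")
        if self.generator_override not in (None, "poisson", "negbin"):
            raise ValueError("generator_override must be 'poisson' or 'negbin'")

    @property
    def total_bins(self) -> int:
        return sum(d for _, d in self.segments)

    @classmethod
    def parse(cls, text: str, generator_override: str = None) -> "SimProtocol":
        """Parse "driven:1000,free:100000" into a protocol."""
        segs = []
        for part in text.split(","):
            mode, dur = part.split(":")
            segs.append((mode.strip(), int(dur)))
        return cls(segs, generator_override)


@dataclass
class SimResult:
    counts: SpikeCountMatrix
    rates: np.ndarray
    currents: np.ndarray
    modes: np.ndarray = field(default=None)          # "driven"/"free" per bin
    sfa_trace: np.ndarray = field(default=None, repr=False)


def _generator_variant(params: ModelParams, override: str) -> str:
    if override is None:
        return params.variant
    base = "sig" if is_sigmoid(params.variant) else "exp"
    return f"{base}_{override}"


def simulate(params: ModelParams, protocol: SimProtocol,
             reference: SpikeCountMatrix = None,
             rng: np.random.Generator = None,
             keep_sfa: bool = False,
             init_history: np.ndarray = None,
             init_sfa: np.ndarray = None) -> SimResult:
    """Run a simulation protocol; (params, protocol, reference, rng seed)
    fully determine the result.

    Driven segments consume the reference sequentially: the first M bins of
    the reference (M = n_lags, 150 ms) seed the history buffer, and segment
    bins then advance through the recording.  Free segments continue from
    whatever history the run has accumulated (reference counts where the
    run was driven, emitted counts where free); with no reference the
    history starts from silence.

    ``init_history`` (N, M) and ``init_sfa`` (5, N) override the starting
    history window and adaptation state — used to continue a run from a
    previously computed state (e.g. post-burst release protocols).
    """
    if rng is None:
        rng = np.random.default_rng()
    if any(m == "driven" for m, _ in protocol.segments) and reference is None:
        raise ValueError("driven segments require reference data")
    gen_variant = _generator_variant(params, protocol.generator_override)
    N = params.n_neurons
    M = params.n_lags
    total = protocol.total_bins
    if reference is not None:
        if reference.dt != params.dt or reference.n_neurons != N:
            raise ValueError("reference incompatible with params")
        needed = M + sum(d for m, d in protocol.segments if m == "driven")
        if reference.n_bins < needed:
            raise ValueError(f"reference too short: need {needed} bins")
        context = reference.counts[:, :M].astype(float)
    else:
        context = np.zeros((N, M))
    if init_history is not None:
        init_history = np.asarray(init_history, float)
        if init_history.shape != (N, M):
            raise ValueError(f"init_history must have shape ({N}, {M})")
        context = init_history

    # hist holds the *effective* past: reference counts over driven bins,
    # emitted counts over free bins; column M+u is protocol bin u.
    hist = np.zeros((N, M + total))
    hist[:, :M] = context
    counts = np.zeros((N, total), dtype=np.int64)
    rates = np.zeros((N, total))
    currents = np.zeros((N, total))
    modes = np.empty(total, dtype=object)
    sfa_all = np.zeros((N_SFA, N, total)) if keep_sfa else None

    K = kernel_matrix(params)
    Kf = K[:, :, ::-1].reshape(N, N * M)  # aligned with old->new windows
    g = params.g_per_neuron()  # (N, 5)
    alpha = params.dt / params.tau_sfa  # (5,)

    # SFA state at the first protocol bin integrates all context counts:
    # sfa_trace gives the state *at* the last context bin, one more update
    # folds that bin's counts in.
    if init_sfa is not None:
        c = np.asarray(init_sfa, float).copy()
        if c.shape != (N_SFA, N):
            raise ValueError(f"init_sfa must have shape ({N_SFA}, {N})")
    else:
        c = sfa_trace(context, params.tau_sfa, params.dt)[:, :, -1]  # (5, N)
        c = c * (1 - alpha)[:, None] + context[None, :, -1] * alpha[:, None]

    pos = 0          # protocol bin index
    ref_cursor = M   # next reference bin to consume in driven mode
    for mode, dur in protocol.segments:
        for _ in range(dur):
            window = hist[:, pos:pos + M]
            H = params.h + Kf @ window.reshape(-1) - (g * c.T).sum(axis=1)
            lam = transfer(H, params.variant, params.lambda_inf, params.gamma)
            S = sample_counts(lam, gen_variant, rng, params.r_nb)
            if mode == "driven":
                drive = reference.counts[:, ref_cursor].astype(float)
                ref_cursor += 1
            else:
                drive = S.astype(float)
            hist[:, M + pos] = drive
            counts[:, pos] = S
            rates[:, pos] = lam
            currents[:, pos] = H
            modes[pos] = mode
            if sfa_all is not None:
                sfa_all[:, :, pos] = c
            c = c * (1 - alpha)[:, None] + drive[None, :] * alpha[:, None]
            pos += 1

    return SimResult(counts=SpikeCountMatrix(counts, params.dt),
                     rates=rates, currents=currents, modes=modes,
                     sfa_trace=sfa_all)


def replay_with_generator(params: ModelParams, generator: str,
                          protocol: SimProtocol,
                          reference: SpikeCountMatrix = None,
                          rng: np.random.Generator = None,
                          keep_sfa: bool = False) -> SimResult:
    """Re-run a protocol with only the count generator substituted.

    The deterministic pipeline (currents, SFA, transfer) is identical to
    ``simulate``; only the sampling distribution changes.
    """
    if generator not in ("poisson", "negbin"):
        raise ValueError("generator must be 'poisson' or 'negbin'")
    proto = SimProtocol(list(protocol.segments), generator_override=generator)
    return simulate(params, proto, reference=reference, rng=rng, keep_sfa=keep_sfa)


def driven_rates(params: ModelParams, reference: SpikeCountMatrix) -> np.ndarray:
    """Deterministic driven-mode rate trace λ_i(u) over a whole recording
    (vectorized; identical to the rates ``simulate`` produces bin by bin
    for an all-driven protocol)."""
    H = current_series(reference.counts, params)
    return transfer(H, params.variant, params.lambda_inf, params.gamma)
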