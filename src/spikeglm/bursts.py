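"""Population-burst detection and downstream spatio-temporal statistics.

Bursts are episodes of elevated population rate detected with a
dual-threshold hysteresis rule on the (optionally smoothed) summed count
trace; thresholds are expressed in multiples of the median nonzero
population rate so the detector transfers across activity levels.
Downstream operations cover amplitude/duration/IBI statistics, the
IBI→amplitude correlation, post-burst recovery protocols, per-burst
first-spike time-ranks with shuffle surrogates, nearest-burst rank-vector
comparisons, and synaptic-strength versus electrode-distance profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr, ttest_ind

from .data import SpikeCountMatrix
from .params import ModelParams


# ---------------------------------------------------------------------------
# detection

@dataclass
class BurstConfig:
    """Hysteresis burst-detector settings.

    Thresholds are multiples of the median nonzero smoothed population
    rate: a burst opens when the rate reaches ``theta_hi`` × that baseline
    and extends while it stays at or above ``theta_lo`` ×.  Bursts closer
    than ``min_gap_s`` are merged; shorter than ``min_duration_s`` dropped.
    """

    smooth_bins: int = 3
    theta_hi: float = 5.0
    theta_lo: float = 2.0
    min_gap_s: float = 0.1
    min_duration_s: float = 0.05


@dataclass
class BurstTable:
    """Detected bursts: half-open bin intervals [onset, offset), total
    spike-count amplitudes, durations and derived inter-burst intervals."""

    onsets: np.ndarray
    offsets: np.ndarray
    amplitudes: np.ndarray
    dt: float

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, int)
        self.offsets = np.asarray(self.offsets, int)
        self.amplitudes = np.asarray(self.amplitudes)
        if np.any(self.offsets <= self.onsets):
            raise ValueError("burst offsets must exceed onsets")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("burst onsets must be strictly increasing")

    @property
    def n_bursts(self) -> int:
        return len(self.onsets)

    @property
    def durations(self) -> np.ndarray:
        """Burst durations in seconds."""
        return (self.offsets - self.onsets) * self.dt

    @property
    def ibis(self) -> np.ndarray:
        """Quiescent offset→next-onset intervals in seconds (n_bursts − 1)."""
        return (self.onsets[1:] - self.offsets[:-1]) * self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_bin": self.onsets, "offset_bin": self.offsets,
            "amplitude": self.amplitudes, "duration_s": self.durations,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: float) -> "BurstTable":
        return cls(df["onset_bin"].to_numpy(), df["offset_bin"].to_numpy(),
                   df["amplitude"].to_numpy(), dt)


def _smooth(rate: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return rate.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(rate, kernel, mode="same")


def detect_bursts(counts: SpikeCountMatrix,
                  config: BurstConfig = None) -> BurstTable:
    """Segment population bursts with a dual-threshold hysteresis rule."""
    if config is None:
        config = BurstConfig()
    rate = counts.population_rate().astype(float)
    if rate.size == 0 or rate.max() == 0:
        return BurstTable(np.empty(0, int), np.empty(0, int), np.empty(0), counts.dt)
    smoothed = _smooth(rate, config.smooth_bins)
    # thresholds scale with the median nonzero raw population rate; for
    # sparse recordings this is 1 count/bin, giving absolute thresholds
    nonzero = rate[rate > 0]
    baseline = np.median(nonzero) if nonzero.size else 0.0
    hi = config.theta_hi * baseline
    lo = config.theta_lo * baseline

    above_lo = smoothed >= lo
    # contiguous runs of above_lo that contain at least one bin >= hi
    edges = np.diff(above_lo.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above_lo[0]:
        starts = np.r_[0, starts]
    if above_lo[-1]:
        ends = np.r_[ends, len(smoothed)]
    keep = [(s, e) for s, e in zip(starts, ends) if smoothed[s:e].max() >= hi]

    # merge bursts separated by short gaps
    min_gap = int(round(config.min_gap_s / counts.dt))
    merged = []
    for s, e in keep:
        if merged and s - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    # discard short bursts
    min_dur = int(round(config.min_duration_s / counts.dt))
    final = [(s, e) for s, e in merged if e - s >= min_dur]

    onsets = np.array([s for s, _ in final], int)
    offsets = np.array([e for _, e in final], int)
    amps = np.array([rate[s:e].sum() for s, e in final])
    return BurstTable(onsets, offsets, amps, counts.dt)


# ---------------------------------------------------------------------------
# scalar statistics

def burst_statistics(table: BurstTable, n_hist_bins: int = 20) -> dict:
    """Mean/std/CV summaries (sample std, n−1) of amplitude, duration and
    IBI, with histograms; degenerate cases are flagged rather than raised."""
    out = {"n_bursts": table.n_bursts, "flags": []}
    series = {"amplitude": table.amplitudes.astype(float),
              "duration": table.durations,
              "ibi": table.ibis}
    for name, x in series.items():
        entry = {}
        if len(x) == 0:
            out["flags"].append(f"no {name} samples")
        else:
            entry["mean"] = float(np.mean(x))
            if len(x) >= 2:
                entry["std"] = float(np.std(x, ddof=1))
                entry["cv"] = entry["std"] / entry["mean"] if entry["mean"] else np.nan
                hist, edges = np.histogram(x, bins=n_hist_bins)
                entry["hist"] = hist
                entry["hist_edges"] = edges
            else:
                entry["std"] = None
                out["flags"].append(f"single {name} sample: std undefined")
        out[name] = entry
    return out


def ibi_amplitude_correlation(table: BurstTable, n_boot: int = 1000,
                              rng: np.random.Generator = None) -> dict:
    """Pearson correlation between each burst's amplitude and the interval
    since the preceding burst, with a seeded bootstrap CI."""
    if table.n_bursts < 3:
        raise ValueError("need at least 3 bursts")
    ibi = table.ibis                   # interval before burst k+1
    amp = table.amplitudes[1:].astype(float)
    if np.std(ibi) == 0 or np.std(amp) == 0:
        return {"c": None, "ci": (None, None), "flag": "constant input"}
    c, p = pearsonr(ibi, amp)
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(ibi)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        x, y = ibi[idx], amp[idx]
        if np.std(x) == 0 or np.std(y) == 0:
            boots[b] = np.nan
            continue
        boots[b] = pearsonr(x, y)[0]
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {"c": float(c), "p": float(p), "ci": (float(lo), float(hi))}


# ---------------------------------------------------------------------------
# post-burst recovery protocol

def post_burst_ibi_protocol(params: ModelParams, reference: SpikeCountMatrix,
                            table: BurstTable, burst_index: int,
                            n_repeats: int, rng: np.random.Generator,
                            horizon_s: float = 20.0,
                            burst_config: BurstConfig = None,
                            n_hist_bins: int = 20) -> dict:
    """Distribution of the time to the next burst after a chosen burst.

    The model is driven by the reference up to the end of burst
    ``burst_index`` and then released; each of ``n_repeats`` free
    continuations is scanned for its first detected burst onset.
    Continuations without a burst within the horizon are censored (counted,
    not included in the moments).

    The driven-mode state at the release point (history window and SFA
    currents) is a deterministic function of the reference, so it is
    computed once and shared by all repeats.
    """
    from .dynamics import sfa_trace
    from .simulate import SimProtocol, simulate  # local: avoid cycle

    if burst_config is None:
        burst_config = BurstConfig()
    offset = int(table.offsets[burst_index])
    horizon = int(round(horizon_s / params.dt))
    M = params.n_lags
    if offset <= M:
        raise ValueError("burst ends within the history burn-in")
    # deterministic driven state at the release bin
    prefix = reference.counts[:, :offset].astype(float)
    init_history = prefix[:, offset - M:offset]
    c = sfa_trace(prefix, params.tau_sfa, params.dt)[:, :, -1]
    alpha = params.dt / params.tau_sfa
    init_sfa = c * (1 - alpha)[:, None] + prefix[None, :, -1] * alpha[:, None]

    proto = SimProtocol([("free", horizon)])
    times = []
    censored = 0
    for _ in range(n_repeats):
        res = simulate(params, proto, rng=rng,
                       init_history=init_history, init_sfa=init_sfa)
        bursts = detect_bursts(res.counts, burst_config)
        if bursts.n_bursts == 0:
            censored += 1
        else:
            times.append(bursts.onsets[0] * params.dt)
    times = np.asarray(times)
    out = {"times": times, "censored": censored, "n_repeats": n_repeats,
           "horizon_s": horizon_s}
    if times.size:
        out["mean"] = float(times.mean())
        out["cv"] = float(times.std(ddof=1) / times.mean()) if times.size > 1 else None
        hist, edges = np.histogram(times, bins=n_hist_bins, range=(0, horizon_s))
        out["hist"], out["hist_edges"] = hist, edges
    return out


# ---------------------------------------------------------------------------
# time-ranks

@dataclass
class RankMatrix:
    """Per-burst, per-neuron first-spike time-ranks (0-based bins since
    burst onset); NaN marks neurons silent within the burst."""

    ranks: np.ndarray            # (n_bursts, n_neurons), float with NaN
    durations_bins: np.ndarray   # (n_bursts,)

    def __post_init__(self):
        self.ranks = np.asarray(self.ranks, float)
        self.durations_bins = np.asarray(self.durations_bins, int)
        if self.ranks.shape[0] != len(self.durations_bins):
            raise ValueError("one duration per burst required")

    @property
    def n_bursts(self) -> int:
        return self.ranks.shape[0]

    def mean_ranks(self) -> np.ndarray:
        """Per-neuron mean rank over the bursts in which it participates."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.ranks, axis=0)

    def filled(self) -> np.ndarray:
        """Ranks with each burst's silent neurons replaced by that burst's
        duration in bins (the 'never spiked within the burst' sentinel)."""
        out = self.ranks.copy()
        rows, cols = np.nonzero(np.isnan(out))
        out[rows, cols] = self.durations_bins[rows]
        return out


def time_ranks(counts: SpikeCountMatrix, table: BurstTable) -> RankMatrix:
    """First-spike time-ranks for every burst and neuron."""
    S = counts.counts
    ranks = np.full((table.n_bursts, counts.n_neurons), np.nan)
    for b, (s, e) in enumerate(zip(table.onsets, table.offsets)):
        seg = S[:, s:e] > 0
        has = seg.any(axis=1)
        first = seg.argmax(axis=1)
        ranks[b, has] = first[has]
    return RankMatrix(ranks, table.offsets - table.onsets)


def rank_shuffle(ranks: RankMatrix, rng: np.random.Generator) -> RankMatrix:
    """Surrogate destroying across-neuron rank correlations: each neuron's
    rank vector is independently permuted across bursts, exactly preserving
    its rank multiset (and hence its mean rank)."""
    if ranks.n_bursts < 2:
        raise ValueError("need at least 2 bursts to shuffle")
    shuffled = ranks.ranks.copy()
    for j in range(shuffled.shape[1]):
        shuffled[:, j] = shuffled[rng.permutation(ranks.n_bursts), j]
    return RankMatrix(shuffled, ranks.durations_bins.copy())


def _pairwise_min_distance(a: RankMatrix, b: RankMatrix,
                           missing: str = "duration"):
    """For each burst (row) of ``a``, Euclidean distance to its closest
    burst in ``b`` over rank vectors.

    missing="duration": NaNs are replaced by the own burst's duration in
    bins, padding all bursts to a common vector space.
    missing="participating": each pair is compared over neurons active in
    both bursts; pairs with empty overlap are skipped, and a burst of ``a``
    with no comparable partner is excluded (returned mask False).
    """
    if missing == "duration":
        A, B = a.filled(), b.filled()
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(d2.min(axis=1)), np.ones(a.n_bursts, bool)
    if missing != "participating":
        raise ValueError("missing must be 'duration' or 'participating'")
    dmin = np.full(a.n_bursts, np.inf)
    for i in range(a.n_bursts):
        for j in range(b.n_bursts):
            both = ~np.isnan(a.ranks[i]) & ~np.isnan(b.ranks[j])
            if not both.any():
                continue
            d = np.sqrt(((a.ranks[i, both] - b.ranks[j, both]) ** 2).sum())
            dmin[i] = min(dmin[i], d)
    ok = np.isfinite(dmin)
    return dmin, ok


def nearest_burst_comparison(data_ranks: RankMatrix, sim_ranks: RankMatrix,
                             surrogate_ranks: RankMatrix,
                             reference_surrogates: tuple = None,
                             missing: str = "duration") -> dict:
    """Are simulated bursts closer to data bursts than shuffled ones?

    For each data burst computes the distance to the closest simulated
    burst (d_sim) and to the closest surrogate burst (d_shuff); the
    distribution of d_shuff − d_sim is compared against a null built the
    same way from two independent surrogates, with a two-sample t-test.
    """
    d_sim, ok1 = _pairwise_min_distance(data_ranks, sim_ranks, missing)
    d_shuff, ok2 = _pairwise_min_distance(data_ranks, surrogate_ranks, missing)
    ok = ok1 & ok2
    diff = d_shuff[ok] - d_sim[ok]
    out = {"d_sim_min": d_sim[ok], "d_shuff_min": d_shuff[ok], "diff": diff,
           "n_excluded": int((~ok).sum())}
    if reference_surrogates is not None:
        ra, rb = reference_surrogates
        d_a, oka = _pairwise_min_distance(data_ranks, ra, missing)
        d_b, okb = _pairwise_min_distance(data_ranks, rb, missing)
        okr = oka & okb
        out["null_diff"] = d_a[okr] - d_b[okr]
        if diff.size >= 2 and out["null_diff"].size >= 2:
            stat, p = ttest_ind(diff, out["null_diff"], equal_var=False)
            out["t_stat"], out["p_value"] = float(stat), float(p)
    return out


# ---------------------------------------------------------------------------
# electrode layout and kernel-distance profiles

@dataclass
class ElectrodeLayout:
    """Channel → 2-D grid position map with an inter-electrode pitch."""

    positions: np.ndarray    # (n_channels, 2) in grid units
    pitch: float = 1.0       # physical units per grid step
    channels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        if self.channels is None:
            self.channels = np.arange(len(self.positions))
        uniq = {tuple(p) for p in self.positions}
        if len(uniq) != len(self.positions):
            raise ValueError("electrode positions must be unique")

    @classmethod
    def mea_grid(cls, side: int = 8, drop_corners: bool = True,
                 pitch: float = 1.0) -> "ElectrodeLayout":
        """Standard square MEA grid (default 8×8 minus the four corners,
        60 channels)."""
        pos = [(x, y) for y in range(side) for x in range(side)
               if not (drop_corners and (x in (0, side - 1)) and (y in (0, side - 1)))]
        return cls(np.array(pos, float), pitch=pitch)

    def distances(self) -> np.ndarray:
        """Pairwise physical distances, (n, n)."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d ** 2).sum(axis=2)) * self.pitch

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels,
                             "x": self.positions[:, 0],
                             "y": self.positions[:, 1]})


def kernel_distance_profile(params: ModelParams, layout: ElectrodeLayout,
                            n_bins: int = 8) -> dict:
    """Absolute synaptic-kernel area versus electrode distance, split by
    sign, with exponential-decay fits A·exp(−d/ξ) to the binned means.

    Returns per-pair tables and the fitted length constants ``xi_exc`` and
    ``xi_inh`` (NaN with a flag when a fit is impossible or the profile is
    flat)."""
    n = params.n_neurons
    if len(layout.positions) < n:
        raise ValueError("layout does not cover all neurons")
    areas = params.kernel_areas()
    dist = layout.distances()[:n, :n]
    off = ~np.eye(n, dtype=bool)
    pairs = pd.DataFrame({"distance": dist[off], "area": areas[off]})
    out = {"pairs": pairs}
    for label, sel in (("exc", pairs.area > 0), ("inh", pairs.area < 0)):
        sub = pairs[sel]
        out[f"n_{label}"] = int(sel.sum())
        xi = np.nan
        flag = None
        if len(sub) >= 4:
            edges = np.linspace(sub.distance.min(), sub.distance.max(), n_bins + 1)
            idx = np.clip(np.digitize(sub.distance, edges) - 1, 0, n_bins - 1)
            means = np.array([np.abs(sub.area[idx == k]).mean()
                              if (idx == k).any() else np.nan
                              for k in range(n_bins)])
            centers = 0.5 * (edges[:-1] + edges[1:])
            good = ~np.isnan(means)
            if good.sum() >= 2:
                try:
                    (amp, xi), _ = curve_fit(
                        lambda d, A, x: A * np.exp(-d / x),
                        centers[good], means[good],
                        p0=(means[good][0], max(centers[good].mean(), 1e-3)),
                        maxfev=10_000)
                    if xi <= 0 or xi > 100 * centers[good].max():
                        flag = "flat or non-decaying profile"
                        xi = np.inf if xi > 0 else np.nan
                except RuntimeError:
                    flag = "fit did not converge"
            else:
                flag = "fewer than 2 distance bins"
            out[f"binned_{label}"] = (centers[good], means[good])
        else:
            flag = "too few pairs"
        out[f"xi_{label}"] = float(xi)
        if flag:
            out[f"flag_{label}"] = flag
    return out
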