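"""Ensemble statistics of growing SAWs and fiber walks.

Reproduces the model's headline observables:

* stopping-time distributions (empirical CDF of the walk length at which a
  walk first reaches a stopping configuration) and their two-sample
  Kolmogorov-Smirnov comparison,
* mean-square-displacement (MSD) scaling: the log-log slope of the mean
  squared origin-to-tip Euclidean distance versus step count gives the
  scaling exponent nu = slope / 2 (an ordinary diffusive walk has nu = 1/2),
  fitted by least squares inside an automatically detected scaling region
  with a bootstrap standard error,
* contraction scaling: the log-log slope of the mean cumulative merge count
  versus step count, a measure of the overall expanded area (reported as
  the raw slope, not halved),
* edge-length class tallies of fiber edges and self-avoiding edges.

Stopping-time ensembles run walks to their natural stopping configuration
(restart policy ``none``); scaling ensembles push every walk to a fixed
length with depth-first backtracking, which deliberately overrides natural
stopping.  The two protocols are kept strictly separate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidConfigurationError,
    InvalidInputError,
    InvalidModeError,
)
from .walk_core import (
    FIBER_WALK,
    RESTART_BACKTRACK,
    RESTART_NONE,
    RESTART_REJECTION,
    UnresolvableWalkError,
    WalkConfig,
    derive_walk_seed,
    simulate_walk,
)


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of a walk ensemble."""

    dimension: int = 2
    mode: str = FIBER_WALK
    n_walks: int = 1000
    max_steps: int = 200
    seed: int = 0
    restart_policy: str = RESTART_NONE
    min_length: Optional[int] = None   # target length for scaling runs

    def __post_init__(self):
        if self.n_walks < 1:
            raise InvalidConfigurationError("n_walks must be >= 1")
        if self.max_steps < 1:
            raise InvalidConfigurationError("max_steps must be >= 1")

    def walk_config(self, index: int, attempt: int = 0) -> WalkConfig:
        return WalkConfig(dimension=self.dimension, mode=self.mode,
                          max_steps=self.max_steps,
                          seed=derive_walk_seed(self.seed, index, attempt),
                          restart_policy=self.restart_policy)


# ----------------------------------------------------------------------
# stopping times
# ----------------------------------------------------------------------
@dataclass
class StoppingTimeResult:
    """Stopping lengths of an ensemble run to natural termination."""

    lengths: np.ndarray          # walk length at stop (censored at max_steps)
    censored: np.ndarray         # True where the walk reached max_steps unstopped
    config: EnsembleConfig

    @property
    def median(self) -> float:
        return float(np.median(self.lengths))

    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF (non-decreasing, right-continuous) of the lengths."""
        xs = np.sort(self.lengths)
        ys = np.arange(1, len(xs) + 1) / len(xs)
        return xs, ys


def stopping_time_ensemble(config: EnsembleConfig) -> StoppingTimeResult:
    """Run ``n_walks`` walks to natural stopping (or censoring at max_steps)."""
    if config.restart_policy != RESTART_NONE:
        raise InvalidConfigurationError(
            "stopping-time ensembles must not restart trapped walks")
    lengths = np.empty(config.n_walks, dtype=np.int64)
    censored = np.zeros(config.n_walks, dtype=bool)
    for i in range(config.n_walks):
        state = simulate_walk(config.walk_config(i))
        lengths[i] = state.n_steps
        censored[i] = not state.stopped
    return StoppingTimeResult(lengths=lengths, censored=censored, config=config)


def two_sample_ks(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: returns (D statistic, p-value)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("KS test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# scaling ensembles
# ----------------------------------------------------------------------
@dataclass
class ScalingEnsemble:
    """Per-walk trajectories of a fixed-length (backtracked) ensemble."""

    disp2: np.ndarray            # (n_walks, max_steps) squared origin-tip distance
    merges: np.ndarray           # (n_walks, max_steps) cumulative merge count
    steps: np.ndarray            # 1 .. max_steps
    n_reseeded: int              # walks restarted with a fresh derived seed
    config: EnsembleConfig


def scaling_ensemble(config: EnsembleConfig) -> ScalingEnsemble:
    """Run ``n_walks`` walks of exactly ``max_steps`` steps for scaling fits.

    Trapped walks are resolved by the walk-level restart policy (backtrack
    by default).  A walk whose backtracking budget is exhausted is re-run
    with a deterministically derived fresh seed and counted in
    ``n_reseeded``.
    """
    if config.restart_policy not in (RESTART_BACKTRACK, RESTART_REJECTION):
        raise InvalidConfigurationError(
            "scaling ensembles need a restart policy (backtrack or rejection)")
    n, m = config.n_walks, config.max_steps
    disp2 = np.empty((n, m), dtype=float)
    merges = np.empty((n, m), dtype=float)
    n_reseeded = 0
    for i in range(n):
        state = None
        for attempt in range(100):
            try:
                state = simulate_walk(config.walk_config(i, attempt))
                break
            except UnresolvableWalkError:
                n_reseeded += 1
        if state is None:  # pragma: no cover - would need 100 failures
            raise UnresolvableWalkError(f"walk {i} failed 100 reseed attempts")
        origin = np.asarray(state.fiber.origin, dtype=float)
        path = np.asarray(state.fiber.vertex_sequence[1:], dtype=float)
        disp2[i] = ((path - origin) ** 2).sum(axis=1)
        merges[i] = np.cumsum([len(ev.merges) for ev in state.event_log])
    return ScalingEnsemble(disp2=disp2, merges=merges,
                           steps=np.arange(1, m + 1), n_reseeded=n_reseeded,
                           config=config)


@dataclass
class MSDCurve:
    """Mean squared origin-to-tip displacement per step."""

    steps: np.ndarray
    msd: np.ndarray
    n_contributing: np.ndarray


def msd_curve(source) -> MSDCurve:
    """MSD curve of a scaling ensemble (or an EnsembleConfig, which is run)."""
    if isinstance(source, EnsembleConfig):
        source = scaling_ensemble(source)
    n = np.full(source.disp2.shape[1], source.disp2.shape[0])
    return MSDCurve(steps=source.steps, msd=source.disp2.mean(axis=0),
                    n_contributing=n)


# ----------------------------------------------------------------------
# scaling-region detection and log-log fits
# ----------------------------------------------------------------------
def _local_slopes(logx: np.ndarray, logy: np.ndarray, window: int) -> np.ndarray:
    """Centered finite-difference log-log slopes with a ``window``-point span."""
    half = window // 2
    m = len(logx)
    idx = np.arange(m)
    lo = np.clip(idx - half, 0, m - 1)
    hi = np.clip(idx + half, 0, m - 1)
    return (logy[hi] - logy[lo]) / (logx[hi] - logx[lo])


def detect_scaling_region(steps, values, threshold: float = 0.1,
                          start: int = 30, window: int = 5,
                          n_grid: int = 33) -> tuple[int, int]:
    """Maximal suffix of steps over which the log-log slope has settled.

    Local slopes are centered finite differences with a ``window``-point
    span, evaluated on a log-uniform resampling of the curve (``n_grid``
    points) so that the window covers a fixed step *ratio* rather than a
    fixed step count; on per-step points the late-curve spacing would be
    far too small for Monte-Carlo noise.  Returns the step interval
    ``[s, max]`` with ``s >= start`` such that every local slope from ``s``
    onwards deviates from the terminal slope by less than ``threshold``.
    """
    steps = np.asarray(steps, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = values > 0
    steps, values = steps[keep], values[keep]
    if len(steps) == 0 or steps[-1] < start:
        raise InsufficientDataError(
            f"curve must extend to at least step {start}")
    grid = np.unique(np.geomspace(steps[0], steps[-1], n_grid).round().astype(int))
    gi = np.searchsorted(steps, grid)
    gsteps = steps[np.clip(gi, 0, len(steps) - 1)]
    gvals = values[np.clip(gi, 0, len(steps) - 1)]
    logx, logy = np.log(gsteps), np.log(gvals)
    local = _local_slopes(logx, logy, window)
    # clamped edge windows are shorter and noisier; only interior points
    # (full centered window) take part in the settling test
    half = window // 2
    interior = slice(half, len(gsteps) - half if len(gsteps) > 2 * half else None)
    terminal = float(np.mean(local[interior][-window:]))
    bad = np.zeros(len(gsteps), dtype=bool)
    bad[interior] = np.abs(local[interior] - terminal) >= threshold
    last_bad = np.nonzero(bad)[0]
    lo = start
    if last_bad.size:
        nxt = int(last_bad[-1]) + 1
        if nxt >= len(gsteps):
            raise InsufficientDataError("no settled scaling region found")
        lo = max(start, int(gsteps[nxt]))
    if lo > steps[-1] - 2:
        raise InsufficientDataError("no settled scaling region found")
    return lo, int(steps[-1])


@dataclass
class ScalingFit:
    """Least-squares log-log fit inside a scaling region."""

    exponent: float              # the reported scaling exponent
    slope: float                 # raw log-log slope of the fitted line
    region: tuple[int, int]
    exponent_se: float           # bootstrap standard error of the exponent
    n_boot: int = 0

    @property
    def nu(self) -> float:
        """MSD convention alias (for MSD fits exponent == nu == slope/2)."""
        return self.exponent

    @property
    def nu_se(self) -> float:
        return self.exponent_se


def _loglog_slope(logx: np.ndarray, logy: np.ndarray) -> float:
    xc = logx - logx.mean()
    return float((xc @ logy) / (xc @ xc))


def _fit_loglog(steps, mean_curve, region, per_walk=None, n_boot: int = 1000,
                seed: int = 0, halve: bool = False) -> ScalingFit:
    steps = np.asarray(steps, dtype=float)
    mean_curve = np.asarray(mean_curve, dtype=float)
    lo, hi = region
    mask = (steps >= lo) & (steps <= hi) & (mean_curve > 0)
    if mask.sum() < 3:
        raise InsufficientDataError("fewer than 3 points in the scaling region")
    logx = np.log(steps[mask])
    slope = _loglog_slope(logx, np.log(mean_curve[mask]))
    se = 0.0
    if per_walk is not None and n_boot > 0:
        sub = np.asarray(per_walk, dtype=float)[:, mask]
        rng = np.random.default_rng(seed)
        n = sub.shape[0]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            means = sub[rng.integers(0, n, n)].mean(axis=0)
            reps[b] = _loglog_slope(logx, np.log(means))
        se = float(reps.std(ddof=1))
    factor = 0.5 if halve else 1.0
    return ScalingFit(exponent=factor * slope, slope=slope,
                      region=(lo, hi), exponent_se=factor * se, n_boot=n_boot)


def fit_exponent(curve: MSDCurve, region: tuple[int, int],
                 ensemble: Optional[ScalingEnsemble] = None,
                 n_boot: int = 1000, seed: int = 0) -> ScalingFit:
    """MSD scaling exponent nu = (log-log slope)/2 with bootstrap SE.

    The bootstrap resamples whole walks (not steps) with replacement when
    the per-walk ensemble is supplied.
    """
    per_walk = ensemble.disp2 if ensemble is not None else None
    return _fit_loglog(curve.steps, curve.msd, region, per_walk=per_walk,
                       n_boot=n_boot, seed=seed, halve=True)


def msd_scaling(config: EnsembleConfig,
                ensemble: Optional[ScalingEnsemble] = None,
                threshold: float = 0.1, start: int = 30,
                n_boot: int = 1000) -> ScalingFit:
    """Full MSD pipeline: ensemble -> curve -> region -> fitted nu."""
    if ensemble is None:
        ensemble = scaling_ensemble(config)
    curve = msd_curve(ensemble)
    region = detect_scaling_region(curve.steps, curve.msd,
                                   threshold=threshold, start=start)
    return fit_exponent(curve, region, ensemble=ensemble, n_boot=n_boot,
                        seed=config.seed)


def contraction_scaling(config: EnsembleConfig,
                        ensemble: Optional[ScalingEnsemble] = None,
                        threshold: float = 0.1, start: int = 30,
                        n_boot: int = 1000) -> ScalingFit:
    """Log-log scaling exponent of the mean cumulative merge count.

    Uses the same region rule and walk-level bootstrap as the MSD fit; the
    exponent is the raw slope (merge counts grow near-linearly).
    """
    if config.mode != FIBER_WALK:
        raise InvalidModeError("contraction scaling requires fiber-walk mode")
    if ensemble is None:
        ensemble = scaling_ensemble(config)
    mean_curve = ensemble.merges.mean(axis=0)
    region = detect_scaling_region(ensemble.steps, mean_curve,
                                   threshold=threshold, start=start)
    return _fit_loglog(ensemble.steps, mean_curve, region,
                       per_walk=ensemble.merges, n_boot=n_boot,
                       seed=config.seed, halve=False)


# ----------------------------------------------------------------------
# edge-length classes
# ----------------------------------------------------------------------
@dataclass
class EdgeLengthTally:
    """Counts of exact edge-length classes over an ensemble."""

    fiber: Counter = field(default_factory=Counter)
    self_avoiding: Counter = field(default_factory=Counter)


def _length_class(length: float) -> float:
    return round(length, 6)


def edge_length_histogram(config: EnsembleConfig) -> EdgeLengthTally:
    """Tally fiber-edge and self-avoiding-edge length classes.

    In a 2D fiber walk the fiber classes are a subset of {1, sqrt(2), 2} and
    the self-avoiding classes a subset of {1, sqrt(2), 2, sqrt(5), 3}; a
    growing SAW only ever produces unit edges.
    """
    tally = EdgeLengthTally()
    for i in range(config.n_walks):
        state = simulate_walk(config.walk_config(i))
        for length in state.fiber.step_lengths:
            tally.fiber[_length_class(length)] += 1
        for e in state.lattice.edges():
            if e.self_avoiding and not e.in_fiber:
                tally.self_avoiding[_length_class(e.length)] += 1
    return tally


# ----------------------------------------------------------------------
# ordinary random walk control
# ----------------------------------------------------------------------
def random_walk_control(n_walks: int, n_steps: int, dimension: int = 2,
                        seed: int = 0) -> ScalingEnsemble:
    """Ordinary (non-avoiding) lattice random walk, the diffusive anchor.

    The simple random walk has <R^2>(N) = N exactly, i.e. nu = 1/2; fitting
    its simulated MSD validates the exponent pipeline.
    """
    rng = np.random.default_rng(seed)
    dirs = np.zeros((2 * dimension, dimension), dtype=np.int64)
    for axis in range(dimension):
        dirs[2 * axis, axis] = 1
        dirs[2 * axis + 1, axis] = -1
    choices = rng.integers(0, 2 * dimension, size=(n_walks, n_steps))
    paths = np.cumsum(dirs[choices], axis=1)
    disp2 = (paths.astype(float) ** 2).sum(axis=2)
    cfg = EnsembleConfig(dimension=dimension, mode=FIBER_WALK, n_walks=n_walks,
                         max_steps=n_steps, seed=seed,
                         restart_policy=RESTART_BACKTRACK)
    return ScalingEnsemble(disp2=disp2, merges=np.zeros_like(disp2),
                           steps=np.arange(1, n_steps + 1), n_reseeded=0,
                           config=cfg)
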