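"""Cluster statistics, percolation and growth-law classification.

The "largest cluster of interacting spins" — the connected component over
attractive bonds — proxies the elastic protein network of the film; its
growth law is the headline observable.  Cluster growth in the steady-state
window is classified as linear vs. exponential by corrected-AIC model
selection between a straight-line fit of size vs. time and a straight-line
fit of log size vs. time (with the log-normal Jacobian term, so the two
likelihoods are comparable on the original scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .lattice import LatticeConfig
from .spin_model import InteractionTable


@dataclass
class ClusterLabeling:
    """Partition of occupied sites into bond-connected clusters.

    ``labels`` has lattice shape with -1 on vacant sites; ``sizes[k]`` and
    ``wraps[k]`` give the site count and periodic-winding flag of cluster k.
    """

    labels: np.ndarray
    sizes: np.ndarray
    wraps: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def label_clusters(cfg: LatticeConfig, table: InteractionTable) -> ClusterLabeling:
    """Connected components of occupied sites over attractive bonds.

    A cluster percolates (wraps) when some cycle of bonds closes with
    nonzero net periodic displacement; detected by relative-displacement
    bookkeeping during the flood fill.
    """
    labels_flat, sizes, wraps = _kernels.label_clusters_kernel(
        cfg.spins, table.cls)
    labels = labels_flat.reshape(cfg.height, cfg.width)
    return ClusterLabeling(labels=labels, sizes=sizes,
                           wraps=wraps.astype(bool))


def largest_cluster_size(labeling: ClusterLabeling) -> int:
    """Size of the largest cluster (0 for an empty lattice)."""
    return int(labeling.sizes.max()) if labeling.n_clusters else 0


def detect_percolation(labeling: ClusterLabeling) -> bool:
    """True iff any cluster wraps either periodic direction."""
    return bool(labeling.wraps.any())


# ---------------------------------------------------------------------------
# growth-law classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowPolicy:
    """Steady-state window: records after the filling phase (occupancy first
    exceeding ``occupancy_fraction`` of its final plateau, estimated as the
    mean over the trailing ``plateau_tail`` of records) and strictly before
    the first percolating record."""

    occupancy_fraction: float = 0.9
    plateau_tail: float = 0.1
    min_points: int = 10
    #: optionally also discard records before this sweep (used by asymptotic
    #: power-law fits that must drop the early transient)
    min_sweep: float | None = None


@dataclass
class GrowthFit:
    """Linear-vs-exponential classification of largest-cluster growth."""

    window: tuple[int, int]              # (start_sweep, end_sweep), inclusive
    n_points: int
    intercept: float
    slope: float
    slope_se: float
    aicc_linear: float
    log_intercept: float
    rate: float
    rate_se: float
    aicc_exponential: float
    label: str                           # linear | exponential | indeterminate
    diagnostic: str = ""

    @property
    def delta_aicc(self) -> float:
        """AICc(linear) - AICc(exponential); positive favours exponential."""
        return self.aicc_linear - self.aicc_exponential


@dataclass
class CoarseningFit:
    """Power-law exponent of largest-cluster area vs. time (log-log slope)."""

    exponent: float
    stderr: float
    window: tuple[int, int]
    n_points: int


def steady_state_window(series, policy: WindowPolicy | None = None) -> tuple[int, int]:
    """Indices ``(i0, i1)`` (inclusive) of the steady-state records."""
    policy = policy or WindowPolicy()
    df = series.data
    n = len(df)
    if n == 0:
        raise ValueError("empty time series")
    nocc = df["n_occupied"].to_numpy(dtype=float)
    tail = max(1, int(math.ceil(policy.plateau_tail * n)))
    plateau = nocc[-tail:].mean()
    filled = np.nonzero(nocc >= policy.occupancy_fraction * plateau)[0]
    i0 = int(filled[0]) if len(filled) else n - 1
    if policy.min_sweep is not None:
        sw = df["sweep"].to_numpy()
        late = np.nonzero(sw >= policy.min_sweep)[0]
        if len(late):
            i0 = max(i0, int(late[0]))
    perc = np.nonzero(df["percolated"].to_numpy() > 0)[0]
    i1 = int(perc[0]) - 1 if len(perc) else n - 1
    return i0, i1


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit y = a + b x; returns (a, b, se_b, rss)."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = max(n - 2, 1)
    sxx = float(((x - x.mean()) ** 2).sum())
    se_b = math.sqrt(max(rss / dof, 0.0) / sxx) if sxx > 0 else float("inf")
    return float(coef[0]), float(coef[1]), se_b, rss

_K_PARAMS = 3  # intercept, slope, residual variance


def _aicc(n: int, rss: float, extra: float = 0.0) -> float:
    """Gaussian AICc from a residual sum of squares (plus a log-Jacobian
    term ``extra`` for models fitted on a transformed response)."""
    k = _K_PARAMS
    rss = max(rss, n * 1e-30)
    aic = n * math.log(rss / n) + 2 * k + extra
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def classify_growth(series, window_policy: WindowPolicy | None = None) -> GrowthFit:
    """Classify largest-cluster growth in the steady-state window.

    Linear model: ``size = a + b t`` (Gaussian errors).  Exponential model:
    ``log size = c + r t`` (log-normal errors; its AICc carries the
    ``2 * sum(log size)`` Jacobian term so the two models are compared as
    densities of the same variable).  The label is decided by AICc with a
    margin of 2; smaller margins give ``indeterminate``.
    """
    policy = window_policy or WindowPolicy()
    i0, i1 = steady_state_window(series, policy)
    df = series.data.iloc[i0:i1 + 1]
    df = df[df["largest_cluster"] > 0]
    n = len(df)
    nan = float("nan")
    if n < policy.min_points:
        return GrowthFit((int(df["sweep"].iloc[0]) if n else -1,
                          int(df["sweep"].iloc[-1]) if n else -1),
                         n, nan, nan, nan, nan, nan, nan, nan, nan,
                         "indeterminate",
                         f"steady-state window too short ({n} points, "
                         f"need {policy.min_points})")
    t = df["sweep"].to_numpy(dtype=float)
    y = df["largest_cluster"].to_numpy(dtype=float)
    a, b, se_b, rss_lin = _ols_line(t, y)
    logy = np.log(y)
    c, r, se_r, rss_log = _ols_line(t, logy)
    aicc_lin = _aicc(n, rss_lin)
    aicc_exp = _aicc(n, rss_log, extra=2.0 * float(logy.sum()))
    delta = aicc_lin - aicc_exp
    if delta > 2.0:
        label = "exponential"
    elif delta < -2.0:
        label = "linear"
    else:
        label = "indeterminate"
    return GrowthFit(window=(int(t[0]), int(t[-1])), n_points=n,
                     intercept=a, slope=b, slope_se=se_b,
                     aicc_linear=aicc_lin, log_intercept=c, rate=r,
                     rate_se=se_r, aicc_exponential=aicc_exp, label=label)


def estimate_coarsening_exponent(series,
                                 window_policy: WindowPolicy | None = None,
                                 ) -> CoarseningFit:
    """Log-log slope of largest-cluster size vs. sweep on the steady-state
    window (the domain-coarsening growth exponent; area ~ t for 2D Potts
    coarsening, i.e. radius ~ t^1/2)."""
    policy = window_policy or WindowPolicy(min_points=5)
    i0, i1 = steady_state_window(series, policy)
    df = series.data.iloc[i0:i1 + 1]
    df = df[df["sweep"] > 0]
    y = df["largest_cluster"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("cluster sizes must be positive on the window")
    if len(df) < max(policy.min_points, 5):
        raise ValueError("too few points for a coarsening fit")
    t = df["sweep"].to_numpy(dtype=float)
    _, slope, se, _ = _ols_line(np.log(t), np.log(y))
    return CoarseningFit(exponent=slope, stderr=se,
                         window=(int(t[0]), int(t[-1])), n_points=len(df))
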