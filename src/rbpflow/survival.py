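"""Kaplan-Meier estimation, log-rank testing, and best-cutoff stratification.

The product-limit estimator and the two-sample log-rank statistic are
implemented directly (and cross-validated against lifelines in the test
suite).  "Best cutoff" stratification scans a quantile grid of expression
thresholds, reports the minimum log-rank p, and always accompanies it with a
grid-size Bonferroni adjustment because the scan is anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

DEFAULT_GRID = np.round(np.arange(0.10, 0.9001, 0.05), 10)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve over the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        assert (s <= 1 + 1e-12).all() and (s >= -1e-12).all()
        assert (np.diff(s) <= 1e-12).all()

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    Censored observations at an event time are processed after the events at
    that time (they remain in the risk set for it).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise InvalidInputError("empty survival input")
    if times.size != events.size:
        raise InvalidInputError("times and events differ in length")
    if (times <= 0).any():
        raise InvalidInputError("survival times must be > 0")

    event_times = np.unique(times[events == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_j = int((times >= t).sum())
        d_j = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_j / n_j
        surv[i] = s
        at_risk[i] = n_j
        d[i] = d_j
    return KMEstimate(event_times, surv, at_risk, d)


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-sample log-rank (Mantel-Cox) test.

    Each group is a frame with columns ``time`` and ``event``.  Returns the
    1-df chi-square statistic and its p-value.  Identical groups give
    statistic 0, p = 1.
    """
    for g, name in ((group_a, "A"), (group_b, "B")):
        if len(g) == 0:
            raise InvalidInputError(f"group {name} is empty")
    ta = group_a["time"].to_numpy(dtype=float)
    ea = group_a["event"].to_numpy(dtype=int)
    tb = group_b["time"].to_numpy(dtype=float)
    eb = group_b["event"].to_numpy(dtype=int)
    return _logrank_arrays(ta, ea, tb, eb)


def _logrank_arrays(ta, ea, tb, eb) -> tuple[float, float]:
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    event_times = np.unique(all_times[all_events == 1])
    if event_times.size == 0:
        return 0.0, 1.0

    # at-risk and event counts at each distinct event time, per group
    n1 = (ta[:, None] >= event_times[None, :]).sum(axis=0)
    n2 = (tb[:, None] >= event_times[None, :]).sum(axis=0)
    d1 = ((ta[:, None] == event_times[None, :]) & (ea[:, None] == 1)).sum(axis=0)
    d2 = ((tb[:, None] == event_times[None, :]) & (eb[:, None] == 1)).sum(axis=0)
    n = n1 + n2
    d = d1 + d2

    expected1 = d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    var = np.where(n > 1, var, 0.0)
    o_minus_e = float((d1 - expected1).sum())
    v = float(var.sum())
    if v == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class CutoffResult:
    """Best-cutoff scan outcome with raw and Bonferroni-adjusted p."""

    cutoff: float
    quantile: float
    p_raw: float
    p_bonferroni: float
    n_grid: int
    low: tuple[str, ...]
    high: tuple[str, ...]


def best_cutoff(
    table: pd.DataFrame,
    grid=DEFAULT_GRID,
    min_group_frac: float = 0.10,
) -> CutoffResult:
    """Minimum-p expression cutoff over a quantile grid.

    ``table`` needs columns ``time``, ``event``, ``expression`` (sample ids
    in the index).  At each grid quantile samples split into low
    (expression <= cutoff) and high; grid points leaving either group below
    ``min_group_frac * n`` are skipped.  The reported raw minimum p is
    anti-conservative; a Bonferroni adjustment over the number of feasible
    grid points is always attached.  Ties in p are broken toward the median
    quantile.
    """
    required = {"time", "event", "expression"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"survival table needs columns {sorted(required)}")
    expr = table["expression"].to_numpy(dtype=float)
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    n = len(table)
    min_size = min_group_frac * n

    candidates = []
    for q in np.asarray(grid, dtype=float):
        cut = float(np.quantile(expr, q))
        low_mask = expr <= cut
        n_low = int(low_mask.sum())
        if n_low < min_size or (n - n_low) < min_size:
            continue
        chi2, p = _logrank_arrays(t[low_mask], e[low_mask],
                                  t[~low_mask], e[~low_mask])
        candidates.append((p, abs(q - 0.5), q, cut, low_mask))
    if not candidates:
        raise InvalidInputError(
            "no feasible grid point (degenerate expression values?)"
        )
    n_grid = len(candidates)
    p_min, _, q_best, cut_best, low_mask = min(candidates, key=lambda c: (c[0], c[1]))
    samples = table.index.to_numpy()
    return CutoffResult(
        cutoff=cut_best,
        quantile=float(q_best),
        p_raw=float(p_min),
        p_bonferroni=float(min(1.0, p_min * n_grid)),
        n_grid=n_grid,
        low=tuple(str(s) for s in samples[low_mask]),
        high=tuple(str(s) for s in samples[~low_mask]),
    )


def median_split(table: pd.DataFrame) -> tuple[float, float]:
    """Log-rank chi-square and p for a median expression split."""
    expr = table["expression"].to_numpy(dtype=float)
    cut = float(np.median(expr))
    low = expr <= cut
    if low.all() or not low.any():
        raise InvalidInputError("median split yields one empty group")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    return _logrank_arrays(t[low], e[low], t[~low], e[~low])
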