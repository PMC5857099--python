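"""qPCR quantification and transcript decay kinetics.

Relative quantification follows the delta-delta-Ct scheme; decay constants
are estimated from transcription-inhibition time courses.  The primary
estimator is the ordinary least-squares slope of ln(abundance) on time — the
best-fit line on a semilog plot — with a direct nonlinear exponential fit
available behind ``method="nls"``.  Half-life is ln(2)/k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


def ddct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Relative expression per sample/gene by the delta-delta-Ct method.

    ``table`` is tidy with columns ``sample``, ``gene``, ``replicate``,
    ``ct``.  Replicate Ct values are averaged on the Ct scale, then
    dCt = Ct(target) - Ct(reference) per sample, ddCt = dCt - dCt(calibrator)
    and relative expression = 2**(-ddCt).  Samples lacking the reference gene
    are skipped with a logged warning.
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"Ct table needs columns {sorted(required)}")
    mean_ct = table.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    if reference_gene not in mean_ct.columns:
        raise InvalidInputError(f"reference gene {reference_gene!r} absent")
    if calibrator_sample not in mean_ct.index:
        raise InvalidInputError(f"calibrator sample {calibrator_sample!r} absent")

    no_ref = mean_ct[reference_gene].isna()
    if no_ref.any():
        logger.warning(
            "samples without reference Ct skipped: %s",
            mean_ct.index[no_ref].tolist(),
        )
        mean_ct = mean_ct.loc[~no_ref]

    dct = mean_ct.sub(mean_ct[reference_gene], axis=0)
    ddct_values = dct.sub(dct.loc[calibrator_sample], axis=1)
    rel = 2.0 ** (-ddct_values)
    targets = [g for g in rel.columns if g != reference_gene]
    out = rel[targets].stack().rename("relative_expression").reset_index()
    return out


def normalize_to_control(
    raw: pd.DataFrame,
    control: pd.DataFrame,
    value_col: str = "abundance",
) -> pd.DataFrame:
    """Divide a target series by the endogenous control, anchor t=0 at 1.

    Both frames are tidy with columns ``gene``, ``condition``, ``replicate``,
    ``time`` and ``value_col``; the control is matched on (condition,
    replicate, time).  After the elementwise division each (gene, condition)
    is rescaled so the mean at t=0 equals 1.
    """
    keys = ["condition", "replicate", "time"]
    ctrl = control.set_index(keys)[value_col]
    if (ctrl == 0).any():
        bad = ctrl.index[ctrl == 0].tolist()
        raise InvalidInputError(f"zero control abundance at {bad[:5]}")
    out = raw.copy()
    matched = ctrl.reindex(pd.MultiIndex.from_frame(raw[keys]))
    if matched.isna().any():
        raise InvalidInputError("control series missing matching samples")
    out[value_col] = raw[value_col].to_numpy() / matched.to_numpy()

    def _anchor(group: pd.DataFrame) -> pd.DataFrame:
        at0 = group.loc[group["time"] == 0, value_col]
        if at0.empty or at0.mean() == 0:
            raise InvalidInputError("series lacks a usable t=0 anchor")
        group[value_col] = group[value_col] / at0.mean()
        return group

    return (
        out.groupby(["gene", "condition"], group_keys=False)[out.columns]
        .apply(_anchor)
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit: rate, half-life, and fit diagnostics."""

    k_decay: float
    t_half: float
    se_k: float
    r_squared: float
    n_points: int
    decaying: bool
    method: str = "loglinear"

    def __post_init__(self) -> None:
        if self.decaying and self.k_decay > 0:
            assert math.isclose(self.t_half * self.k_decay, LN2)


def _halflife(k: float) -> float:
    return LN2 / k if k > 0 else math.inf


def fit_decay(
    tc: pd.DataFrame,
    time_col: str = "time",
    value_col: str = "abundance",
    method: str = "loglinear",
) -> DecayFit:
    """Fit a first-order decay constant to a time course.

    Replicate points are pooled into a single regression.  With
    ``method="loglinear"`` (primary) k is minus the OLS slope of
    ln(abundance) on time; non-positive abundances are dropped with a
    warning.  ``method="nls"`` performs nonlinear least squares on
    A*exp(-k*t), initialized from the log-linear estimate.  A non-negative
    slope yields k=0 with the fit flagged non-decaying (t_half infinite).
    """
    t = tc[time_col].to_numpy(dtype=float)
    y = tc[value_col].to_numpy(dtype=float)
    keep = y > 0
    if (~keep).any():
        logger.warning("%d non-positive abundances dropped", int((~keep).sum()))
        t, y = t[keep], y[keep]
    if len(np.unique(t)) < 3:
        raise InvalidInputError("need >= 3 distinct timepoints")

    res = stats.linregress(t, np.log(y))
    k = -res.slope
    se = res.stderr
    r2 = res.rvalue**2

    if method == "nls":
        k0 = max(k, 1e-6)
        a0 = float(np.exp(res.intercept))

        def model(tt, a, kk):
            return a * np.exp(-kk * tt)

        popt, pcov = optimize.curve_fit(
            model, t, y, p0=(a0, k0), maxfev=10000
        )
        k = float(popt[1])
        se = float(np.sqrt(pcov[1, 1]))
        resid = y - model(t, *popt)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    elif method != "loglinear":
        raise InvalidInputError(f"unknown fit method {method!r}")

    if k <= 0:
        return DecayFit(0.0, math.inf, float(se), float(r2), len(t), False,
                        method)
    return DecayFit(float(k), _halflife(k), float(se), float(r2), len(t),
                    True, method)


@dataclass(frozen=True)
class StabilityComparison:
    """Half-life ratio between two conditions plus an interaction p-value."""

    ratio: float | None
    p_value: float | None
    applicable: bool
    slope_difference: float | None = None


def compare_stability(
    fit_a: DecayFit,
    fit_b: DecayFit,
    tc_a: pd.DataFrame,
    tc_b: pd.DataFrame,
    time_col: str = "time",
    value_col: str = "abundance",
) -> StabilityComparison:
    """Ratio of half-lives a/b with a slope-difference (interaction) test.

    The p-value comes from the time x condition interaction term of a joint
    OLS regression of ln(abundance) on time.  When either fit is
    non-decaying the result is flagged not applicable (no exception).
    """
    if not (fit_a.decaying and fit_b.decaying):
        return StabilityComparison(None, None, False)

    frames = []
    for cond, tc in ((0.0, tc_a), (1.0, tc_b)):
        t = tc[time_col].to_numpy(dtype=float)
        y = tc[value_col].to_numpy(dtype=float)
        keep = y > 0
        frames.append(
            pd.DataFrame({"t": t[keep], "lny": np.log(y[keep]), "cond": cond})
        )
    data = pd.concat(frames, ignore_index=True)
    X = sm.add_constant(
        pd.DataFrame(
            {
                "t": data["t"],
                "cond": data["cond"],
                "t_cond": data["t"] * data["cond"],
            }
        )
    )
    model = sm.OLS(data["lny"], X).fit()
    p = float(model.pvalues["t_cond"])
    slope_diff = float(model.params["t_cond"])
    if not math.isfinite(p):  # perfectly collinear / zero-residual toy input
        p = 1.0
    return StabilityComparison(
        ratio=fit_a.t_half / fit_b.t_half,
        p_value=p,
        applicable=True,
        slope_difference=slope_diff,
    )


def fit_decay_table(
    tc: pd.DataFrame,
    by: tuple[str, ...] = ("gene", "condition"),
    method: str = "loglinear",
) -> pd.DataFrame:
    """Fit every (gene, condition) series in a tidy time-course table."""
    rows = []
    for key, sub in tc.groupby(list(by), sort=True):
        fit = fit_decay(sub, method=method)
        rows.append(
            dict(zip(by, key if isinstance(key, tuple) else (key,)))
            | {
                "k_decay": fit.k_decay,
                "t_half": fit.t_half,
                "se_k": fit.se_k,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "decaying": fit.decaying,
            }
        )
    return pd.DataFrame(rows)
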