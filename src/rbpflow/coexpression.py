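"""Cohort log2-CPM transformation, composite expression groups, and
immune-factor co-expression calls.

Sample groups are built from single- or two-gene extreme quantiles: for a
pair, the high group is the intersection of both genes' top-q samples (and
analogously for low).  Immune-factor differential expression between the
groups uses Welch t-tests with BH adjustment and a log2 fold-change gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyGroupError, InvalidInputError, UndefinedCorrelationError

logger = logging.getLogger(__name__)


def logcpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """log2 counts per million: log2((count + 0.5) / (libsize + 1) * 1e6)."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise InvalidInputError("library sizes must be > 0")
    return np.log2((counts + 0.5).div(library_sizes + 1.0, axis=1) * 1e6)


@dataclass(frozen=True)
class CompositeGroups:
    """High/low sample partitions from one- or two-gene quantile rules."""

    genes: tuple[str, ...]
    quantile: float
    high: tuple[str, ...]
    low: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise InvalidInputError("high and low groups overlap")


def _extreme_samples(
    row: pd.Series, n_take: int, top: bool
) -> list[str]:
    # deterministic tie-break: by sample id order within equal values
    order = row.reset_index()
    order.columns = ["sample", "value"]
    order = order.sort_values(
        ["value", "sample"], ascending=[not top, True], kind="mergesort"
    )
    return order["sample"].head(n_take).tolist()


def composite_groups(
    expr: pd.DataFrame,
    genes: str | tuple[str, ...] | list[str],
    q: float = 0.30,
) -> CompositeGroups:
    """Build high/low groups from the top/bottom-q samples of one or two genes.

    Single gene: high = top floor(q*n) samples by expression, low = bottom
    floor(q*n).  Pair: high (low) = intersection of both genes' top (bottom)
    sets.  Ties are broken by sample id order (logged).  Empty high or low
    groups raise :class:`EmptyGroupError`.
    """
    if isinstance(genes, str):
        genes = (genes,)
    genes = tuple(genes)
    if not 0 < q < 0.5:
        raise InvalidInputError(f"quantile q must be in (0, 0.5), got {q}")
    if len(genes) not in (1, 2):
        raise InvalidInputError("composite groups need one or two genes")
    for g in genes:
        if g not in expr.index:
            raise InvalidInputError(f"gene {g!r} absent from expression matrix")

    n = expr.shape[1]
    n_take = int(np.floor(q * n))
    if n_take == 0:
        raise EmptyGroupError(f"q={q} with n={n} samples selects no samples")

    tops, bottoms = [], []
    for g in genes:
        row = expr.loc[g]
        if row.duplicated().any():
            logger.info("ties in %s broken by sample id order", g)
        tops.append(set(_extreme_samples(row, n_take, top=True)))
        bottoms.append(set(_extreme_samples(row, n_take, top=False)))
    high = set.intersection(*tops)
    low = set.intersection(*bottoms)
    if not high or not low:
        raise EmptyGroupError(
            f"empty composite group for {genes} at q={q} "
            f"(|high|={len(high)}, |low|={len(low)})"
        )
    order = {s: i for i, s in enumerate(expr.columns)}
    return CompositeGroups(
        genes=genes,
        quantile=q,
        high=tuple(sorted(high, key=order.get)),
        low=tuple(sorted(low, key=order.get)),
    )


def immune_de(
    expr: pd.DataFrame,
    groups: CompositeGroups,
    immune_list: list[str] | set[str],
    lfc_gate: float = 0.75,
    p_gate: float = 0.01,
    linear_fold: bool = False,
) -> pd.DataFrame:
    """Immune-factor differential expression between composite groups.

    Per immune gene: logFC = mean(high) - mean(low) on log2-CPM values,
    Welch t-test p, BH q.  A gene passes when |logFC| >= lfc_gate and
    p <= p_gate (``linear_fold=True`` reinterprets the gate as a linear fold
    change).  Negative logFC means higher expression in the low group
    (anti-correlation with the index gene/pair).  Z-score rows over the
    included samples are attached for heatmaps.
    """
    immune_list = list(dict.fromkeys(immune_list))
    if not immune_list:
        raise InvalidInputError("immune gene list is empty")
    if not groups.high or not groups.low:
        raise InvalidInputError("composite groups are empty")
    present = [g for g in immune_list if g in expr.index]
    absent = set(immune_list) - set(present)
    if absent:
        logger.warning("%d immune genes absent from matrix", len(absent))
    if not present:
        raise InvalidInputError("no immune gene present in the matrix")

    gate = np.log2(lfc_gate) if linear_fold else lfc_gate
    hi = expr.loc[present, list(groups.high)].to_numpy(dtype=float)
    lo = expr.loc[present, list(groups.low)].to_numpy(dtype=float)
    logfc = hi.mean(axis=1) - lo.mean(axis=1)
    _, p = stats.ttest_ind(hi, lo, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"logFC": logfc, "p_value": p, "q_value": q},
        index=pd.Index(present, name="gene"),
    )
    out["passes"] = (np.abs(out["logFC"]) >= gate) & (out["p_value"] <= p_gate)
    z = zscore_rows(
        expr.loc[present, list(groups.high) + list(groups.low)]
    )
    return out.join(z.add_prefix("z::"))


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("need two equal-length vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-row Z scores using the population standard deviation (divisor n).

    Constant rows are returned as zeros with a logged warning.
    """
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d constant rows z-scored to zeros", int(flat.sum()))
    sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)
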