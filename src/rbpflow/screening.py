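"""Multi-dataset prioritization of RBP genes from two-group expression data.

The screen takes three independent two-group expression datasets, median
centers each gene, tests the group difference per gene with a two-sample
t-test, ranks significantly down-regulated RBP genes into percentiles, and
admits genes into a high-priority set through three union rules.  Candidates
are then filtered by their copy-number deletion fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

RULE_ALL_THREE = "all_three"
RULE_TOP5_ANY_ONE = "top5_any_one"
RULE_TOP10_ANY_TWO = "top10_any_two"


@dataclass
class ExpressionDataset:
    """Genes x samples log2-intensity matrix with a two-level sample grouping.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    groups
        Series mapping sample id to one of exactly two group labels.
    reference
        The label of the reference group (log fold changes are
        case minus reference).  Defaults to the lexicographically
        smaller label.
    name
        Optional dataset label used in provenance columns.
    """

    values: pd.DataFrame
    groups: pd.Series
    reference: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.values.empty:
            raise InvalidInputError("expression matrix is empty")
        if self.values.index.has_duplicates:
            raise InvalidInputError("duplicate gene ids in expression matrix")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise InvalidInputError(f"samples without group label: {missing}")
        levels = sorted(self.groups.unique())
        if len(levels) != 2:
            raise InvalidInputError(
                f"expected exactly two group levels, got {levels}"
            )
        counts = self.groups.value_counts()
        if (counts < 2).any():
            raise InvalidInputError("each group needs at least 2 samples")
        if self.reference is None:
            self.reference = levels[0]
        if self.reference not in levels:
            raise InvalidInputError(
                f"reference group {self.reference!r} not in {levels}"
            )

    @property
    def case(self) -> str:
        """The non-reference group label."""
        return next(g for g in sorted(self.groups.unique()) if g != self.reference)

    def group_columns(self, label: str) -> pd.Index:
        return self.groups.index[self.groups == label]


def median_center(dataset: ExpressionDataset) -> ExpressionDataset:
    """Center every gene row so its median across all samples is zero."""
    if not np.isfinite(dataset.values.to_numpy()).all():
        raise InvalidInputError("non-finite values in expression matrix")
    centered = dataset.values.sub(dataset.values.median(axis=1), axis=0)
    return ExpressionDataset(
        centered, dataset.groups.copy(), dataset.reference, dataset.name
    )


def two_group_ttest(
    dataset: ExpressionDataset, *, welch: bool = False
) -> pd.DataFrame:
    """Per-gene two-sample t-test between the two groups.

    Returns a DataFrame indexed by gene with columns ``mean_ref``,
    ``mean_case``, ``log_fold_change`` (case minus reference),
    ``t_statistic`` and ``p_value``.  The pooled-variance (Student) test is
    the default; ``welch=True`` switches to unequal variances.  Genes with
    zero variance in both groups and equal means get t=0, p=1 by convention.
    """
    ref_cols = dataset.group_columns(dataset.reference)
    case_cols = dataset.group_columns(dataset.case)
    ref = dataset.values[ref_cols].to_numpy(dtype=float)
    case = dataset.values[case_cols].to_numpy(dtype=float)

    t, p = stats.ttest_ind(case, ref, axis=1, equal_var=not welch)
    mean_ref = ref.mean(axis=1)
    mean_case = case.mean(axis=1)
    diff = mean_case - mean_ref

    # scipy yields nan when the pooled variance vanishes
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        equal = degenerate & np.isclose(diff, 0.0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        separated = degenerate & ~np.isclose(diff, 0.0)
        with np.errstate(invalid="ignore"):
            t = np.where(separated, np.sign(diff) * np.inf, t)
        p = np.where(separated, 0.0, p)

    return pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_case": mean_case,
            "log_fold_change": diff,
            "t_statistic": t,
            "p_value": p,
        },
        index=dataset.values.index,
    )


def rank_top_down(
    stats_table: pd.DataFrame,
    rbp_ids: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Percentile-rank significantly down-regulated RBP genes.

    Restricts to RBP genes with ``p_value < alpha`` and negative log fold
    change, ranks them ascending by fold change (most down-regulated first)
    and assigns ``down_rank_percentile = rank / n_ranked``.  Ties are broken
    by smaller p-value, then gene id.  Non-qualifying RBP genes keep NaN.
    """
    rbp_ids = set(rbp_ids)
    missing = rbp_ids - set(stats_table.index)
    if missing:
        logger.warning(
            "%d RBP ids absent from the stats table (ignored)", len(missing)
        )
    table = stats_table.loc[stats_table.index.isin(rbp_ids)].copy()
    table["down_rank_percentile"] = np.nan

    gate = (table["p_value"] < alpha) & (table["log_fold_change"] < 0)
    qualifying = (
        table.loc[gate]
        .assign(_gene=lambda df: df.index)
        .sort_values(["log_fold_change", "p_value", "_gene"], kind="mergesort")
    )
    n = len(qualifying)
    if n:
        table.loc[qualifying.index, "down_rank_percentile"] = (
            np.arange(1, n + 1) / n
        )
    return table


def select_high_priority(
    rankings: Sequence[pd.DataFrame],
    thr_score: float = 0.10,
    thr_any1: float = 0.05,
    thr_any2: float = 0.10,
) -> pd.DataFrame:
    """Union of the three admission rules over exactly three ranking tables.

    A gene "scores" in a dataset when its percentile is <= ``thr_score``.
    Admission rules: scoring in all three datasets; percentile <=
    ``thr_any1`` in at least one dataset; percentile <= ``thr_any2`` in at
    least two datasets.  The result carries per-dataset percentiles and a
    boolean column per rule plus a comma-joined ``rules`` provenance column.
    """
    if len(rankings) != 3:
        raise InvalidInputError(
            f"select_high_priority needs exactly 3 ranking tables, got {len(rankings)}"
        )
    pct = pd.DataFrame(
        {
            f"pct_{i + 1}": r["down_rank_percentile"]
            for i, r in enumerate(rankings)
        }
    )
    cols = [f"pct_{i}" for i in (1, 2, 3)]
    scored = pct[cols].le(thr_score)  # NaN -> False
    all_three = scored.all(axis=1)
    any_one = pct[cols].le(thr_any1).any(axis=1)
    any_two = pct[cols].le(thr_any2).sum(axis=1) >= 2

    out = pct.copy()
    out[RULE_ALL_THREE] = all_three
    out[RULE_TOP5_ANY_ONE] = any_one
    out[RULE_TOP10_ANY_TWO] = any_two
    member = all_three | any_one | any_two
    out = out.loc[member]
    out["rules"] = out[[RULE_ALL_THREE, RULE_TOP5_ANY_ONE, RULE_TOP10_ANY_TWO]].apply(
        lambda row: ",".join(name for name, hit in row.items() if hit), axis=1
    )
    return out.sort_index()


@dataclass
class CNATable:
    """Per-gene fractions of samples with deletion / amplification."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for col in ("fraction_deleted", "fraction_amplified"):
            if col not in self.table.columns:
                raise InvalidInputError(f"CNA table missing column {col!r}")
            vals = self.table[col]
            if ((vals < 0) | (vals > 1)).any():
                raise InvalidInputError(f"{col} outside [0, 1]")


def filter_by_deletion(
    priority_genes: Iterable[str],
    cna: CNATable | pd.DataFrame,
    min_fraction: float = 0.05,
) -> list[str]:
    """Keep priority genes deleted in strictly more than ``min_fraction``.

    Genes absent from the CNA table are dropped with a logged warning; the
    result is sorted descending by deletion fraction.
    """
    table = cna.table if isinstance(cna, CNATable) else CNATable(cna).table
    genes = list(priority_genes)
    absent = [g for g in genes if g not in table.index]
    if absent:
        logger.warning("%d priority genes missing from CNA table", len(absent))
    present = [g for g in genes if g in table.index]
    fracs = table.loc[present, "fraction_deleted"]
    kept = fracs[fracs > min_fraction]
    return kept.sort_values(ascending=False, kind="mergesort").index.tolist()
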