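"""Calling bound, down-regulated, and destabilized transcripts.

Combines three evidence layers for an RNA-binding protein: RIP-seq
enrichment over input and IgG libraries, steady-state down-regulation in
knockdown vs control, and loss of stability after transcription inhibition.
Also annotates peak intervals against minimal gene models and implements the
3'UTR-length qPCR assay comparison.

All genomic coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

REGION_PRIORITY = ("3'UTR", "5'UTR", "CDS", "intron", "intergenic")


@dataclass
class CountMatrix:
    """Transcripts x samples non-negative integer counts.

    ``library_sizes`` are the per-sample mapped-read totals (may exceed the
    column sums); ``lengths`` are transcript lengths in bp (needed only for
    RPKM).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.library_sizes <= 0).any():
            raise InvalidInputError("library sizes must be > 0")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)

    def cpm(self, pseudocount: float = 0.0) -> pd.DataFrame:
        """Counts per million mapped reads (optionally with a pseudocount
        added to the CPM values, not the counts)."""
        out = self.counts.div(self.library_sizes, axis=1) * 1e6
        return out + pseudocount if pseudocount else out


def compute_rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = count / ((length / 1000) * (library size / 1e6)).
    """
    if counts.lengths is None:
        raise InvalidInputError("transcript lengths required for RPKM")
    if (counts.lengths <= 0).any():
        raise InvalidInputError("transcript lengths must be > 0")
    per_kb = counts.counts.div(counts.lengths / 1e3, axis=0)
    return per_kb.div(counts.library_sizes / 1e6, axis=1)


@dataclass
class RIPExperiment:
    """Per-transcript counts for the IP, input, and (optional) IgG libraries."""

    counts: pd.DataFrame  # columns: ip, input, igg (igg optional)
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        for col in ("ip", "input"):
            if col not in self.counts.columns:
                raise InvalidInputError(f"RIP counts missing column {col!r}")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("negative RIP counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.library_sizes <= 0).any():
            raise InvalidInputError("RIP library sizes must be > 0")

    @property
    def has_igg(self) -> bool:
        return "igg" in self.counts.columns


def call_bound(
    rip: RIPExperiment,
    min_fold_vs_input: float = 2.0,
    min_fold_vs_igg: float = 2.0,
    min_input_cpm: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Call transcripts bound by the protein from RIP-seq enrichment.

    A transcript is bound when log2((IP_cpm+pc)/(input_cpm+pc)) >=
    log2(min_fold_vs_input), the analogous IgG enrichment >=
    log2(min_fold_vs_igg), and its input CPM >= ``min_input_cpm``.  With no
    IgG library the IgG criterion is skipped with a logged warning.
    """
    cpm = rip.counts.div(rip.library_sizes, axis=1) * 1e6
    enr_input = np.log2((cpm["ip"] + pseudocount) / (cpm["input"] + pseudocount))
    out = pd.DataFrame(
        {
            "input_cpm": cpm["input"],
            "enrichment_input": enr_input,
        }
    )
    bound = (enr_input >= np.log2(min_fold_vs_input)) & (
        cpm["input"] >= min_input_cpm
    )
    if rip.has_igg:
        enr_igg = np.log2((cpm["ip"] + pseudocount) / (cpm["igg"] + pseudocount))
        out["enrichment_igg"] = enr_igg
        bound &= enr_igg >= np.log2(min_fold_vs_igg)
    else:
        logger.warning("no IgG library; falling back to input-only calling")
    out["bound"] = bound
    return out


@dataclass
class GeneModel:
    """Minimal transcript structure for region annotation."""

    transcript_id: str
    chrom: str
    strand: str
    exons: Sequence[tuple[int, int]]
    cds: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InvalidInputError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise InvalidInputError(
                    f"{self.transcript_id}: malformed exon ({start}, {end})"
                )
            if start < prev_end:
                raise InvalidInputError(
                    f"{self.transcript_id}: overlapping exons"
                )
            prev_end = end
        cs, ce = self.cds
        if cs >= ce:
            raise InvalidInputError(f"{self.transcript_id}: malformed CDS")
        if not (self._in_exon(cs) and self._in_exon(ce - 1)):
            raise InvalidInputError(
                f"{self.transcript_id}: CDS not contained in exons"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def _in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def region_of(self, pos: int) -> str | None:
        """Region of a genomic position within this transcript (or None)."""
        if not (self.start <= pos < self.end):
            return None
        if not self._in_exon(pos):
            return "intron"
        cs, ce = self.cds
        if cs <= pos < ce:
            return "CDS"
        left_of_cds = pos < cs
        if self.strand == "+":
            return "5'UTR" if left_of_cds else "3'UTR"
        return "3'UTR" if left_of_cds else "5'UTR"

    def distance_to_stop(self, pos: int) -> int:
        """Signed bp from ``pos`` to the last CDS base in transcript
        orientation (negative = upstream of the stop)."""
        cs, ce = self.cds
        if self.strand == "+":
            return pos - (ce - 1)
        return cs - pos


@dataclass
class Peak:
    """A peak interval assigned to a region of a transcript."""

    chrom: str
    start: int
    end: int
    transcript_id: str | None = None
    region: str | None = None
    distance_to_stop: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidInputError(
                f"malformed peak interval ({self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def annotate_peak_region(
    peak: Peak, models: Iterable[GeneModel]
) -> Peak:
    """Label a peak by the region its midpoint falls in.

    Among all transcripts overlapping the midpoint the label with the highest
    priority (3'UTR > 5'UTR > CDS > intron) wins; with no overlap the peak is
    intergenic.  The returned peak carries the winning transcript id and the
    signed distance from the midpoint to that transcript's stop codon.
    """
    mp = peak.midpoint
    best: tuple[int, int, str, GeneModel] | None = None
    for model in models:
        if model.chrom != peak.chrom:
            continue
        region = model.region_of(mp)
        if region is None:
            continue
        rank = REGION_PRIORITY.index(region)
        dist = model.distance_to_stop(mp)
        key = (rank, abs(dist))
        if best is None or key < (best[0], best[1]):
            best = (rank, abs(dist), region, model)
    if best is None:
        return Peak(peak.chrom, peak.start, peak.end, None, "intergenic", None,
                    peak.name)
    _, _, region, model = best
    return Peak(
        peak.chrom,
        peak.start,
        peak.end,
        model.transcript_id,
        region,
        model.distance_to_stop(mp),
        peak.name,
    )


def region_distribution(
    peaks: Iterable[Peak], models: Iterable[GeneModel]
) -> pd.Series:
    """Counts of annotated peaks per region label."""
    models = list(models)
    labels = [annotate_peak_region(p, models).region for p in peaks]
    return (
        pd.Series(labels, dtype="object")
        .value_counts()
        .reindex(REGION_PRIORITY, fill_value=0)
    )


@dataclass(frozen=True)
class SelectionResult:
    """A called transcript set plus the per-transcript evidence table."""

    table: pd.DataFrame = field(repr=False)
    selected: frozenset = field(default_factory=frozenset)


def steady_state_down(
    expr_kd: CountMatrix,
    expr_ctrl: CountMatrix,
    min_fold: float = 1.1,
    max_q: float = 0.05,
    pseudocount: float = 0.5,
) -> SelectionResult:
    """Transcripts down-regulated at steady state in knockdown vs control.

    Linear fold change = mean control CPM / mean knockdown CPM (with
    pseudocount); p-values come from a two-sided t-test on log2 CPM and are
    BH-adjusted.  Selection requires fold > min_fold (strict) and q < max_q.
    """
    for cm, label in ((expr_kd, "knockdown"), (expr_ctrl, "control")):
        if cm.counts.shape[1] < 2:
            raise InvalidInputError(
                f"{label} has a single replicate; re-run with a "
                "fold-change-only mode flag (not yet requested)"
            )
    common = expr_kd.counts.index.intersection(expr_ctrl.counts.index)
    kd_cpm = expr_kd.cpm(pseudocount).loc[common]
    ct_cpm = expr_ctrl.cpm(pseudocount).loc[common]
    fold = ct_cpm.mean(axis=1) / kd_cpm.mean(axis=1)
    _, p = stats.ttest_ind(
        np.log2(kd_cpm.to_numpy()), np.log2(ct_cpm.to_numpy()), axis=1
    )
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"fold_down": fold, "p_value": p, "q_value": q}, index=common
    )
    table["selected"] = (table["fold_down"] > min_fold) & (table["q_value"] < max_q)
    return SelectionResult(table, frozenset(table.index[table["selected"]]))


def compute_stability_measures(
    kd_t0: CountMatrix,
    kd_t9: CountMatrix,
    ctrl_t0: CountMatrix,
    ctrl_t9: CountMatrix,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Knockdown-vs-control log fold changes at both timepoints.

    ``stability_delta`` is the late-minus-early difference of the kd/ctrl
    log2 fold changes; this equals the log2 ratio of the two conditions'
    retention fractions.
    """
    common = kd_t0.counts.index
    for cm in (kd_t9, ctrl_t0, ctrl_t9):
        common = common.intersection(cm.counts.index)

    def logfc(kd: CountMatrix, ctrl: CountMatrix) -> pd.Series:
        kd_mean = kd.cpm(pseudocount).loc[common].mean(axis=1)
        ct_mean = ctrl.cpm(pseudocount).loc[common].mean(axis=1)
        return np.log2(kd_mean) - np.log2(ct_mean)

    out = pd.DataFrame(
        {"logfc_0h": logfc(kd_t0, ctrl_t0), "logfc_9h": logfc(kd_t9, ctrl_t9)},
        index=common,
    )
    out["stability_delta"] = out["logfc_9h"] - out["logfc_0h"]
    return out


def destabilized_set(
    measures: pd.DataFrame, min_fold: float = 1.1
) -> SelectionResult:
    """Transcripts whose stability contrast drops more than ``min_fold``.

    Selection: stability_delta < -log2(min_fold), strict.  Transcripts with a
    missing timepoint log fold change are skipped with a logged warning.
    """
    table = measures.copy()
    if "stability_delta" not in table.columns:
        table["stability_delta"] = table["logfc_9h"] - table["logfc_0h"]
    missing = table[["logfc_0h", "logfc_9h"]].isna().any(axis=1)
    if missing.any():
        logger.warning(
            "%d transcripts missing a timepoint; skipped", int(missing.sum())
        )
        table = table.loc[~missing]
    table["selected"] = table["stability_delta"] < -math.log2(min_fold)
    return SelectionResult(table, frozenset(table.index[table["selected"]]))


def intersect_targets(
    bound: Iterable[str],
    down: Iterable[str],
    destab: Iterable[str],
) -> tuple[pd.DataFrame, dict]:
    """Per-transcript flags and the triple-intersection summary.

    The summary reports ``pct_of_bound`` — the triple intersection as a
    percentage of the bound set — rounded to two decimals (exact rational
    arithmetic; the unrounded value is kept in ``pct_of_bound_exact``).  With
    an empty bound set the percentage is not applicable (None).
    """
    bound, down, destab = set(bound), set(down), set(destab)
    ids = sorted(bound | down | destab)
    table = pd.DataFrame(
        {
            "bound": [t in bound for t in ids],
            "steady_down": [t in down for t in ids],
            "destabilized": [t in destab for t in ids],
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    table["in_intersection"] = (
        table["bound"] & table["steady_down"] & table["destabilized"]
    )
    n_triple = int(table["in_intersection"].sum())
    summary = {
        "n_bound": len(bound),
        "n_down": len(down),
        "n_destab": len(destab),
        "n_intersection": n_triple,
    }
    if bound:
        exact = Fraction(100 * n_triple, len(bound))
        summary["pct_of_bound"] = round(float(exact), 2)
        summary["pct_of_bound_exact"] = float(exact)
    else:
        summary["pct_of_bound"] = None
        summary["pct_of_bound_exact"] = None
    return table, summary


def secreted_filter(
    targets: Sequence[str], secreted_ids: Iterable[str]
) -> list[str]:
    """Order-preserving intersection with a user-supplied secreted-gene list."""
    secreted = set(secreted_ids)
    return [t for t in targets if t in secreted]


def utr_length_assay(
    levels: pd.DataFrame,
    cds_amplicon: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, str]:
    """Compare distal-3'UTR/CDS amplicon ratios between two conditions.

    ``levels`` is tidy with columns ``amplicon``, ``condition``,
    ``replicate``, ``level``.  Per replicate each amplicon's level is divided
    by the CDS amplicon's level; per amplicon a two-sided t-test on the log
    ratios compares the two conditions, BH-adjusted across amplicons.  The
    verdict is "no length change" when nothing passes ``alpha``.
    """
    required = {"amplicon", "condition", "replicate", "level"}
    if not required.issubset(levels.columns):
        raise InvalidInputError(f"levels table needs columns {sorted(required)}")
    conditions = sorted(levels["condition"].unique())
    if len(conditions) != 2:
        raise InvalidInputError(
            f"need exactly two conditions, got {conditions}"
        )
    if cds_amplicon not in set(levels["amplicon"]):
        raise InvalidInputError(f"CDS amplicon {cds_amplicon!r} missing")

    wide = levels.pivot_table(
        index=["condition", "replicate"], columns="amplicon", values="level"
    )
    for cond in conditions:
        sub = wide.loc[cond]
        if sub[cds_amplicon].isna().any() or len(sub) < 2:
            raise InvalidInputError(
                f"condition {cond!r} needs the CDS amplicon in >= 2 replicates"
            )
    ratios = wide.div(wide[cds_amplicon], axis=0)
    amplicons = [a for a in ratios.columns if a != cds_amplicon]
    if not amplicons:
        raise InvalidInputError("no distal amplicon beyond the CDS amplicon")

    rows = []
    for amp in amplicons:
        a = np.log(ratios.loc[conditions[0], amp].dropna())
        b = np.log(ratios.loc[conditions[1], amp].dropna())
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.isclose(
            a.mean(), b.mean()
        ):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "amplicon": amp,
                f"ratio_{conditions[0]}": float(np.exp(a.mean())),
                f"ratio_{conditions[1]}": float(np.exp(b.mean())),
                "t_statistic": float(t),
                "p_value": float(p),
            }
        )
    table = pd.DataFrame(rows).set_index("amplicon")
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["flagged"] = table["q_value"] < alpha
    verdict = "length change" if table["flagged"].any() else "no length change"
    return table, verdict


def read_gtf_models(path) -> list[GeneModel]:
    """Read minimal gene models (exon/CDS features) from a GTF file.

    GTF intervals are 1-based closed and converted to 0-based half-open.
    """
    cols = [
        "chrom", "source", "feature", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    tid = df["attributes"].str.extract(r'transcript_id "([^"]+)"')[0]
    if tid.isna().any():
        raise InvalidInputError("GTF record without transcript_id attribute")
    models = []
    for transcript, sub in df.assign(tid=tid).groupby("tid", sort=True):
        exons = [
            (int(r.start) - 1, int(r.end))
            for r in sub[sub.feature == "exon"].itertuples()
        ]
        cds_rows = sub[sub.feature == "CDS"]
        if not len(exons) or not len(cds_rows):
            raise InvalidInputError(
                f"transcript {transcript!r} lacks exon or CDS features"
            )
        cds = (int(cds_rows["start"].min()) - 1, int(cds_rows["end"].max()))
        models.append(
            GeneModel(
                transcript_id=str(transcript),
                chrom=str(sub["chrom"].iloc[0]),
                strand=str(sub["strand"].iloc[0]),
                exons=exons,
                cds=cds,
            )
        )
    return models


def read_bed_peaks(path) -> list[Peak]:
    """Read peaks from a BED6 file (0-based half-open, as BED is)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        Peak(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
             name=str(r.name))
        for r in df.itertuples(index=False)
    ]
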