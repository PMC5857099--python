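"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be simulated here: two-group
log-intensity matrices with planted down-regulated RBP genes, copy-number
fraction tables, negative-binomial RIP-seq and transcription-inhibition
count matrices, decay time courses, expression cohorts with planted gene-gene
correlations, survival tables with expression-proportional hazards, and an
exact Venn membership fixture.

One global seed expands into independent per-generator substreams, so adding
or re-running one generator never perturbs another.  Count noise is negative
binomial with a user-set dispersion; ``dispersion -> 0`` degenerates to
Poisson.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, VennInfeasibleError
from .targets import CountMatrix, GeneModel, Peak, RIPExperiment

logger = logging.getLogger(__name__)

_STREAMS = {
    "screen": 0,
    "cna": 1,
    "rip": 2,
    "stability": 3,
    "timecourse": 4,
    "cohort": 5,
    "survival": 6,
    "venn": 7,
}


@dataclass
class SimulationConfig:
    """Knobs shared by all generators; defaults mirror the study design
    where printed (354 cohort samples, 0/2/4/6/8 h timepoints, a 9 h
    stability contrast) and are freely overridable."""

    n_genes: int = 1000
    n_rbp_genes: int = 100
    samples_per_group: int = 10
    planted_logfc: float = -1.0
    noise_sd: float = 0.5
    nb_dispersion: float = 0.05
    rip_enrichment_fold: float = 8.0
    half_life_hours: Mapping[str, float] = field(
        default_factory=lambda: {"control": 9.0, "knockdown": 4.5}
    )
    hazard_beta: float = 0.0
    seed: int = 0

    # screen planting layout: a small focal tier planted down in all three
    # datasets at planted_logfc, a decoy tier planted in exactly two
    # datasets at a scaled effect (populates the percentile ranking pool),
    # and a null tier
    screen_n_all3: int = 2
    screen_decoy_scale: float = 0.45
    screen_n_null_rbp: int = 7

    # stability / timecourse design
    stability_hours: float = 9.0
    timepoints: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0)
    tc_noise: float = 0.10
    tc_replicates: int = 3
    stability_replicates: int = 2  # per the two-replicate shut-off design

    # cohort / survival design
    n_cohort_samples: int = 354
    censoring_rate: float = 0.30
    base_hazard: float = 0.05  # events per month at expression z=0

    # "none" emits expected means instead of sampled counts, giving exact
    # zero-noise limits for the closed-form checks
    count_noise: str = "nb"

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_rbp_genes <= 0:
            raise InvalidConfigError("gene counts must be positive")
        if self.n_rbp_genes > self.n_genes:
            raise InvalidConfigError("n_rbp_genes cannot exceed n_genes")
        if self.samples_per_group < 2:
            raise InvalidConfigError("need >= 2 samples per group")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be >= 0")
        if self.rip_enrichment_fold <= 1:
            raise InvalidConfigError("rip_enrichment_fold must be > 1")
        for cond, hl in self.half_life_hours.items():
            if hl <= 0:
                raise InvalidConfigError(f"non-positive half-life for {cond!r}")
        if not 0 <= self.censoring_rate < 1:
            raise InvalidConfigError("censoring_rate must be in [0, 1)")
        if self.count_noise not in ("nb", "none"):
            raise InvalidConfigError("count_noise must be 'nb' or 'none'")
        if self.tc_noise < 0:
            raise InvalidConfigError("tc_noise must be >= 0")
        if self.screen_n_all3 + self.screen_n_null_rbp > self.n_rbp_genes:
            raise InvalidConfigError("screen tiers exceed n_rbp_genes")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream of the global seed for one generator."""
        seq = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(seq)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["half_life_hours"] = dict(self.half_life_hours)
        d["timepoints"] = list(self.timepoints)
        return d


def _nb(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial draw with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _counts(rng: np.random.Generator, mean, config: SimulationConfig):
    """NB-sampled counts, or the expected means in the zero-noise limit."""
    if config.count_noise == "none":
        return np.asarray(mean, dtype=float)
    return _nb(rng, mean, config.nb_dispersion)


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    rbp = [f"RBP{i:04d}" for i in range(1, config.n_rbp_genes + 1)]
    other = [
        f"GENE{i:04d}"
        for i in range(config.n_rbp_genes + 1, config.n_genes + 1)
    ]
    return rbp, other


# ---------------------------------------------------------------------------
# screening inputs
# ---------------------------------------------------------------------------

DATASET_NAMES = ("cancer_state", "metastasis", "stemness")


@dataclass
class ScreenSim:
    datasets: list  # of screening.ExpressionDataset
    truth: pd.DataFrame


def gen_screen_datasets(
    config: SimulationConfig,
    planting: Mapping[str, tuple[Sequence[int], float]] | None = None,
) -> ScreenSim:
    """Three two-group log2 expression matrices with planted down-regulation.

    ``planting`` maps gene id -> (dataset indices, true log2 fold change);
    by default the focal tier (``screen_n_all3`` RBP genes) is planted in all
    three datasets at ``planted_logfc``, a decoy tier of RBP genes is
    planted in exactly two datasets at ``screen_decoy_scale *
    planted_logfc``, and ``screen_n_null_rbp`` RBP genes plus all non-RBP
    genes stay at zero expected group difference.
    """
    from .screening import ExpressionDataset  # deferred: avoid cycle

    rbp, other = _gene_ids(config)
    genes = rbp + other
    if planting is None:
        planting = {}
        focal = rbp[: config.screen_n_all3]
        for g in focal:
            planting[g] = ((0, 1, 2), config.planted_logfc)
        n_decoys = config.n_rbp_genes - config.screen_n_all3 - config.screen_n_null_rbp
        pairs = itertools.cycle([(0, 1), (0, 2), (1, 2)])
        for g, pair in zip(rbp[config.screen_n_all3:config.screen_n_all3 + n_decoys], pairs):
            planting[g] = (pair, config.screen_decoy_scale * config.planted_logfc)
    unknown = set(planting) - set(genes)
    if unknown:
        raise InvalidConfigError(f"planting refers to unknown genes: {unknown}")

    rng = config.rng("screen")
    n = config.samples_per_group
    truth = pd.DataFrame(
        {
            "is_rbp": [g in set(rbp) for g in genes],
            "true_logfc": 0.0,
            **{f"planted_{name}": False for name in DATASET_NAMES},
        },
        index=pd.Index(genes, name="gene"),
    )
    datasets = []
    for d, name in enumerate(DATASET_NAMES):
        base = rng.normal(7.0, 1.0, size=len(genes))
        values = base[:, None] + rng.normal(
            0.0, config.noise_sd, size=(len(genes), 2 * n)
        )
        samples = [f"{name}_ref{i:02d}" for i in range(n)] + [
            f"{name}_case{i:02d}" for i in range(n)
        ]
        df = pd.DataFrame(values, index=genes, columns=samples)
        for g, (ds_idx, lfc) in planting.items():
            if d in ds_idx:
                df.loc[g, samples[n:]] += lfc
                truth.loc[g, f"planted_{name}"] = True
                truth.loc[g, "true_logfc"] = lfc
        groups = pd.Series(
            ["reference"] * n + ["case"] * n, index=samples, name="group"
        )
        datasets.append(
            ExpressionDataset(df, groups, reference="reference", name=name)
        )
    logger.info("gen_screen_datasets seed=%s", config.seed)
    return ScreenSim(datasets, truth)


def gen_cna(
    config: SimulationConfig,
    genes: Sequence[str] | None = None,
    planted: Mapping[str, float] | None = None,
    beta_params: tuple[float, float] = (1.0, 20.0),
) -> pd.DataFrame:
    """Per-gene deleted/amplified sample fractions.

    Background fractions are Beta draws; ``planted`` pins specific genes to
    given deletion fractions (useful for straddling the 5% filter).
    """
    if genes is None:
        rbp, other = _gene_ids(config)
        genes = rbp + other
    planted = dict(planted or {})
    for g, f in planted.items():
        if not 0 <= f <= 1:
            raise InvalidConfigError(f"planted fraction {f} for {g!r} outside [0,1]")
    rng = config.rng("cna")
    table = pd.DataFrame(
        {
            "fraction_deleted": rng.beta(*beta_params, size=len(genes)),
            "fraction_amplified": rng.beta(*beta_params, size=len(genes)),
        },
        index=pd.Index(genes, name="gene"),
    )
    for g, f in planted.items():
        if g not in table.index:
            table.loc[g] = [f, 0.0]
        else:
            table.loc[g, "fraction_deleted"] = f
    logger.info("gen_cna seed=%s", config.seed)
    return table


# ---------------------------------------------------------------------------
# RIP-seq
# ---------------------------------------------------------------------------

@dataclass
class RipSim:
    experiment: RIPExperiment
    peaks: list
    models: list
    truth: pd.DataFrame


def _transcript_ids(n: int) -> list[str]:
    return [f"TX{i:04d}" for i in range(1, n + 1)]


def gen_rip(
    config: SimulationConfig,
    n_transcripts: int = 300,
    bound_ids: Sequence[str] | None = None,
    base_mean: float = 200.0,
    peak_offset: int = 25,
) -> RipSim:
    """RIP-seq IP/input/IgG counts plus peaks and gene models.

    Bound transcripts have an expected IP/input count ratio equal to
    ``rip_enrichment_fold`` with IgG at the unenriched background; every
    bound transcript receives one peak whose midpoint lies in its 3'UTR,
    ``peak_offset`` bp downstream of the stop codon.  Library sizes are set
    to the common nominal depth (sum of the expected input means) so CPM
    ratios equal count-mean ratios.
    """
    ids = _transcript_ids(n_transcripts)
    if bound_ids is None:
        bound_ids = ids[: max(1, n_transcripts // 10)]
    bound = set(bound_ids)
    unknown = bound - set(ids)
    if unknown:
        raise InvalidConfigError(f"bound ids not in transcript set: {unknown}")

    rng = config.rng("rip")
    base = rng.lognormal(mean=math.log(base_mean), sigma=1.0, size=len(ids))
    is_bound = np.array([t in bound for t in ids])
    ip_mean = np.where(is_bound, base * config.rip_enrichment_fold, base)
    counts = pd.DataFrame(
        {
            "ip": _counts(rng, ip_mean, config),
            "input": _counts(rng, base, config),
            "igg": _counts(rng, base, config),
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    depth = float(base.sum())
    libs = pd.Series(depth, index=["ip", "input", "igg"])
    experiment = RIPExperiment(counts, libs)

    models, peaks = [], []
    for i, tid in enumerate(ids):
        s = i * 5000
        strand = "+" if i % 2 == 0 else "-"
        exons = [(s, s + 1500), (s + 2000, s + 3500)]
        if strand == "+":
            cds = (s + 200, s + 3200)  # 3'UTR: [s+3200, s+3500)
            mid = cds[1] - 1 + peak_offset
        else:
            cds = (s + 300, s + 3300)  # 3'UTR: [s, s+300)
            mid = cds[0] - peak_offset
        models.append(GeneModel(tid, "chr1", strand, exons, cds))
        if tid in bound:
            peaks.append(
                Peak("chr1", mid - 15, mid + 16, name=f"peak_{tid}")
            )
    truth = pd.DataFrame(
        {"is_bound": is_bound, "base_mean": base},
        index=pd.Index(ids, name="transcript_id"),
    )
    logger.info("gen_rip seed=%s", config.seed)
    return RipSim(experiment, peaks, models, truth)


# ---------------------------------------------------------------------------
# transcription-inhibition stability counts
# ---------------------------------------------------------------------------

@dataclass
class StabilitySim:
    kd_t0: CountMatrix
    kd_t9: CountMatrix
    ctrl_t0: CountMatrix
    ctrl_t9: CountMatrix
    truth: pd.DataFrame


def gen_stability(
    config: SimulationConfig,
    n_transcripts: int = 300,
    destabilized: Sequence[str] | None = None,
    steady_down: Sequence[str] | None = None,
    steady_down_fold: float = 2.0,
    base_mean: float = 200.0,
) -> StabilitySim:
    """Paired 0 h / t h count matrices for knockdown and control.

    Expected abundance decays as ``A(t) = A(0) * 2**(-t / t_half)`` with the
    condition-specific half-lives from ``config.half_life_hours`` applied to
    the ``destabilized`` transcripts (all other transcripts keep the control
    half-life in both conditions).  ``steady_down`` transcripts start with a
    ``steady_down_fold`` lower baseline in the knockdown.  All libraries use
    one nominal depth so CPM contrasts equal abundance contrasts.
    """
    if steady_down_fold <= 0:
        raise InvalidConfigError("steady_down_fold must be > 0")
    ids = _transcript_ids(n_transcripts)
    if destabilized is None:
        destabilized = ids[:40]
    if steady_down is None:
        steady_down = ids[:30]
    destab, down = set(destabilized), set(steady_down)
    for name, s in (("destabilized", destab), ("steady_down", down)):
        unknown = s - set(ids)
        if unknown:
            raise InvalidConfigError(f"{name} ids not in transcript set: {unknown}")

    hl_ctrl = config.half_life_hours["control"]
    hl_kd = config.half_life_hours["knockdown"]
    t = config.stability_hours
    rng = config.rng("stability")

    base = rng.lognormal(mean=math.log(base_mean), sigma=1.0, size=len(ids))
    is_destab = np.array([x in destab for x in ids])
    is_down = np.array([x in down for x in ids])

    base_kd = np.where(is_down, base / steady_down_fold, base)
    hl_in_kd = np.where(is_destab, hl_kd, hl_ctrl)
    means = {
        ("ctrl", 0.0): base,
        ("ctrl", t): base * 2.0 ** (-t / hl_ctrl),
        ("kd", 0.0): base_kd,
        ("kd", t): base_kd * 2.0 ** (-t / hl_in_kd),
    }
    depth = float(base.sum())

    def matrix(cond: str, tp: float) -> CountMatrix:
        cols = {
            f"{cond}_t{tp:g}_r{r + 1}": _counts(rng, means[(cond, tp)], config)
            for r in range(config.stability_replicates)
        }
        df = pd.DataFrame(cols, index=pd.Index(ids, name="transcript_id"))
        return CountMatrix(df, pd.Series(depth, index=df.columns))

    truth = pd.DataFrame(
        {
            "steady_down": is_down,
            "destabilized": is_destab,
            "half_life_control": hl_ctrl,
            "half_life_knockdown": hl_in_kd,
            "base_mean": base,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    logger.info("gen_stability seed=%s", config.seed)
    return StabilitySim(
        matrix("kd", 0.0), matrix("kd", t), matrix("ctrl", 0.0), matrix("ctrl", t),
        truth,
    )


# ---------------------------------------------------------------------------
# DRB-style decay time course
# ---------------------------------------------------------------------------

@dataclass
class TimeCourseSim:
    timecourse: pd.DataFrame  # gene, condition, replicate, time, abundance
    truth: pd.DataFrame       # gene, condition, k, t_half


def gen_timecourse(
    config: SimulationConfig,
    k_values: Mapping[tuple[str, str], float] | None = None,
) -> TimeCourseSim:
    """Multi-timepoint relative-abundance series with multiplicative noise.

    ``abundance(t) = exp(-k t) * (1 + eps)`` with ``eps ~ N(0, tc_noise)``
    (clipped above -0.9 to keep abundances positive).  By default a single
    gene carries the decay constants implied by ``config.half_life_hours``.
    """
    if k_values is None:
        k_values = {
            ("target", cond): math.log(2.0) / hl
            for cond, hl in config.half_life_hours.items()
        }
    for key, k in k_values.items():
        if k < 0:
            raise InvalidConfigError(f"negative decay constant for {key}")
    rng = config.rng("timecourse")
    rows = []
    for (gene, cond), k in sorted(k_values.items()):
        for rep in range(1, config.tc_replicates + 1):
            for tp in config.timepoints:
                eps = np.clip(rng.normal(0.0, config.tc_noise), -0.9, None)
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "time": float(tp),
                        "abundance": math.exp(-k * tp) * (1.0 + eps),
                    }
                )
    truth = pd.DataFrame(
        [
            {
                "gene": g,
                "condition": c,
                "k": k,
                "t_half": math.log(2.0) / k if k > 0 else math.inf,
            }
            for (g, c), k in sorted(k_values.items())
        ]
    )
    logger.info("gen_timecourse seed=%s", config.seed)
    return TimeCourseSim(pd.DataFrame(rows), truth)


# ---------------------------------------------------------------------------
# cohort with planted correlations
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    cohort: CountMatrix
    latent: pd.DataFrame  # genes x samples latent log2 expression
    truth: dict


def gen_cohort(
    config: SimulationConfig,
    genes: Sequence[str] | None = None,
    correlations: Mapping[tuple[str, str], float] | None = None,
    n_background: int = 200,
    base_log2: float = 6.0,
    latent_sd: float = 1.0,
) -> CohortSim:
    """RNA-seq cohort counts with a requested latent correlation structure.

    Latent per-sample log2 means are multivariate normal with unit diagonal
    and the requested pairwise correlations; NB counts are drawn around
    ``2**(base_log2 + latent_sd * z)``.  A non positive-semi-definite
    request raises :class:`InvalidConfigError`.
    """
    if genes is None:
        genes = ["IDX", "PARTNER"]
    genes = list(genes)
    correlations = dict(correlations or {})
    gidx = {g: i for i, g in enumerate(genes)}
    corr = np.eye(len(genes))
    for (a, b), r in correlations.items():
        if a not in gidx or b not in gidx:
            raise InvalidConfigError(f"correlation names unknown gene: {(a, b)}")
        if not -1 <= r <= 1:
            raise InvalidConfigError(f"correlation {r} outside [-1, 1]")
        corr[gidx[a], gidx[b]] = corr[gidx[b], gidx[a]] = r
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        raise InvalidConfigError(
            f"requested correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g})"
        )

    rng = config.rng("cohort")
    n = config.n_cohort_samples
    # PSD (possibly singular) factor via eigen decomposition
    w, v = np.linalg.eigh(corr)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal(size=(n, len(genes))) @ factor.T

    all_genes = genes + [f"BG{i:04d}" for i in range(1, n_background + 1)]
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    log2_mean = np.empty((len(all_genes), n))
    log2_mean[: len(genes)] = base_log2 + latent_sd * z.T
    bg = rng.normal(base_log2, 1.0, size=len(all_genes) - len(genes))
    log2_mean[len(genes):] = bg[:, None]
    mean_counts = 2.0 ** log2_mean
    counts = pd.DataFrame(
        _counts(rng, mean_counts, config),
        index=pd.Index(all_genes, name="gene"),
        columns=samples,
    )
    latent = pd.DataFrame(log2_mean[: len(genes)], index=genes, columns=samples)
    cohort = CountMatrix(counts)
    logger.info("gen_cohort seed=%s n=%d", config.seed, n)
    return CohortSim(cohort, latent, {"correlations": correlations,
                                      "latent_sd": latent_sd})


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSim:
    table: pd.DataFrame  # index sample; time, event, expression
    truth: dict


def gen_survival(
    config: SimulationConfig,
    n_samples: int = 200,
    effect: str = "linear",
) -> SurvivalSim:
    """Exponential event times with hazard proportional to exp(beta * z).

    Expression is standard normal; censoring is an independent exponential
    clock tuned so the expected censored fraction equals
    ``config.censoring_rate`` under the null.  ``effect="step"`` plants a
    threshold at the expression median instead of the log-linear effect:
    hazard = base * exp(beta * 1[z > 0]).
    """
    if effect not in ("linear", "step"):
        raise InvalidConfigError("effect must be 'linear' or 'step'")
    rng = config.rng("survival")
    z = rng.standard_normal(n_samples)
    dose = (z > 0).astype(float) if effect == "step" else z
    lam = config.base_hazard * np.exp(config.hazard_beta * dose)
    t_event = rng.exponential(1.0 / lam)
    c = config.censoring_rate
    if c > 0:
        rate_c = config.base_hazard * c / (1.0 - c)
        t_cens = rng.exponential(1.0 / rate_c, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    table = pd.DataFrame(
        {"time": time, "event": event, "expression": z},
        index=pd.Index([f"P{i:04d}" for i in range(1, n_samples + 1)],
                       name="sample"),
    )
    return SurvivalSim(
        table,
        {"hazard_beta": config.hazard_beta, "censoring_rate": c},
    )


# ---------------------------------------------------------------------------
# exact Venn membership fixture
# ---------------------------------------------------------------------------

def fixture_venn(
    n_bound: int,
    n_down: int,
    n_destab: int,
    n_triple: int,
    pairwise_overlaps: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Membership table realizing exact set sizes and a triple intersection.

    ``pairwise_overlaps`` gives (|bound & down|, |bound & destab|,
    |down & destab|); when omitted each defaults to the triple count — the
    minimal feasible configuration, placing all surplus elements outside the
    overlaps.  Infeasible requests raise :class:`VennInfeasibleError` naming
    the violated region.  Transcript ids are synthetic and shuffled with
    ``seed``.
    """
    for name, v in (("bound", n_bound), ("down", n_down),
                    ("destab", n_destab), ("triple", n_triple)):
        if v < 0:
            raise VennInfeasibleError(name, v)
    if pairwise_overlaps is None:
        pairwise_overlaps = (n_triple, n_triple, n_triple)
    ab, ac, bc = pairwise_overlaps

    regions = {
        "bound&down": ab - n_triple,
        "bound&destab": ac - n_triple,
        "down&destab": bc - n_triple,
        "bound&down&destab": n_triple,
    }
    regions["bound"] = n_bound - ab - ac + n_triple
    regions["down"] = n_down - ab - bc + n_triple
    regions["destab"] = n_destab - ac - bc + n_triple
    for name, count in regions.items():
        if count < 0:
            raise VennInfeasibleError(name, count)

    total = sum(regions.values())
    ids = [f"T{i:06d}" for i in range(1, total + 1)]
    np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["venn"],))
                          ).shuffle(ids)
    flags = {
        "bound": (True, False, False),
        "down": (False, True, False),
        "destab": (False, False, True),
        "bound&down": (True, True, False),
        "bound&destab": (True, False, True),
        "down&destab": (False, True, True),
        "bound&down&destab": (True, True, True),
    }
    rows = []
    cursor = 0
    for region, count in regions.items():
        b, dn, ds = flags[region]
        for tid in ids[cursor:cursor + count]:
            rows.append(
                {"transcript_id": tid, "bound": b, "steady_down": dn,
                 "destabilized": ds}
            )
        cursor += count
    table = (
        pd.DataFrame(
            rows,
            columns=["transcript_id", "bound", "steady_down", "destabilized"],
        )
        .set_index("transcript_id")
        .sort_index()
    )
    logger.info("fixture_venn seed=%s", seed)
    return table


def venn_sets(membership: pd.DataFrame) -> tuple[set, set, set]:
    """Extract the (bound, down, destabilized) id sets from a membership table."""
    return (
        set(membership.index[membership["bound"]]),
        set(membership.index[membership["steady_down"]]),
        set(membership.index[membership["destabilized"]]),
    )
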