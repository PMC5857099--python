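import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpflow import synthetic
from rbpflow.errors import InvalidInputError
from rbpflow.targets import (
    CountMatrix,
    GeneModel,
    Peak,
    RIPExperiment,
    annotate_peak_region,
    call_bound,
    compute_rpkm,
    compute_stability_measures,
    destabilized_set,
    intersect_targets,
    read_bed_peaks,
    read_gtf_models,
    region_distribution,
    secreted_filter,
    steady_state_down,
    utr_length_assay,
)


def cm(counts, libs=None, lengths=None):
    df = pd.DataFrame(counts).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    libsizes = None if libs is None else pd.Series(libs, index=df.columns)
    lens = None if lengths is None else pd.Series(lengths)
    return CountMatrix(df, libsizes, lens)


class TestRPKM:
    def test_zero_count(self):
        m = cm({"t": [0]}, libs=[1e6], lengths={"t": 500})
        assert compute_rpkm(m).loc["t", "s0"] == 0.0

    def test_unit_case(self):
        m = cm({"t": [10]}, libs=[1e6], lengths={"t": 1000})
        assert compute_rpkm(m).loc["t", "s0"] == pytest.approx(10.0)

    def test_formula_oracle(self, rng):
        counts = rng.integers(0, 1000, size=(20, 4))
        lengths = rng.integers(200, 5000, size=20)
        libs = rng.integers(int(1e5), int(1e7), size=4).astype(float)
        m = CountMatrix(
            pd.DataFrame(counts, index=[f"t{i}" for i in range(20)],
                         columns=[f"s{i}" for i in range(4)]),
            pd.Series(libs, index=[f"s{i}" for i in range(4)]),
            pd.Series(lengths, index=[f"t{i}" for i in range(20)]),
        )
        rpkm = compute_rpkm(m).to_numpy()
        expected = counts / ((lengths[:, None] / 1e3) * (libs[None, :] / 1e6))
        np.testing.assert_allclose(rpkm, expected)

    def test_zero_library_rejected(self):
        with pytest.raises(InvalidInputError):
            cm({"t": [1]}, libs=[0.0], lengths={"t": 100})

    def test_missing_lengths_rejected(self):
        m = cm({"t": [1]}, libs=[100.0])
        with pytest.raises(InvalidInputError):
            compute_rpkm(m)


class TestCallBound:
    def test_equal_cpm_not_bound(self):
        rip = RIPExperiment(
            pd.DataFrame({"ip": [100], "input": [100], "igg": [100]},
                         index=["t"]),
            pd.Series([1e5, 1e5, 1e5], index=["ip", "input", "igg"]),
        )
        res = call_bound(rip)
        assert res.loc["t", "enrichment_input"] == pytest.approx(0.0, abs=1e-6)
        assert not res.loc["t", "bound"]

    def test_expression_floor(self):
        # input CPM 0.1 excluded regardless of IP enrichment
        rip = RIPExperiment(
            pd.DataFrame({"ip": [1000], "input": [1], "igg": [1]}, index=["t"]),
            pd.Series([1e7, 1e7, 1e7], index=["ip", "input", "igg"]),
        )
        assert not call_bound(rip)["bound"].loc["t"]

    def test_planted_recovery_seeded(self):
        cfg = synthetic.SimulationConfig(seed=0)
        sim = synthetic.gen_rip(cfg)
        calls = call_bound(sim.experiment)
        truth = sim.truth["is_bound"]
        tp = int((calls["bound"] & truth).sum())
        fp = int((calls["bound"] & ~truth).sum())
        assert tp == 30  # all planted recovered at this seed
        assert fp <= 2

    def test_missing_igg_falls_back(self, caplog):
        rip = RIPExperiment(
            pd.DataFrame({"ip": [800], "input": [100]}, index=["t"]),
            pd.Series([1e5, 1e5], index=["ip", "input"]),
        )
        with caplog.at_level("WARNING"):
            res = call_bound(rip)
        assert res.loc["t", "bound"]
        assert "IgG" in caplog.text


def plus_model():
    #  exons [0,100) [200,400); CDS [50,300); 3'UTR [300,400)
    return GeneModel("tx+", "chr1", "+", [(0, 100), (200, 400)], (50, 300))


def minus_model():
    #  3'UTR genomically left: [0,50)
    return GeneModel("tx-", "chr2", "-", [(0, 100), (200, 400)], (50, 300))


class TestGeneModel:
    def test_rejects_cds_outside_exons(self):
        with pytest.raises(InvalidInputError):
            GeneModel("t", "chr1", "+", [(0, 100)], (50, 150))

    def test_rejects_overlapping_exons(self):
        with pytest.raises(InvalidInputError):
            GeneModel("t", "chr1", "+", [(0, 100), (50, 150)], (10, 60))


class TestAnnotatePeakRegion:
    def test_three_prime_utr(self):
        peak = Peak("chr1", 340, 360)
        out = annotate_peak_region(peak, [plus_model()])
        assert out.region == "3'UTR"
        assert out.transcript_id == "tx+"
        assert out.distance_to_stop == 350 - 299

    def test_intergenic_without_model(self):
        out = annotate_peak_region(Peak("chrX", 10, 20), [plus_model()])
        assert out.region == "intergenic"
        assert out.distance_to_stop is None

    def test_intron(self):
        out = annotate_peak_region(Peak("chr1", 140, 160), [plus_model()])
        assert out.region == "intron"

    def test_five_prime_utr_and_cds(self):
        assert annotate_peak_region(Peak("chr1", 10, 30), [plus_model()]).region == "5'UTR"
        assert annotate_peak_region(Peak("chr1", 60, 80), [plus_model()]).region == "CDS"

    def test_minus_strand_distance(self):
        # midpoint 50 bp genomically left of the CDS start coordinate is
        # +50 downstream of the stop in transcript orientation
        model = GeneModel("t", "chr1", "-", [(0, 500)], (100, 400))
        out = annotate_peak_region(Peak("chr1", 40, 61), [model])
        assert out.midpoint == 50
        assert out.region == "3'UTR"
        assert out.distance_to_stop == 50

    def test_strand_mirror_invariance(self):
        length = 1000
        plus = GeneModel("p", "chr1", "+", [(100, 300), (400, 700)], (150, 650))
        mirrored_exons = [(length - e, length - s) for s, e in plus.exons]
        minus = GeneModel("m", "chr1", "-", mirrored_exons,
                          (length - 650, length - 150))
        for mid in (120, 160, 350, 500, 660):
            pk_plus = annotate_peak_region(Peak("chr1", mid, mid + 1), [plus])
            mirrored_mid = length - 1 - mid
            pk_minus = annotate_peak_region(
                Peak("chr1", mirrored_mid, mirrored_mid + 1), [minus]
            )
            assert pk_plus.region == pk_minus.region
            assert pk_plus.distance_to_stop == pk_minus.distance_to_stop

    def test_utr_priority_on_overlap(self):
        # 3'UTR of one transcript wins over CDS of an overlapping one
        a = GeneModel("a", "chr1", "+", [(0, 400)], (50, 300))
        b = GeneModel("b", "chr1", "+", [(0, 400)], (10, 390))
        out = annotate_peak_region(Peak("chr1", 340, 360), [b, a])
        assert out.region == "3'UTR"
        assert out.transcript_id == "a"

    def test_malformed_interval(self):
        with pytest.raises(InvalidInputError):
            Peak("chr1", 10, 10)

    def test_gen_rip_peaks_all_three_prime(self):
        cfg = synthetic.SimulationConfig(seed=3)
        sim = synthetic.gen_rip(cfg, n_transcripts=50)
        dist = region_distribution(sim.peaks, sim.models)
        assert dist["3'UTR"] == len(sim.peaks)
        assert dist.drop("3'UTR").sum() == 0


class TestSteadyStateDown:
    def test_identical_matrices_empty(self):
        counts = {"t1": [100, 110, 90], "t2": [50, 55, 45]}
        assert steady_state_down(cm(counts), cm(counts)).selected == frozenset()

    def test_boundary_fold_excluded(self):
        # expected CPM ratio exactly 1.1 must fail the strict inequality
        kd = cm({"t": [1000, 1000]}, libs=[1e6, 1e6])
        ct = cm({"t": [1100, 1100]}, libs=[1e6, 1e6])
        res = steady_state_down(kd, ct, pseudocount=0.0)
        assert res.table.loc["t", "fold_down"] == pytest.approx(1.1)
        assert res.selected == frozenset()

    def test_single_replicate_rejected(self):
        kd = cm({"t": [10]}, libs=[1e6])
        ct = cm({"t": [20, 21]}, libs=[1e6, 1e6])
        with pytest.raises(InvalidInputError, match="fold-change-only"):
            steady_state_down(kd, ct)

    def test_planted_recovery_seeded(self):
        cfg = synthetic.SimulationConfig(
            seed=2, nb_dispersion=0.005, stability_replicates=3
        )
        ids = [f"TX{i:04d}" for i in range(1, 301)]
        down = set(ids[10:40])
        sim = synthetic.gen_stability(
            cfg, destabilized=ids[20:60], steady_down=sorted(down),
            steady_down_fold=2.5, base_mean=1000.0,
        )
        res = steady_state_down(sim.kd_t0, sim.ctrl_t0)
        assert res.selected == frozenset(down)  # pilot-frozen perfect recovery


class TestDestabilized:
    def test_zero_delta_excluded(self):
        meas = pd.DataFrame({"logfc_0h": [0.0], "logfc_9h": [0.0]}, index=["t"])
        assert destabilized_set(meas).selected == frozenset()

    def test_retention_arithmetic(self):
        # kd retention 25% vs ctrl 50% at 9 h: delta = -1 -> included
        meas = pd.DataFrame(
            {"logfc_0h": [0.0], "logfc_9h": [math.log2(0.25 / 0.5)]},
            index=["t"],
        )
        res = destabilized_set(meas)
        assert res.table.loc["t", "stability_delta"] == pytest.approx(-1.0)
        assert res.selected == frozenset({"t"})

    def test_boundary_exact_excluded(self):
        meas = pd.DataFrame(
            {"logfc_0h": [0.0], "logfc_9h": [-math.log2(1.1)]}, index=["t"]
        )
        assert destabilized_set(meas).selected == frozenset()

    def test_missing_timepoint_skipped(self, caplog):
        meas = pd.DataFrame(
            {"logfc_0h": [0.0, np.nan], "logfc_9h": [-2.0, -2.0]},
            index=["a", "b"],
        )
        with caplog.at_level("WARNING"):
            res = destabilized_set(meas)
        assert res.selected == frozenset({"a"})

    def test_threshold_monotone(self, rng):
        meas = pd.DataFrame(
            {"logfc_0h": rng.normal(size=100), "logfc_9h": rng.normal(size=100)},
            index=[f"t{i}" for i in range(100)],
        )
        prev = destabilized_set(meas, min_fold=1.0).selected
        for fold in (1.1, 1.5, 2.0, 4.0):
            cur = destabilized_set(meas, min_fold=fold).selected
            assert cur <= prev
            prev = cur


class TestStabilityMeasures:
    def test_zero_noise_contrast_minus_one(self):
        cfg = synthetic.SimulationConfig(seed=0, count_noise="none")
        sim = synthetic.gen_stability(cfg, n_transcripts=50,
                                      destabilized=["TX0001"], steady_down=[])
        meas = compute_stability_measures(
            sim.kd_t0, sim.kd_t9, sim.ctrl_t0, sim.ctrl_t9, pseudocount=0.0
        )
        # t_half 4.5 h vs 9 h at 9 h: log2(2^-2) - log2(2^-1) = -1
        assert meas.loc["TX0001", "stability_delta"] == pytest.approx(-1.0)
        np.testing.assert_allclose(
            meas.drop("TX0001")["stability_delta"], 0.0, atol=1e-12
        )


class TestIntersectTargets:
    def test_venn_fixture_pct(self):
        membership = synthetic.fixture_venn(1084, 708, 2560, 91)
        bound, down, destab = synthetic.venn_sets(membership)
        _, summary = intersect_targets(bound, down, destab)
        assert summary["n_intersection"] == 91
        assert summary["pct_of_bound"] == 8.39

    def test_disjoint_sets(self):
        _, summary = intersect_targets({"a"}, {"b"}, {"c"})
        assert summary["n_intersection"] == 0
        assert summary["pct_of_bound"] == 0.0

    def test_empty_bound_not_applicable(self):
        _, summary = intersect_targets(set(), {"b"}, {"c"})
        assert summary["pct_of_bound"] is None

    def test_random_sets_match_brute_force(self, rng):
        universe = [f"t{i}" for i in range(200)]
        for _ in range(20):
            b = {t for t in universe if rng.uniform() < 0.3}
            d = {t for t in universe if rng.uniform() < 0.3}
            s = {t for t in universe if rng.uniform() < 0.3}
            table, summary = intersect_targets(b, d, s)
            assert summary["n_intersection"] == len(b & d & s)
            assert set(table.index[table["in_intersection"]]) == b & d & s
            assert set(table.index[table["bound"]]) == b
            if b:
                assert 0 <= summary["pct_of_bound"] <= 100


class TestSecretedFilter:
    SECRETED = [f"SEC{i}" for i in range(1, 8)]

    def test_seven_secreted_ids_from_91(self):
        targets = [f"t{i}" for i in range(84)] + self.SECRETED
        out = secreted_filter(targets, self.SECRETED)
        assert out == self.SECRETED
        assert len(out) == 7

    def test_empty_filter(self):
        assert secreted_filter(["a", "b"], []) == []

    def test_superset_filter(self):
        assert secreted_filter(["a", "b"], ["a", "b", "c"]) == ["a", "b"]


class TestUtrLengthAssay:
    @staticmethod
    def levels(distal_kd_scale=1.0, noise=0.0, rng=None):
        rows = []
        for cond in ("ctrl", "kd"):
            for rep in range(3):
                base = {"cds": 1.0, "d1": 0.8, "d2": 0.5}
                for amp, lvl in base.items():
                    if cond == "kd" and amp != "cds":
                        lvl = lvl * distal_kd_scale
                    if rng is not None:
                        lvl *= 1 + rng.normal(0, noise)
                    rows.append(
                        {"amplicon": amp, "condition": cond,
                         "replicate": rep, "level": lvl}
                    )
        return pd.DataFrame(rows)

    def test_identical_ratios_no_change(self):
        table, verdict = utr_length_assay(self.levels(), "cds")
        assert (table["p_value"] == 1.0).all()
        assert verdict == "no length change"

    def test_halved_distal_flagged(self, rng):
        table, verdict = utr_length_assay(
            self.levels(distal_kd_scale=0.5, noise=0.01, rng=rng), "cds"
        )
        assert verdict == "length change"
        assert table["flagged"].all()

    def test_single_condition_rejected(self):
        lv = self.levels()
        with pytest.raises(InvalidInputError):
            utr_length_assay(lv[lv.condition == "kd"], "cds")

    def test_missing_cds_rejected(self):
        lv = self.levels()
        with pytest.raises(InvalidInputError):
            utr_length_assay(lv, "nope")


class TestEndToEndPlantedTruth:
    def test_triple_intersection_recovers_planted(self):
        # pilot-frozen exact counts at seed 2
        ids = [f"TX{i:04d}" for i in range(1, 301)]
        bound = set(ids[:30])
        down = set(ids[10:40])
        destab = set(ids[20:60])
        cfg = synthetic.SimulationConfig(
            seed=2, nb_dispersion=0.005, stability_replicates=3
        )
        sim = synthetic.gen_stability(
            cfg, destabilized=sorted(destab), steady_down=sorted(down),
            steady_down_fold=2.5, base_mean=1000.0,
        )
        down_res = steady_state_down(sim.kd_t0, sim.ctrl_t0)
        meas = compute_stability_measures(
            sim.kd_t0, sim.kd_t9, sim.ctrl_t0, sim.ctrl_t9
        )
        destab_res = destabilized_set(meas)
        table, summary = intersect_targets(
            bound, down_res.selected, destab_res.selected
        )
        called = set(table.index[table["in_intersection"]])
        assert called == bound & down & destab  # 10 TP, 0 FP at this seed
        assert summary["n_intersection"] == 10


class TestGtfBedRoundTrip:
    def test_models_round_trip(self, tmp_path):
        from rbpflow import io

        cfg = synthetic.SimulationConfig(seed=5)
        sim = synthetic.gen_rip(cfg, n_transcripts=10)
        path = tmp_path / "models.gtf"
        io.write_gtf(sim.models, path)
        back = read_gtf_models(path)
        orig = {m.transcript_id: m for m in sim.models}
        assert len(back) == len(orig)
        for m in back:
            o = orig[m.transcript_id]
            assert list(m.exons) == list(o.exons)
            assert tuple(m.cds) == tuple(o.cds)
            assert m.strand == o.strand

    def test_peaks_round_trip(self, tmp_path):
        from rbpflow import io

        cfg = synthetic.SimulationConfig(seed=5)
        sim = synthetic.gen_rip(cfg, n_transcripts=10)
        path = tmp_path / "peaks.bed"
        io.write_bed6(sim.peaks, path)
        back = read_bed_peaks(path)
        assert [(p.chrom, p.start, p.end) for p in back] == [
            (p.chrom, p.start, p.end) for p in sim.peaks
        ]


@settings(max_examples=30, deadline=None)
@given(
    b=st.sets(st.integers(0, 50)),
    d=st.sets(st.integers(0, 50)),
    s=st.sets(st.integers(0, 50)),
)
def test_intersection_property(b, d, s):
    ids = lambda xs: {f"t{x}" for x in xs}
    table, summary = intersect_targets(ids(b), ids(d), ids(s))
    assert summary["n_intersection"] == len(ids(b) & ids(d) & ids(s))
    if summary["pct_of_bound"] is not None:
        assert 0 <= summary["pct_of_bound"] <= 100
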