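"""Triplet eligibility, PWM scanning, and predictive-feature tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtlmed.synthetic import generate_motif_instances
from qtlmed.triplets import (
    PWM,
    annotate_and_compare,
    build_forward_triplets,
    build_reactive_triplets,
    build_trans_triplets,
    scan_pwm,
    validate_triplets,
)


@pytest.fixture
def simple_pwm():
    m = np.ones((4, 4))
    m[0, 0] = m[1, 1] = m[2, 2] = m[3, 3] = 9.0  # consensus ACGT
    return PWM(m, name="TFX")


def brute_force_scan(sequence, pwm, threshold):
    """Exhaustive per-offset scoring, coded independently."""
    lo = pwm.log_odds()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    lo_min, lo_max = lo.min(axis=0).sum(), lo.max(axis=0).sum()
    hits = []
    for off in range(len(sequence) - pwm.width + 1):
        score = sum(lo[idx[b], i] for i, b in enumerate(
            sequence[off : off + pwm.width]))
        rel = (score - lo_min) / (lo_max - lo_min)
        if rel >= threshold:
            hits.append((off, rel))
    return hits


class TestScanPwm:
    def test_consensus_scores_one(self, simple_pwm):
        hits = scan_pwm("ACGT", simple_pwm, both_strands=False)
        assert len(hits) == 1
        assert hits["relative_score"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_oracle(self, simple_pwm, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=10))
            got = scan_pwm(seq, simple_pwm, min_relative_score=0.5,
                           both_strands=False)
            expect = brute_force_scan(seq, simple_pwm, 0.5)
            assert len(got) == len(expect)
            for (_, row), (off, rel) in zip(got.iterrows(), expect):
                assert row["offset"] == off
                assert row["relative_score"] == pytest.approx(rel)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=30))
    def test_forward_hits_match_oracle_property(self, seq):
        pwm = PWM(np.array([[9, 1, 1, 1], [1, 9, 1, 1],
                            [1, 1, 9, 1], [1, 1, 1, 9.0]]).T.reshape(4, 4))
        got = scan_pwm(seq, pwm, min_relative_score=0.6, both_strands=False)
        expect = brute_force_scan(seq, pwm, 0.6)
        assert [int(o) for o in got["offset"]] == [o for o, _ in expect]

    def test_reverse_strand_found(self, simple_pwm):
        # reverse complement of ACGT is ACGT; use an asymmetric motif
        m = np.ones((4, 3))
        m[0, 0] = m[0, 1] = m[2, 2] = 9.0  # consensus AAG -> revcomp CTT
        pwm = PWM(m)
        hits = scan_pwm("GCTTG", pwm, min_relative_score=0.99)
        assert (hits["strand"] == "-").any()

    def test_default_threshold_is_80_percent(self, simple_pwm):
        import inspect

        sig = inspect.signature(scan_pwm)
        assert sig.parameters["min_relative_score"].default == 0.8

    def test_planted_motifs_all_recovered(self):
        peaks = pd.DataFrame({"peak_id": [f"p{i}" for i in range(6)],
                              "chrom": "chr1",
                              "start": np.arange(6) * 100,
                              "end": np.arange(6) * 100 + 40})
        m = np.ones((4, 8))
        m[1] = 12.0  # consensus CCCCCCCC, rare by chance in 40 bp
        seqs, truth = generate_motif_instances(m, peaks, 1.0, seed=5)
        pwm = PWM(m)
        for _, row in truth.iterrows():
            hits = scan_pwm(seqs[row["peak_id"]], pwm, both_strands=False)
            assert int(row["offset"]) in set(hits["offset"])


class TestBuildForwardTriplets:
    @pytest.fixture
    def layout_tables(self):
        variant_meta = pd.DataFrame({
            "variant_id": ["v_in", "v_out", "v_edge"],
            "chrom": ["chr1"] * 3,
            "pos": [150, 99, 100],  # peak is [100, 200)
        })
        peaks = pd.DataFrame({"peak_id": ["pk"], "chrom": ["chr1"],
                              "start": [100], "end": [200]})
        genes = pd.DataFrame({"gene_id": ["g_near", "g_far"],
                              "chrom": ["chr1", "chr1"],
                              "tss": [50_000, 2_000_000]})
        return variant_meta, peaks, genes

    def test_variant_must_be_inside_peak(self, layout_tables):
        vmeta, peaks, genes = layout_tables
        caqtl = pd.DataFrame({"variant_id": ["v_in", "v_out"],
                              "feature_id": ["pk", "pk"], "beta": [1.0, 1.0]})
        eqtl = pd.DataFrame({"variant_id": ["v_in", "v_out"],
                             "feature_id": ["g_near", "g_near"],
                             "beta": [0.5, 0.5]})
        trips = build_forward_triplets(caqtl, eqtl, vmeta, peaks, genes)
        ids = {t.x_variant_id for t in trips}
        assert ids == {"v_in"}  # 1 bp upstream of the peak is not inside

    def test_half_open_boundary_start_inside(self, layout_tables):
        vmeta, peaks, genes = layout_tables
        caqtl = pd.DataFrame({"variant_id": ["v_edge"], "feature_id": ["pk"],
                              "beta": [1.0]})
        eqtl = pd.DataFrame({"variant_id": ["v_edge"], "feature_id": ["g_near"],
                             "beta": [-0.5]})
        trips = build_forward_triplets(caqtl, eqtl, vmeta, peaks, genes)
        assert len(trips) == 1
        assert trips[0].direction_shared is False

    def test_distant_gene_excluded(self, layout_tables):
        vmeta, peaks, genes = layout_tables
        caqtl = pd.DataFrame({"variant_id": ["v_in"], "feature_id": ["pk"],
                              "beta": [1.0]})
        eqtl = pd.DataFrame({"variant_id": ["v_in"], "feature_id": ["g_far"],
                             "beta": [1.0]})
        trips = build_forward_triplets(caqtl, eqtl, vmeta, peaks, genes)
        assert trips == []

    def test_fixture_counts_match_brute_force(self, layout_tables):
        vmeta, peaks, genes = layout_tables
        caqtl = pd.DataFrame({
            "variant_id": ["v_in", "v_in", "v_out", "v_edge", "v_edge"],
            "feature_id": ["pk"] * 5,
            "beta": [1.0, 1.0, 1.0, 1.0, 1.0],
        }).drop_duplicates()
        eqtl = pd.DataFrame({
            "variant_id": ["v_in", "v_out", "v_edge"],
            "feature_id": ["g_near", "g_near", "g_far"],
            "beta": [1.0, 1.0, 1.0],
        })
        trips = build_forward_triplets(caqtl, eqtl, vmeta, peaks, genes)
        # qualifying: v_in->g_near only (v_out outside peak, v_edge gene too far)
        assert len(trips) == 1
        validate_triplets(trips, vmeta, peaks, genes)


class TestBuildReactiveTriplets:
    def test_variant_inside_target_peak_excluded(self, simple_pwm):
        vmeta = pd.DataFrame({"variant_id": ["v"], "chrom": ["chr1"], "pos": [150]})
        peaks = pd.DataFrame({"peak_id": ["pk"], "chrom": ["chr1"],
                              "start": [100], "end": [200]})
        tf_egenes = pd.DataFrame({"variant_id": ["v"], "feature_id": ["TFX"],
                                  "beta": [1.0]})
        trans_ca = pd.DataFrame({"variant_id": ["v"], "feature_id": ["pk"],
                                 "beta": [1.0]})
        trips = build_reactive_triplets(tf_egenes, {"TFX": simple_pwm},
                                        {"pk": "ACGTACGT"}, trans_ca, vmeta, peaks)
        assert trips == []

    def test_peak_without_motif_skipped(self, simple_pwm):
        vmeta = pd.DataFrame({"variant_id": ["v"], "chrom": ["chr2"], "pos": [150]})
        peaks = pd.DataFrame({"peak_id": ["pk"], "chrom": ["chr1"],
                              "start": [100], "end": [200]})
        tf_egenes = pd.DataFrame({"variant_id": ["v"], "feature_id": ["TFX"],
                                  "beta": [1.0]})
        trans_ca = pd.DataFrame({"variant_id": ["v"], "feature_id": ["pk"],
                                 "beta": [1.0]})
        trips = build_reactive_triplets(tf_egenes, {"TFX": simple_pwm},
                                        {"pk": "TTTTTTTT"}, trans_ca, vmeta, peaks)
        assert trips == []

    def test_planted_architecture_recovered(self, simple_pwm):
        vmeta = pd.DataFrame({"variant_id": ["v"], "chrom": ["chr2"], "pos": [150]})
        peaks = pd.DataFrame({"peak_id": ["pk"], "chrom": ["chr1"],
                              "start": [100], "end": [200]})
        tf_egenes = pd.DataFrame({"variant_id": ["v"], "feature_id": ["TFX"],
                                  "beta": [1.0]})
        trans_ca = pd.DataFrame({"variant_id": ["v"], "feature_id": ["pk"],
                                 "beta": [-2.0]})
        trips = build_reactive_triplets(tf_egenes, {"TFX": simple_pwm},
                                        {"pk": "GGACGTGG"}, trans_ca, vmeta, peaks)
        assert len(trips) == 1
        assert trips[0].eligibility == "reactive"
        validate_triplets(trips, vmeta, peaks, pd.DataFrame(
            {"gene_id": ["TFX"], "chrom": ["chr2"], "tss": [0]}))


class TestBuildTransTriplets:
    def test_self_pair_rejected(self):
        cis = pd.DataFrame({"variant_id": ["v"], "feature_id": ["gA"],
                            "beta": [1.0]})
        trans = pd.DataFrame({"variant_id": ["v"], "feature_id": ["gA"],
                              "beta": [1.0]})
        assert build_trans_triplets(cis, trans) == []

    def test_symmetric_crossmap_mean_filters(self):
        cis = pd.DataFrame({"variant_id": ["v"], "feature_id": ["gA"],
                            "beta": [1.0]})
        trans = pd.DataFrame({"variant_id": ["v"], "feature_id": ["gB"],
                              "beta": [1.0]})
        # (crossmap(A,B) + crossmap(B,A)) / 2 = (8 + 4) / 2 = 6 > 5 -> dropped
        cm = pd.DataFrame({"gene_a": ["gA", "gB"], "gene_b": ["gB", "gA"],
                           "log2_crossmap": [8.0, 4.0]})
        assert build_trans_triplets(cis, trans, cm) == []
        # (4 + 4) / 2 = 4 <= 5 -> retained
        cm2 = pd.DataFrame({"gene_a": ["gA", "gB"], "gene_b": ["gB", "gA"],
                            "log2_crossmap": [4.0, 4.0]})
        assert len(build_trans_triplets(cis, trans, cm2)) == 1

    def test_planted_architectures_counted(self):
        cis = pd.DataFrame({"variant_id": ["v1", "v2"],
                            "feature_id": ["gA", "gC"], "beta": [1.0, 1.0]})
        trans = pd.DataFrame({"variant_id": ["v1", "v2"],
                              "feature_id": ["gB", "gD"], "beta": [1.0, -1.0]})
        trips = build_trans_triplets(cis, trans)
        assert len(trips) == 2
        assert {t.y_feature_id for t in trips} == {"gB", "gD"}


class TestAnnotateAndCompare:
    def test_null_features_rarely_rejected(self, rng):
        rejections = 0
        for seed in range(50):
            local = np.random.default_rng(seed)
            table = pd.DataFrame({
                "classification": ["forward"] * 20 + ["independence"] * 20,
                "r2_ym": local.uniform(size=40),
                "tss_distance": local.integers(0, 10_000, size=40),
                "in_promoter": local.random(40) < 0.3,
            })
            res = annotate_and_compare(table)
            if (res[res["test"] == "t"]["p"] < 0.05).any():
                rejections += 1
        assert rejections <= 10  # no rejection in >= 80% of null seeds

    def test_perfect_separation_chi_square(self):
        table = pd.DataFrame({
            "classification": ["forward"] * 10 + ["independence"] * 10,
            "in_promoter": [True] * 10 + [False] * 10,
        })
        res = annotate_and_compare(table)
        p = res[res["feature"] == "in_promoter"]["p"].iloc[0]
        assert p < 0.01

    def test_small_class_skipped(self):
        table = pd.DataFrame({
            "classification": ["forward", "independence", "independence"],
            "r2_ym": [0.5, 0.4, 0.3],
        })
        assert annotate_and_compare(table).empty
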