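"""Anchor-peak-gene linkage, enrichment and permutation tests."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from chromalink.expression import DEtable
from chromalink.integration import (
    IntegrationRecord,
    accessible_anchors,
    assign_genes,
    build_report,
    de_enrichment,
    integration_records,
    silencer_loss_test,
    truncate_sig,
    write_report,
)
from chromalink.intervals import (
    Gene,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    overlap_pairs,
)
from chromalink.stats import DIAGNOSIS, RELAPSE


def make_de(log_fc_by_gene, up=(), down=()):
    genes = sorted(log_fc_by_gene)
    return DEtable(
        results=pd.DataFrame(
            {"feature_id": genes, "log_fc": [log_fc_by_gene[g] for g in genes]}
        ),
        upregulated=list(up),
        downregulated=list(down),
        universe=genes,
        alpha=0.1,
        lfc=1.0,
    )


class TestAccessibleAnchors:
    def test_anchor_containing_peak_kept(self):
        anchors = [GenomicInterval("chr1", 0, 5000)]
        peaks = PeakSet("p", [GenomicInterval("chr1", 100, 300, "pk1")])
        (acc,) = accessible_anchors(anchors, peaks)
        assert acc.peak_ids == ("pk1",)

    def test_no_overlap_empty(self):
        anchors = [GenomicInterval("chr1", 0, 5000)]
        peaks = PeakSet("p", [GenomicInterval("chr1", 9000, 9300)])
        assert accessible_anchors(anchors, peaks) == []

    def test_matches_overlap_pairs_brute_force(self, rng):
        anchors = [
            GenomicInterval("chr1", int(s), int(s) + 5000)
            for s in rng.integers(0, 500_000, size=100)
        ]
        peaks = PeakSet(
            "p",
            [
                GenomicInterval("chr1", int(s), int(s) + 400, f"p{i}")
                for i, s in enumerate(rng.integers(0, 500_000, size=150))
            ],
        )
        acc = accessible_anchors(anchors, peaks)
        expected = {i for i, _ in overlap_pairs(anchors, peaks.intervals)}
        assert {a.anchor.key() for a in acc} == {
            anchors[i].key() for i in expected
        }


class TestAssignGenes:
    ann = GeneAnnotation(
        [Gene("g1", "G1", GenomicInterval("chr1", 10_000, 20_000), "+")]
    )

    def test_linked_within_window(self):
        links = assign_genes(
            [GenomicInterval("chr1", 35_000, 36_000)], self.ann, window=20_000
        )
        assert links == [("g1", 0)]

    def test_not_linked_beyond_window(self):
        links = assign_genes(
            [GenomicInterval("chr1", 45_001, 46_000)], self.ann, window=20_000
        )
        assert links == []

    def test_links_deduplicated(self):
        region = GenomicInterval("chr1", 12_000, 13_000)
        links = assign_genes([region, region], self.ann)
        assert links == [("g1", 0), ("g1", 1)]


class TestDeEnrichment:
    def test_all_ties_give_p_one(self):
        de = make_de({f"g{i}": 1.0 for i in range(40)})
        res = de_enrichment([f"g{i}" for i in range(5)], de, de.universe, seed=1)
        assert res.p_empirical == 1.0

    def test_forced_ordering_gives_minimum_p(self):
        lfc = {f"g{i}": 0.0 for i in range(200)}
        linked = [f"g{i}" for i in range(10)]
        for g in linked:
            lfc[g] = 2.0
        de = make_de(lfc)
        res = de_enrichment(linked, de, de.universe, n_random=10, seed=11)
        assert res.p_empirical == pytest.approx(1 / 11)
        assert res.observed_stat == 2.0
        assert np.all(res.null_stats < 2.0)

    def test_small_pool_rejected(self):
        de = make_de({"a": 1.0, "b": 2.0, "c": 0.0})
        with pytest.raises(ValueError, match="smaller than"):
            de_enrichment(["a", "b"], de, ["a", "b", "c"])

    def test_add_one_bounds(self):
        de = make_de({f"g{i}": float(i) for i in range(50)})
        res = de_enrichment(["g49"], de, de.universe, n_random=10, seed=2)
        assert 1 / 11 <= res.p_empirical <= 1.0


def record(gene, chrom, d_start, d_width, state=DIAGNOSIS, lid="L1"):
    return IntegrationRecord(
        gene_id=gene,
        state=state,
        loop_id=lid,
        promoter_anchor=GenomicInterval(chrom, 0, 5000),
        distal_anchor=GenomicInterval(chrom, d_start, d_start + d_width),
        peak_ids=("pk",),
        log_fc=2.0,
    )


class TestSilencerLossTest:
    sizes = {"chr1": 1_000_000}

    def test_zero_observed_gives_p_one(self):
        cands = [record("g1", "chr1", 500_000, 5000)]
        marks = PeakSet("m", [GenomicInterval("chr1", 0, 2000)])
        res = silencer_loss_test(cands, marks, self.sizes, n_perm=200, seed=1)
        assert res.observed_prop == 0.0
        assert res.p_value == 1.0

    def test_saturated_marks_give_p_one(self):
        cands = [record("g1", "chr1", 500_000, 5000)]
        marks = PeakSet("m", [GenomicInterval("chr1", 0, 1_000_000)])
        res = silencer_loss_test(cands, marks, self.sizes, n_perm=200, seed=1)
        assert res.observed_prop == 1.0
        assert res.p_value == 1.0

    def test_forced_extreme_reaches_add_one_floor(self):
        # sparse marks sitting exactly on every candidate distal anchor
        cands = [
            record(f"g{i}", "chr1", 100_000 + 50_000 * i, 5000, lid=f"L{i}")
            for i in range(12)
        ]
        marks = PeakSet(
            "m",
            [GenomicInterval("chr1", c.distal_anchor.start, c.distal_anchor.end)
             for c in cands],
        )
        res = silencer_loss_test(cands, marks, self.sizes, n_perm=10_000, seed=3)
        assert res.observed_prop == 1.0
        assert res.k_exceed == 0
        assert res.p_value == pytest.approx(1 / 10_001)

    def test_anchor_wider_than_chromosome_rejected(self):
        cands = [record("g1", "chr1", 100, 5000)]
        marks = PeakSet("m", [GenomicInterval("chr1", 0, 2000)])
        with pytest.raises(ValueError, match="shorter than"):
            silencer_loss_test(cands, marks, {"chr1": 3000}, n_perm=10, seed=1)

    def test_empty_candidates_rejected(self):
        marks = PeakSet("m", [GenomicInterval("chr1", 0, 2000)])
        with pytest.raises(ValueError, match="empty"):
            silencer_loss_test([], marks, self.sizes)


class TestTruncateSig:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (1 / 10_001, 9.99e-5),
            (0.123456, 0.123),
            (0.9999, 0.999),
            (0.0, 0.0),
        ],
    )
    def test_truncation(self, x, expected):
        assert truncate_sig(x, 3) == pytest.approx(expected, rel=1e-12)


class TestIntegrationChain:
    def _fixture(self):
        # gene near anchor A of loop L1; anchor A carries a peak; B is distal
        genes = [
            Gene("g1", "G1", GenomicInterval("chr1", 6_000, 8_000), "+"),
            Gene("g2", "G2", GenomicInterval("chr1", 500_000, 502_000), "+"),
        ]
        ann = GeneAnnotation(genes)
        a = GenomicInterval("chr1", 0, 5_000)
        b = GenomicInterval("chr1", 200_000, 205_000)
        loops = {"L1": (a, b)}
        peaks = PeakSet("d", [GenomicInterval("chr1", 100, 600, "pk1")])
        de = make_de({"g1": 2.5, "g2": 0.1}, up=["g1"])
        return ann, loops, peaks, de

    def test_chain_links_expected_gene(self):
        ann, loops, peaks, de = self._fixture()
        recs = integration_records(loops, ["L1"], peaks, ann, de, DIAGNOSIS)
        assert [r.gene_id for r in recs] == ["g1"]
        r = recs[0]
        assert r.promoter_anchor.start == 0 and r.distal_anchor.start == 200_000
        assert r.peak_ids == ("pk1",)
        assert r.log_fc == 2.5

    def test_repressive_flag_set_from_marks(self):
        ann, loops, peaks, de = self._fixture()
        marks = PeakSet("m", [GenomicInterval("chr1", 201_000, 202_000)])
        recs = integration_records(
            loops, ["L1"], peaks, ann, de, DIAGNOSIS, marks=marks
        )
        assert recs[0].repressive_overlap

    def test_matches_brute_force_chain(self, small_dataset):
        """Linked gene sets equal an independent recomputation of
        anchor -> peak overlap -> gene window on the simulated data."""
        from chromalink.loops import build_loop_matrix, call_differential_loops
        from chromalink.peaks import derive_states
        from chromalink.expression import differential_expression

        ds = small_dataset
        lm = build_loop_matrix(ds.loop_records, ds.groups)
        dl = call_differential_loops(lm)
        sp = derive_states(*[ds.peak_sets[s] for s in ("D1", "D2", "R1", "R2")])
        de = differential_expression(ds.counts)
        recs = integration_records(
            dl.anchors,
            dl.diagnosis_specific,
            sp.diagnosis_specific,
            ds.annotation,
            de,
            DIAGNOSIS,
        )
        # brute force: every (gene, anchor) with peak overlap and window hit
        window = 20_000
        expect = set()
        for lid in dl.diagnosis_specific:
            for anchor in dl.anchors[lid]:
                has_peak = any(
                    anchor.overlap_width(p) > 0
                    for p in sp.diagnosis_specific.intervals
                )
                if not has_peak:
                    continue
                for g in ds.annotation:
                    gap = GenomicInterval(
                        anchor.chrom,
                        max(0, anchor.start - window),
                        anchor.end + window,
                    )
                    if gap.overlap_width(g.body) > 0:
                        expect.add(g.gene_id)
        assert {r.gene_id for r in recs} == expect


class TestBuildReport:
    def test_missing_stage_named(self):
        with pytest.raises(ValueError, match="diff_loops"):
            build_report()

    def test_empty_inputs_valid_schema(self):
        de = make_de({"g1": 0.0})
        report = build_report(
            de=de,
            records_by_state={DIAGNOSIS: [], RELAPSE: []},
            allow_missing=True,
        )
        assert report["tri_omic_genes"] == []
        assert report["integration"][DIAGNOSIS]["n_records"] == 0

    def test_report_bytes_stable(self, tmp_path):
        de = make_de({"g1": 1.0, "g2": -1.0}, up=["g1"])
        recs = {DIAGNOSIS: [record("g1", "chr1", 100_000, 5000)], RELAPSE: []}
        paths = []
        for sub in ("a", "b"):
            rep = build_report(
                de=de, records_by_state=recs, allow_missing=True,
                parameters={"seed": 1},
            )
            paths.append(write_report(rep, tmp_path / sub))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_tri_omic_requires_de_significance(self):
        de = make_de({"g1": 1.0, "g2": 3.0}, up=["g2"])
        recs = {
            DIAGNOSIS: [record("g1", "chr1", 100_000, 5000)],
            RELAPSE: [record("g2", "chr1", 300_000, 5000, state=RELAPSE)],
        }
        rep = build_report(de=de, records_by_state=recs, allow_missing=True)
        assert rep["tri_omic_genes"] == ["g2"]


def test_permutation_p_values_respect_add_one_bounds(rng):
    sizes = {"chr1": 500_000}
    for _ in range(5):
        cands = [
            record(f"g{i}", "chr1", int(s), 2_000, lid=f"L{i}")
            for i, s in enumerate(rng.integers(0, 400_000, size=8))
        ]
        marks = PeakSet(
            "m",
            [
                GenomicInterval("chr1", int(s), int(s) + 1_500)
                for s in rng.integers(0, 480_000, size=30)
            ],
        )
        res = silencer_loss_test(cands, marks, sizes, n_perm=99, seed=int(rng.integers(2**31)))
        assert 1 / 100 <= res.p_value <= 1.0
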