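"""GWAS-hit pruning, gene annotation filters and shortlist prioritization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from audiogene.candidates import (
    GwasHit,
    annotate_and_filter,
    prioritize,
    prune_regions,
    run_candidate_filter,
    CandidateGene,
)
from audiogene.genio import GeneInterval, InputError


def _hit(snp, pos, p, chrom="1"):
    return GwasHit(snp_id=snp, chrom=chrom, pos=pos, p_value=p)


class TestPruneRegions:
    def test_close_pair_keeps_most_significant(self):
        hits = [_hit("a", 1_000_000, 1e-5), _hit("b", 1_100_000, 1e-6)]
        assert [h.snp_id for h in prune_regions(hits)] == ["b"]

    def test_distant_pair_both_survive(self):
        hits = [_hit("a", 1_000_000, 1e-5), _hit("b", 1_600_000, 1e-6)]
        assert {h.snp_id for h in prune_regions(hits)} == {"a", "b"}

    def test_chromosomes_independent(self):
        hits = [_hit("a", 100, 1e-6), _hit("b", 200, 1e-5, chrom="2")]
        assert len(prune_regions(hits)) == 2

    def test_no_two_survivors_within_window(self):
        rng = np.random.default_rng(0)
        hits = [
            _hit(f"s{i}", int(rng.integers(1, 5_000_000)), float(rng.uniform(1e-8, 1e-5)))
            for i in range(60)
        ]
        out = prune_regions(hits, window=250_000)
        pos = sorted(h.pos for h in out)
        assert all(b - a > 250_000 for a, b in zip(pos, pos[1:]))

    def test_greedy_matches_brute_force_on_cluster_fixture(self):
        # 30 hits in 3 clusters; exhaustive application of the greedy rule
        rng = np.random.default_rng(1)
        hits = []
        for c, center in enumerate((1_000_000, 2_000_000, 3_000_000)):
            for i in range(10):
                hits.append(
                    _hit(f"c{c}_{i}", center + int(rng.integers(-100_000, 100_000)),
                         float(rng.uniform(1e-9, 1e-5)))
                )
        out = prune_regions(hits)

        def brute(hs):
            rem = sorted(hs, key=lambda h: (h.p_value, h.chrom, h.pos, h.snp_id))
            surv = []
            while rem:
                b = rem[0]
                surv.append(b)
                rem = [x for x in rem[1:] if abs(x.pos - b.pos) > 250_000 or x.chrom != b.chrom]
            return sorted(s.snp_id for s in surv)

        assert sorted(h.snp_id for h in out) == brute(hits)
        assert len(out) == 3  # one survivor per cluster

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_input_order_invariance(self, r):
        rng = np.random.default_rng(2)
        hits = [
            _hit(f"s{i}", int(rng.integers(1, 3_000_000)), float(rng.uniform(1e-9, 1e-4)))
            for i in range(25)
        ]
        shuffled = hits.copy()
        r.shuffle(shuffled)
        assert [h.snp_id for h in prune_regions(hits)] == [
            h.snp_id for h in prune_regions(shuffled)
        ]


class TestAnnotateAndFilter:
    def test_gene_desert_dropped(self):
        genes = [GeneInterval("G1", "1", 1_300_001, 1_400_000)]
        out = annotate_and_filter([_hit("a", 1_000_000, 1e-6)], genes)
        assert out == []

    def test_gene_within_window_kept_with_distance(self):
        genes = [GeneInterval("G1", "1", 1_200_001, 1_300_000)]
        (cand,) = annotate_and_filter([_hit("a", 1_000_000, 1e-6)], genes)
        assert cand.gene_id == "G1"
        assert cand.distance == 200_001

    def test_intragenic_distance_zero(self):
        genes = [GeneInterval("G1", "1", 900_000, 1_100_000)]
        (cand,) = annotate_and_filter([_hit("a", 1_000_000, 1e-6)], genes)
        assert cand.distance == 0 and cand.intragenic

    def test_loc_and_fam_names_excluded(self):
        genes = [
            GeneInterval("LOC102724", "1", 990_000, 995_000),
            GeneInterval("FAM13A", "1", 970_000, 975_000),
            GeneInterval("REALGENE", "1", 1_050_000, 1_060_000),
        ]
        (cand,) = annotate_and_filter([_hit("a", 1_000_000, 1e-6)], genes)
        assert cand.gene_id == "REALGENE"

    def test_disease_exclusion_list(self):
        genes = [GeneInterval("BADGENE", "1", 990_000, 995_000)]
        out = annotate_and_filter(
            [_hit("a", 1_000_000, 1e-6)], genes,
            disease_exclusion_list=("BADGENE",),
        )
        assert out == []

    def test_multi_gene_mode_anchors_several_genes_to_one_snp(self):
        """One SNP anchoring three genes at ~39/92/100 kb."""
        hit = _hit("rs-like", 1_000_000, 1e-6, chrom="17")
        genes = [
            GeneInterval("GENE_A", "17", 1_039_000 + 1, 1_060_000),
            GeneInterval("GENE_B", "17", 1_092_000 + 1, 1_120_000),
            GeneInterval("GENE_C", "17", 1_100_000 + 1, 1_130_000),
        ]
        out = annotate_and_filter([hit], genes, multi_gene=True)
        assert [c.gene_id for c in out] == ["GENE_A", "GENE_B", "GENE_C"]
        assert [c.distance for c in out] == [39_001, 92_001, 100_001]
        assert len({c.snp_id for c in out}) == 1
        # single-gene mode keeps only the closest
        (closest,) = annotate_and_filter([hit], genes, multi_gene=False)
        assert closest.gene_id == "GENE_A"

    def test_empty_annotation_rejected(self):
        with pytest.raises(InputError):
            annotate_and_filter([_hit("a", 1, 1e-6)], [])


class TestPrioritize:
    def _cands(self):
        return [CandidateGene("G1", "s1", 0), CandidateGene("G2", "s1", 10_000)]

    def test_antibody_is_mandatory_gate(self):
        crit = pd.DataFrame(
            {
                "gene_id": ["G1"], "antibody_available": [False],
                "hhl_family_similarity": [True], "highly_suggestive_p": [True],
                "ear_expression_db": [True], "pathway_link": [True],
                "suggestive_p": [True],
            }
        )
        (c1, _) = prioritize(self._cands(), crit)
        assert not c1.shortlisted

    def test_antibody_plus_one_criterion_shortlists(self):
        crit = pd.DataFrame(
            {"gene_id": ["G1"], "antibody_available": [True],
             "hhl_family_similarity": [True]}
        )
        (c1, c2) = prioritize(self._cands(), crit)
        assert c1.shortlisted
        assert not c2.shortlisted  # absent from table -> all flags False

    def test_antibody_alone_insufficient(self):
        crit = pd.DataFrame({"gene_id": ["G1"], "antibody_available": [True]})
        (c1, _) = prioritize(self._cands(), crit)
        assert not c1.shortlisted


class TestFullFunnel:
    def _fixture(self):
        rng = np.random.default_rng(3)
        hits = []
        for c, center in enumerate((1_000_000, 2_500_000, 6_000_000)):
            for i in range(10):
                hits.append(
                    _hit(f"c{c}_{i}", center + int(rng.integers(-120_000, 120_000)),
                         float(rng.uniform(1e-9, 1e-5)))
                )
        genes = [
            GeneInterval("GOODGENE", "1", 1_050_000, 1_080_000),
            GeneInterval("LOC999", "1", 2_400_000, 2_600_000),
            # nothing near 6 Mb: third cluster is a gene desert
        ]
        crit = pd.DataFrame(
            {"gene_id": ["GOODGENE"], "antibody_available": [True],
             "ear_expression_db": [True]}
        )
        return hits, genes, crit

    def test_funnel_counts_and_idempotence(self):
        hits, genes, crit = self._fixture()
        table = run_candidate_filter(hits, genes, crit)
        # 3 pruning survivors -> 1 desert, 1 LOC-only, 1 real gene
        assert len(table) == 1
        assert table.iloc[0]["gene"] == "GOODGENE"
        assert bool(table.iloc[0]["shortlisted"])
        again = run_candidate_filter(hits, genes, crit)
        pd.testing.assert_frame_equal(table, again)

    def test_shuffle_invariance(self):
        hits, genes, crit = self._fixture()
        base = run_candidate_filter(hits, genes, crit)
        rng = np.random.default_rng(4)
        for _ in range(10):
            shuffled = list(hits)
            rng.shuffle(shuffled)
            pd.testing.assert_frame_equal(run_candidate_filter(shuffled, genes, crit), base)
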