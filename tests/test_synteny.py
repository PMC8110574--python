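import numpy as np
import pytest

from syntevo.genome import HomologyHit
from syntevo.synteny import (
    AnchorPair,
    Orthogroup,
    SyntenyBlock,
    SyntenyParams,
    chain_collinear_blocks,
    classify_syntenic_homologs,
    complete_orthogroups,
    cull_hits,
    extend_blocks,
    gene_to_genome,
    hits_within_orthogroups,
    infer_pairwise_orthogroups,
    prune_blocks_density,
    summarize_synteny,
    summary_from_counts,
)

from conftest import make_annotation


def anchors(pairs, score=100.0):
    return [AnchorPair(f"a{ra}", f"b{rb}", ra, rb, score) for ra, rb in pairs]


# ---------------------------------------------------------------------------
# Hit culling
# ---------------------------------------------------------------------------

class TestCullHits:
    @pytest.fixture
    def two_genomes(self):
        a = make_annotation("A", {"c1": 20})
        b = make_annotation("B", {"c1": 20})
        return {"A": a, "B": b}

    def test_top_two_per_target_genome(self, two_genomes):
        hits = [
            HomologyHit("A_c1_0000", f"B_c1_{i:04d}", s)
            for i, s in enumerate([300, 250, 200, 150, 100])
        ]
        kept = cull_hits(hits, two_genomes)
        assert sorted(h.bit_score for h in kept) == [250, 300]

    def test_score_floor_is_strict(self, two_genomes):
        hits = [
            HomologyHit("A_c1_0000", "B_c1_0000", 49.9),
            HomologyHit("A_c1_0001", "B_c1_0001", 50.0),
        ]
        kept = cull_hits(hits, two_genomes)
        assert [h.bit_score for h in kept] == [50.0]

    def test_diploid_target_keeps_four(self):
        anns = {
            "A": make_annotation("A", {"c1": 5}, ploidy=2),
            "B": make_annotation("B", {"c1": 12}, ploidy=2),
        }
        hits = [HomologyHit("A_c1_0000", f"B_c1_{i:04d}", 100 + i) for i in range(10)]
        kept = cull_hits(hits, anns)
        assert len(kept) == 4
        assert min(h.bit_score for h in kept) == 106

    def test_subset_and_idempotent(self, two_genomes):
        rng = np.random.default_rng(1)
        hits = [
            HomologyHit(f"A_c1_{int(q):04d}", f"B_c1_{int(t):04d}", float(s))
            for q, t, s in zip(
                rng.integers(0, 20, 100), rng.integers(0, 20, 100),
                rng.uniform(20, 300, 100),
            )
        ]
        once = cull_hits(hits, two_genomes)
        assert set((h.query_gene, h.target_gene, h.bit_score) for h in once) <= set(
            (h.query_gene, h.target_gene, h.bit_score) for h in hits
        )
        twice = cull_hits(once, two_genomes)
        assert [(h.query_gene, h.target_gene) for h in twice] == [
            (h.query_gene, h.target_gene) for h in once
        ]

    def test_self_hits_removed(self, two_genomes):
        kept = cull_hits([HomologyHit("A_c1_0000", "A_c1_0000", 500)], two_genomes)
        assert kept == []

    def test_unknown_gene_rejected(self, two_genomes):
        with pytest.raises(Exception, match="unknown gene"):
            cull_hits([HomologyHit("nope", "B_c1_0000", 100)], two_genomes)


# ---------------------------------------------------------------------------
# Pairwise orthogroups
# ---------------------------------------------------------------------------

class TestPairwiseOrthogroups:
    GENOME_OF = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "C1": "C"}

    def test_reciprocal_pairs_give_two_groups(self):
        hits = [HomologyHit("A1", "B1", 200), HomologyHit("A2", "B2", 180)]
        groups = infer_pairwise_orthogroups(hits, self.GENOME_OF, ("A", "B"))
        assert len(groups) == 2
        assert all(g.size == 2 for g in groups)

    def test_connected_clique_is_one_group(self):
        hits = [
            HomologyHit(a, b, 150)
            for a in ("A1", "A2")
            for b in ("B1", "B2")
        ]
        groups = infer_pairwise_orthogroups(hits, self.GENOME_OF, ("A", "B"))
        assert len(groups) == 1
        assert groups[0].genes() == {"A1", "A2", "B1", "B2"}

    def test_isolated_gene_not_clustered(self):
        hits = [HomologyHit("A1", "B1", 200)]
        groups = infer_pairwise_orthogroups(hits, self.GENOME_OF, ("A", "B"))
        assert "A2" not in {g for og in groups for g in og.genes()}

    def test_weak_edge_below_best_fraction_cut(self):
        # A1's best is 400; the 150 edge to B2 is < 50% of both endpoints' best
        hits = [HomologyHit("A1", "B1", 400), HomologyHit("A1", "B2", 150),
                HomologyHit("A2", "B2", 400)]
        groups = infer_pairwise_orthogroups(hits, self.GENOME_OF, ("A", "B"))
        assert len(groups) == 2

    def test_hits_within_orthogroups_filters_cross_group(self):
        hits = [HomologyHit("A1", "B1", 400), HomologyHit("A2", "B2", 400)]
        groups = infer_pairwise_orthogroups(hits, self.GENOME_OF, ("A", "B"))
        cross = HomologyHit("A1", "B2", 60)
        kept = hits_within_orthogroups(hits + [cross], groups)
        assert cross not in kept and len(kept) == 2


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def oracle_best_chain_length(pairs, max_gap):
    """Independent quadratic DP: longest strictly-monotone chain (either
    orientation) with per-step gaps <= max_gap on both axes."""
    best = 0
    for sign in (1, -1):
        pts = sorted(pairs)
        n = len(pts)
        dp = [1] * n
        for i in range(n):
            for j in range(i):
                da = pts[i][0] - pts[j][0]
                db = sign * (pts[i][1] - pts[j][1])
                if 1 <= da <= max_gap and 1 <= db <= max_gap:
                    dp[i] = max(dp[i], dp[j] + 1)
        best = max(best, max(dp, default=0))
    return best


class TestChaining:
    def test_perfect_diagonal_one_collinear_block(self):
        blocks = chain_collinear_blocks(anchors([(i, i) for i in range(30)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == "collinear"
        assert blocks[0].anchor_count == 30

    def test_diagonal_plus_antidiagonal(self):
        pts = [(i, i) for i in range(30)] + [(40 + i, 100 - i) for i in range(30)]
        blocks = chain_collinear_blocks(anchors(pts))
        assert len(blocks) == 2
        assert sorted(b.orientation for b in blocks) == ["collinear", "inverted"]
        assert all(b.anchor_count == 30 for b in blocks)

    def test_below_minimum_block_size_discarded(self):
        blocks = chain_collinear_blocks(anchors([(i, i) for i in range(9)]))
        assert blocks == []

    @pytest.mark.parametrize("gap,expected_blocks", [(26, 2), (25, 1)])
    def test_gap_rule_boundary(self, gap, expected_blocks):
        pts = [(i, i) for i in range(30)]
        pts += [(29 + gap + i, 29 + gap + i) for i in range(30)]
        blocks = chain_collinear_blocks(anchors(pts))
        assert len(blocks) == expected_blocks

    def test_total_gap_budget_rule_limits_accumulated_gaps(self):
        # anchors every 2 ranks: each step costs 2 excess ranks; under the
        # total-budget reading (budget 25) a chain stops near 13 anchors,
        # under the per-step reading all 30 chain together
        pts = [(2 * i, 2 * i) for i in range(30)]
        per_step = chain_collinear_blocks(anchors(pts))
        assert len(per_step) == 1 and per_step[0].anchor_count == 30
        budgeted = chain_collinear_blocks(
            anchors(pts), SyntenyParams(gap_rule="total_gaps")
        )
        assert all(b.anchor_count <= 13 for b in budgeted)
        assert max(b.anchor_count for b in budgeted) == 13

    def test_duplicate_anchors_deduplicated_with_warning(self):
        pts = [(i, i) for i in range(12)] + [(3, 3)]
        with pytest.warns(UserWarning, match="deduplicated"):
            blocks = chain_collinear_blocks(anchors(pts))
        assert blocks[0].anchor_count == 12

    def test_emitted_blocks_strictly_monotone(self):
        rng = np.random.default_rng(4)
        pts = {(int(a), int(b)) for a, b in zip(rng.integers(0, 300, 400),
                                                rng.integers(0, 300, 400))}
        for blk in chain_collinear_blocks(anchors(sorted(pts))):
            ras = [a.rank_a for a in blk.anchors]
            rbs = [a.rank_b for a in blk.anchors]
            assert ras == sorted(ras) and len(set(ras)) == len(ras)
            if blk.orientation == "collinear":
                assert rbs == sorted(rbs) and len(set(rbs)) == len(rbs)
            else:
                assert rbs == sorted(rbs, reverse=True) and len(set(rbs)) == len(rbs)

    @pytest.mark.parametrize("seed", range(5))
    def test_first_block_matches_oracle_chain_length(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        pts = {(int(a), int(b)) for a, b in zip(rng.integers(0, 80, n),
                                                rng.integers(0, 80, n))}
        params = SyntenyParams(mbs=3)
        blocks = chain_collinear_blocks(anchors(sorted(pts)), params)
        expected = oracle_best_chain_length(sorted(pts), params.max_gap)
        if expected < params.mbs:
            assert blocks == []
        else:
            assert blocks[0].anchor_count == expected


# ---------------------------------------------------------------------------
# DBSCAN pruning
# ---------------------------------------------------------------------------

def oracle_dbscan(points, eps, min_pts):
    """Direct quadratic DBSCAN (Chebyshev metric) with the deterministic
    border rule: clusters are the connected components of core points under
    eps-adjacency; each border point joins its nearest core point's cluster."""

    def cheb(p, q):
        return max(abs(p[0] - q[0]), abs(p[1] - q[1]))

    n = len(points)
    neigh = [[j for j in range(n) if cheb(points[i], points[j]) <= eps] for i in range(n)]
    core = [len(neigh[i]) >= min_pts for i in range(n)]
    labels = [-1] * n
    c = 0
    for start in range(n):
        if not core[start] or labels[start] != -1:
            continue
        stack = [start]
        while stack:
            i = stack.pop()
            if labels[i] != -1:
                continue
            labels[i] = c
            stack.extend(j for j in neigh[i] if core[j] and labels[j] == -1)
        c += 1
    for i in range(n):
        if not core[i]:
            cores_near = [j for j in neigh[i] if core[j]]
            if cores_near:
                labels[i] = labels[min(cores_near, key=lambda j: (cheb(points[i], points[j]), j))]
    return labels


class TestPruning:
    def test_outliers_removed_dense_core_survives(self):
        pts = [(i, i) for i in range(30)] + [(200, 5), (5, 200), (300, 300)]
        blk = SyntenyBlock("b", "A", "B", "c", "c", anchors(pts), "collinear")
        out = prune_blocks_density([blk])
        assert len(out) == 1
        assert out[0].anchor_count == 30
        assert all(a.rank_a < 100 and a.rank_b < 100 for a in out[0].anchors)

    def test_exactly_mbs_anchors_within_eps_retained(self):
        pts = [(i, i) for i in range(10)]
        blk = SyntenyBlock("b", "A", "B", "c", "c", anchors(pts), "collinear")
        out = prune_blocks_density([blk])
        assert len(out) == 1 and out[0].anchor_count == 10

    def test_below_min_pts_block_removed(self):
        pts = [(i, i) for i in range(8)]
        blk = SyntenyBlock("b", "A", "B", "c", "c", anchors(pts), "collinear")
        assert prune_blocks_density([blk]) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_direct_quadratic_dbscan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        pts = [(int(a), int(b)) for a, b in zip(rng.integers(0, 400, n),
                                                rng.integers(0, 400, n))]
        params = SyntenyParams()
        blk = SyntenyBlock("b", "A", "B", "c", "c", anchors(sorted(set(pts))), "collinear")
        got = prune_blocks_density([blk], params)
        pts_u = sorted({(a.rank_a, a.rank_b) for a in blk.anchors})
        labels = oracle_dbscan(pts_u, params.eps, params.min_pts)
        expected_clusters = {}
        for p, l in zip(pts_u, labels):
            if l >= 0:
                expected_clusters.setdefault(l, set()).add(p)
        expected = {
            frozenset(v) for v in expected_clusters.values() if len(v) >= params.mbs
        }
        assert {frozenset((a.rank_a, a.rank_b) for a in b.anchors) for b in got} == expected


# ---------------------------------------------------------------------------
# Completion
# ---------------------------------------------------------------------------

class TestCompletion:
    GENOME_OF = {"A1": "A", "B1": "B", "C1": "C", "D1": "D", "E1": "E", "A2": "A", "B2": "B"}

    def og(self, *genes):
        og = Orthogroup("x")
        for g in genes:
            og.members.setdefault(self.GENOME_OF[g], set()).add(g)
        return og

    def test_shared_gene_merges_groups(self):
        merged = complete_orthogroups(
            [self.og("A1", "B1"), self.og("B1", "C1")], self.GENOME_OF
        )
        assert len(merged) == 1
        assert merged[0].genes() == {"A1", "B1", "C1"}

    def test_disjoint_groups_unchanged(self):
        merged = complete_orthogroups(
            [self.og("A1", "B1"), self.og("A2", "B2")], self.GENOME_OF
        )
        assert sorted(len(m.genes()) for m in merged) == [2, 2]

    def test_chain_across_five_genomes_collapses(self):
        chain = [self.og("A1", "B1"), self.og("B1", "C1"), self.og("C1", "D1"),
                 self.og("D1", "E1")]
        merged = complete_orthogroups(chain, self.GENOME_OF)
        assert len(merged) == 1 and len(merged[0].genes()) == 5

    def test_completion_is_idempotent(self):
        once = complete_orthogroups(
            [self.og("A1", "B1"), self.og("B1", "C1"), self.og("A2", "B2")],
            self.GENOME_OF,
        )
        twice = complete_orthogroups(once, self.GENOME_OF)
        assert sorted(frozenset(m.genes()) for m in once) == sorted(
            frozenset(m.genes()) for m in twice
        )


# ---------------------------------------------------------------------------
# Extension
# ---------------------------------------------------------------------------

class TestExtension:
    def setup_method(self):
        self.ann_a = make_annotation("A", {"c1": 120})
        self.ann_b = make_annotation("B", {"c1": 120})

    def hit(self, i, j, score=100.0):
        return HomologyHit(f"A_c1_{i:04d}", f"B_c1_{j:04d}", score)

    def test_nearby_hits_fill_gap(self):
        ranks = [i for i in range(40) if i not in (17, 18, 19)]
        hits = [self.hit(i, i) for i in ranks]
        blocks = chain_collinear_blocks(
            [AnchorPair(h.query_gene, h.target_gene, i, i, 100.0)
             for h, i in zip(hits, ranks)],
            genome_a="A", genome_b="B", chrom_a="c1", chrom_b="c1",
        )
        all_hits = hits + [self.hit(i, i) for i in (17, 18, 19)]
        extended = extend_blocks(blocks, all_hits, self.ann_a, self.ann_b)
        assert len(extended) == 1
        assert extended[0].anchor_count == blocks[0].anchor_count + 3

    def test_hits_beyond_radius_ignored(self):
        hits = [self.hit(i, i) for i in range(15)]
        blocks = chain_collinear_blocks(
            [AnchorPair(h.query_gene, h.target_gene, i, i, 100.0)
             for i, h in enumerate(hits)],
            genome_a="A", genome_b="B", chrom_a="c1", chrom_b="c1",
        )
        # 5 hits 115 ranks away: outside the 100-rank radius and too few to chain
        far = [self.hit(115 + i, 115 + i) for i in range(5)]
        extended = extend_blocks(blocks, hits + far, self.ann_a, self.ann_b)
        got = {(a.rank_a, a.rank_b) for b in extended for a in b.anchors}
        assert got == {(i, i) for i in range(15)}

    def test_no_extra_hits_is_idempotent(self):
        hits = [self.hit(i, i) for i in range(15)]
        blocks = chain_collinear_blocks(
            [AnchorPair(h.query_gene, h.target_gene, i, i, 100.0)
             for i, h in enumerate(hits)],
            genome_a="A", genome_b="B", chrom_a="c1", chrom_b="c1",
        )
        extended = extend_blocks(blocks, hits, self.ann_a, self.ann_b)
        assert {(a.rank_a, a.rank_b) for b in extended for a in b.anchors} == {
            (a.rank_a, a.rank_b) for b in blocks for a in b.anchors
        }


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class TestClassification:
    def setup_method(self):
        self.anns = {
            "A": make_annotation("A", {"c1": 40}),
            "B": make_annotation("B", {"c1": 40}),
        }
        pts = [(i, i) for i in range(20)]
        self.blocks = [SyntenyBlock(
            "b", "A", "B", "c1", "c1",
            [AnchorPair(f"A_c1_{i:04d}", f"B_c1_{i:04d}", i, i, 200.0) for i, _ in pts],
            "collinear",
        )]
        og = Orthogroup("og0")
        og.members = {"A": {"A_c1_0005", "A_c1_0006"}, "B": {"B_c1_0005"}}
        self.groups = [og]

    def classify(self, hits):
        return {
            (c.gene_a, c.gene_b): c.label
            for c in classify_syntenic_homologs(
                self.blocks, hits, self.groups, self.anns
            )
        }

    def test_same_group_inter_genome_is_ortholog(self):
        labels = self.classify([HomologyHit("A_c1_0005", "B_c1_0005", 300)])
        assert labels[("A_c1_0005", "B_c1_0005")] == "ortholog"

    def test_same_group_intra_genome_is_paralog(self):
        labels = self.classify([HomologyHit("A_c1_0005", "A_c1_0006", 250)])
        assert labels[("A_c1_0005", "A_c1_0006")] == "paralog"

    def test_unclustered_at_forty_percent_of_best_dropped(self):
        hits = [HomologyHit("A_c1_0010", "B_c1_0010", 500),
                HomologyHit("A_c1_0010", "B_c1_0012", 200)]
        labels = self.classify(hits)
        assert labels[("A_c1_0010", "B_c1_0012")] == "dropped"
        assert labels[("A_c1_0010", "B_c1_0010")] == "unclustered_homolog"

    def test_far_from_blocks_not_reported(self):
        labels = self.classify([HomologyHit("A_c1_0039", "B_c1_0039", 300)])
        # rank 39 is within the 50-rank cull radius of the block; shrink radius
        labels2 = {
            (c.gene_a, c.gene_b): c.label
            for c in classify_syntenic_homologs(
                self.blocks, [HomologyHit("A_c1_0039", "B_c1_0039", 300)],
                self.groups, self.anns, SyntenyParams(orthology_cull_radius=5),
            )
        }
        assert ("A_c1_0039", "B_c1_0039") in labels
        assert ("A_c1_0039", "B_c1_0039") not in labels2


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

class TestSummary:
    def test_zero_blocks(self):
        ann = make_annotation("A", {"c1": 10})
        df = summarize_synteny([], ann)
        row = df[df.chromosome == "c1"].iloc[0]
        assert row.genes_in_blocks == 0 and row.pct_in_blocks == 0.0

    def test_per_chromosome_counts_sum_to_total(self):
        ann = make_annotation("A", {"c1": 40, "c2": 40})
        blocks = []
        for chrom in ("c1", "c2"):
            blocks.append(SyntenyBlock(
                chrom, "A", "B", chrom, "x",
                [AnchorPair(f"A_{chrom}_{i:04d}", f"x{i}", i, i, 1.0) for i in range(30)],
                "collinear",
            ))
        df = summarize_synteny(blocks, ann, min_block_genes=25)
        total = df[df.chromosome == "TOTAL"].iloc[0]
        assert total.genes_in_blocks == df[df.chromosome != "TOTAL"].genes_in_blocks.sum()
        assert total.pct_in_blocks == pytest.approx(round(100 * 60 / 80, 1))

    def test_reporting_threshold_refilters(self):
        ann = make_annotation("A", {"c1": 40})
        small = SyntenyBlock(
            "s", "A", "B", "c1", "x",
            [AnchorPair(f"A_c1_{i:04d}", f"x{i}", i, i, 1.0) for i in range(12)],
            "collinear",
        )
        df = summarize_synteny([small], ann, min_block_genes=25)
        assert df[df.chromosome == "c1"].iloc[0].genes_in_blocks == 0

    def test_summary_from_counts_arithmetic(self):
        df = summary_from_counts([("1", 2436, 2235, 426), ("3", 2618, 2574, 2297)])
        r1 = df[df.chromosome == "1"].iloc[0]
        r3 = df[df.chromosome == "3"].iloc[0]
        assert r1.pct_in_blocks == 91.7
        assert r3.pct_in_blocks == 98.3
        assert r3.pct_largest_block == 87.7
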