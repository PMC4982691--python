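"""Operon-association rules: rank distances, co-promoter chains, verdicts."""

import pandas as pd
import pytest

import operon_recruit as opr
from operon_recruit.model import build_annotation
from operon_recruit.neighborhood import (
    UNLINKED,
    block_distance,
    classify_association,
    co_promoter,
    contexts_frame,
    neighbor_context,
    orf_distance,
    partition,
)


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "family", "evalue", "score"]
    )


def _orf(rank, start, end, strand="+", replicon="chrom"):
    from operon_recruit.model import Orf

    return Orf(
        locus_tag=f"t{replicon}{rank}", replicon_id=replicon, rank=rank,
        start=start, end=end, strand=strand, protein_id=f"p{rank}",
    )


class TestDistances:
    def test_adjacent_is_one(self):
        assert orf_distance(_orf(5, 500, 600), _orf(6, 700, 800)) == 1

    def test_same_gene_is_zero(self):
        a = _orf(3, 100, 200)
        assert orf_distance(a, a) == 0

    def test_block_distance_min_over_members(self):
        block = [_orf(3, 300, 390), _orf(4, 400, 490)]
        assert block_distance(_orf(10, 1000, 1090), block) == 6

    def test_inside_block_span_is_zero(self):
        block = [_orf(3, 300, 390), _orf(6, 600, 690)]
        assert block_distance(_orf(4, 400, 490), block) == 0

    def test_cross_replicon_unlinked(self):
        assert orf_distance(
            _orf(0, 100, 200), _orf(0, 100, 200, replicon="plasmid")
        ) is UNLINKED


class TestCoPromoter:
    def test_small_gaps_one_strand(self):
        chain = [_orf(0, 100, 400), _orf(1, 421, 700), _orf(2, 751, 1000)]
        assert co_promoter(chain, gap_max_bp=150)

    def test_strand_switch_breaks_chain(self):
        chain = [_orf(0, 100, 400), _orf(1, 421, 700, strand="-")]
        assert not co_promoter(chain, gap_max_bp=150)

    def test_big_gap_breaks_chain(self):
        chain = [_orf(0, 100, 400), _orf(1, 801, 1100)]
        assert not co_promoter(chain, gap_max_bp=150)

    def test_single_gene_chain_trivially_true(self):
        assert co_promoter([_orf(0, 100, 400)])


def layout_genome(genome_factory, roles, strands=None, gaps=None):
    n = len(roles)
    strands = strands or ["+"] * n
    layout = []
    for i in range(n):
        gap = gaps[i] if gaps else 50
        layout.append((roles[i], strands[i], gap))
    return genome_factory("g1", layout)


class TestClassify:
    def test_contiguous_operon_associated(self, genome_factory):
        ann, hits = layout_genome(
            genome_factory, [None, "sufC", "sufB", "sufT", None]
        )
        ctx, = classify_association(ann, _hits(hits))
        assert ctx.associated and ctx.orf_distance == 1 and ctx.co_promoter

    def test_five_ranks_away_not_associated(self, genome_factory):
        roles = ["sufB", "sufC"] + [None] * 4 + ["sufT"]
        ann, hits = layout_genome(genome_factory, roles)
        ctx, = classify_association(ann, _hits(hits))
        assert ctx.orf_distance == 5 and not ctx.associated

    def test_exactly_four_ranks_boundary_associated(self, genome_factory):
        roles = ["sufB", "sufC"] + [None] * 3 + ["sufT"]
        ann, hits = layout_genome(genome_factory, roles)
        ctx, = classify_association(ann, _hits(hits))
        assert ctx.orf_distance == 4 and ctx.associated

    def test_sufT_inside_operon_associated(self, genome_factory):
        # block with sufT between sufB and sufC, as in some actinobacterial
        # suf operons
        ann, hits = layout_genome(
            genome_factory, ["sufB", "sufT", "sufC", None]
        )
        ctx, = classify_association(ann, _hits(hits))
        assert ctx.associated and ctx.orf_distance == 0

    def test_opposite_strand_not_associated(self, genome_factory):
        ann, hits = layout_genome(
            genome_factory,
            ["sufB", "sufC", "sufT"],
            strands=["+", "+", "-"],
        )
        ctx, = classify_association(ann, _hits(hits))
        assert not ctx.associated and not ctx.co_promoter
        assert ctx.orf_distance == 1 and not ctx.same_strand

    def test_big_gap_not_associated(self, genome_factory):
        ann, hits = layout_genome(
            genome_factory, ["sufB", "sufC", "sufT"], gaps=[50, 50, 400]
        )
        ctx, = classify_association(ann, _hits(hits))
        assert not ctx.associated and ctx.max_intergenic_gap_bp == 400

    def test_no_block_unlinked(self, genome_factory):
        ann, hits = layout_genome(genome_factory, [None, "sufT", None])
        ctx, = classify_association(ann, _hits(hits))
        assert not ctx.associated and ctx.orf_distance is UNLINKED

    def test_monotone_in_thresholds(self, genome_factory):
        roles = ["sufB", "sufC", None, None, "sufT"]
        ann, hits = layout_genome(genome_factory, roles, gaps=[50] * 4 + [140])
        for dist in (3, 4, 6):
            for gap in (139, 141, 300):
                loose = classify_association(
                    ann, _hits(hits), max_orf_distance=dist + 1,
                    gap_max_bp=gap + 50,
                )[0]
                tight = classify_association(
                    ann, _hits(hits), max_orf_distance=dist, gap_max_bp=gap
                )[0]
                assert loose.associated or not tight.associated

    def test_reversal_symmetry(self):
        cfg = opr.SimulationConfig(seed=13, n_genomes=30)
        anns, hits, _ = opr.simulate_genomes(cfg)
        retained = hits[hits["evalue"] <= 1e-5]
        flip = {"+": "-", "-": "+"}
        for ann in anns:
            fwd = {
                c.sufT_protein_id: c.associated
                for c in classify_association(ann, retained)
            }
            rows = []
            for orf in ann.orfs():
                top = max(o.end for o in ann.replicons[orf.replicon_id]) + 100
                rows.append(
                    (orf.replicon_id, orf.locus_tag, top + 1 - orf.end,
                     top + 1 - orf.start, flip[orf.strand], orf.protein_id)
                )
            rev_ann = build_annotation(ann.genome_id, rows)
            rev = {
                c.sufT_protein_id: c.associated
                for c in classify_association(rev_ann, retained)
            }
            assert fwd == rev


class TestPartition:
    def test_empty(self):
        p = partition([])
        assert (p.n_associated, p.n_non_associated) == (0, 0)

    def test_conservation_on_random_layouts(self):
        cfg = opr.SimulationConfig(seed=99, n_genomes=100)
        anns, hits, truth = opr.simulate_genomes(cfg)
        retained = hits[hits["evalue"] <= 1e-5]
        ctxs = []
        for ann in anns:
            ctxs += classify_association(ann, retained)
        p = partition(ctxs)
        assert p.n_total == len(truth.association)
        assert p.n_associated == sum(
            a for a, _ in truth.association.values()
        )

    def test_planted_partition_recovered_exactly(self):
        import random

        from operon_recruit.simulate import plan_partition_cohort

        rng = random.Random(42)
        plans = plan_partition_cohort(37, 41, rng)
        anns, hits, truth = opr.simulate_genomes(
            opr.SimulationConfig(seed=42), plans=plans
        )
        ctxs = []
        for ann in anns:
            ctxs += classify_association(ann, hits[hits["evalue"] <= 1e-5])
        p = partition(ctxs)
        assert (p.n_associated, p.n_non_associated) == (37, 41)
        for c in ctxs:
            assert c.associated == truth.association[c.sufT_protein_id][0]


class TestNeighborContext:
    def test_planted_partner_in_context(self, genome_factory):
        ann, hits = layout_genome(
            genome_factory, [None, "sufT", "other:anaerobic_RNR_activase"]
        )
        focal = ann.replicons["chrom"][1]
        ctx = neighbor_context(ann, _hits(hits), focal, window=4)
        assert "other:anaerobic_RNR_activase" in ctx

    def test_replicon_edge_truncates_window(self, genome_factory):
        ann, hits = layout_genome(genome_factory, ["sufT", None])
        focal = ann.replicons["chrom"][0]
        assert neighbor_context(ann, _hits(hits), focal, window=4) == []

    def test_lacto_style_partner_recovered_always(self):
        cfg = opr.SimulationConfig(
            seed=8, n_genomes=40, p_sufBC=0.0, n_lacto_genomes=40,
            p_sufT_given_no_sufBC=0.0,
        )
        anns, hits, truth = opr.simulate_genomes(cfg)
        retained = hits[hits["evalue"] <= 1e-5]
        assert len(truth.lacto_partner) == 40
        found = 0
        for ann in anns:
            partner = truth.lacto_partner[ann.genome_id]
            for ctx in classify_association(ann, retained):
                if partner in ctx.neighbor_families:
                    found += 1
        assert found == 40

    def test_contexts_frame_columns(self, genome_factory):
        ann, hits = layout_genome(genome_factory, ["sufB", "sufC", "sufT"])
        df = contexts_frame(classify_association(ann, _hits(hits)))
        assert list(df["associated"]) == [True]
        assert df.iloc[0]["orf_distance"] == 1
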