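"""Operon association of sufT with the sufBC block by gene-neighborhood rules.

A sufT homolog is called *suf-operon associated* when it lies within a
configurable number of open reading frames (default four) of the nearest
sufB/sufC gene on the same replicon AND the whole chain of genes linking it
to the block looks co-transcribed: one shared strand, colinear gene order,
and every intergenic gap at most ``gap_max_bp`` (default 150 bp) — a
standard operon-prediction heuristic standing in for "transcribed from a
common promoter".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import DataError, GenomeAnnotation, Orf, qualify

#: sentinel orf_distance for sufT on a replicon without any sufB/sufC gene
UNLINKED = None


@dataclass
class OperonContext:
    """Association verdict and neighborhood evidence for one sufT homolog."""

    sufT_protein_id: str
    associated: bool
    orf_distance: int | None  # rank offset to nearest block member; UNLINKED if none
    same_strand: bool
    co_promoter: bool
    max_intergenic_gap_bp: int | None
    neighbor_families: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AssociationPartition:
    n_associated: int
    n_non_associated: int

    @property
    def n_total(self) -> int:
        return self.n_associated + self.n_non_associated


def orf_distance(a: Orf, b: Orf) -> int | None:
    """Rank offset between two ORFs; UNLINKED across replicons."""
    if a.replicon_id != b.replicon_id:
        return UNLINKED
    return abs(a.rank - b.rank)


def block_distance(focal: Orf, block: list[Orf]) -> int | None:
    """Rank distance from ``focal`` to a multi-gene block.

    0 iff the focal gene lies inside the block's rank span; otherwise the
    minimum rank offset over block members; UNLINKED across replicons.
    """
    if not block:
        return UNLINKED
    if any(m.replicon_id != focal.replicon_id for m in block):
        return UNLINKED
    ranks = [m.rank for m in block]
    if min(ranks) <= focal.rank <= max(ranks):
        return 0
    return min(abs(focal.rank - r) for r in ranks)


def intergenic_gaps(chain: list[Orf]) -> list[int]:
    """Gaps (bp, may be negative for overlaps) between rank-consecutive ORFs."""
    return [
        chain[i + 1].start - chain[i].end - 1 for i in range(len(chain) - 1)
    ]


def co_promoter(chain: list[Orf], gap_max_bp: int = 150) -> bool:
    """Heuristic single-transcription-unit test for a rank-contiguous chain.

    True iff all members share one strand and every intergenic gap along the
    chain is at most ``gap_max_bp``. Chains are given in rank (= start
    coordinate) order, so colinearity with the transcription direction of
    the shared strand holds by construction; a single-gene chain is trivially
    co-transcribed.
    """
    if len(chain) <= 1:
        return True
    strands = {o.strand for o in chain}
    if len(strands) != 1:
        return False
    return all(gap <= gap_max_bp for gap in intergenic_gaps(chain))


def _family_orfs(
    genome: GenomeAnnotation, hits: pd.DataFrame, family: str
) -> list[Orf]:
    """ORFs of ``genome`` whose protein has a retained hit to ``family``."""
    wanted = set(hits.loc[hits["family"] == family, "protein_id"])
    out = []
    for orf in genome.orfs():
        if (
            orf.protein_id in wanted
            or qualify(genome.genome_id, orf.protein_id) in wanted
        ):
            out.append(orf)
    return out


def _group_blocks(members: list[Orf], max_rank_gap: int = 2) -> list[list[Orf]]:
    """Group sufB/sufC ORFs on one replicon into contiguous blocks."""
    by_replicon: dict[str, list[Orf]] = {}
    for orf in sorted(members, key=lambda o: (o.replicon_id, o.rank)):
        by_replicon.setdefault(orf.replicon_id, []).append(orf)
    blocks: list[list[Orf]] = []
    for orfs in by_replicon.values():
        current = [orfs[0]]
        for orf in orfs[1:]:
            if orf.rank - current[-1].rank <= max_rank_gap:
                current.append(orf)
            else:
                blocks.append(current)
                current = [orf]
        blocks.append(current)
    return blocks


def _chain(replicon: list[Orf], focal: Orf, block: list[Orf]) -> list[Orf]:
    """Rank-contiguous ORF chain linking ``focal`` to (and through) the block."""
    ranks = [m.rank for m in block] + [focal.rank]
    lo, hi = min(ranks), max(ranks)
    return replicon[lo : hi + 1]


def classify_association(
    genome: GenomeAnnotation,
    hits: pd.DataFrame,
    max_orf_distance: int = 4,
    gap_max_bp: int = 150,
) -> list[OperonContext]:
    """Assess every sufT homolog of a genome for suf-operon association.

    Returns one :class:`OperonContext` per sufT homolog. Genomes lacking a
    sufB/sufC gene on the homolog's replicon (or entirely) yield
    non-associated contexts with UNLINKED distance. When two blocks are
    equidistant the one with the smaller start coordinate is used, for
    determinism.
    """
    sufT_orfs = _family_orfs(genome, hits, "sufT")
    block_members = _family_orfs(genome, hits, "sufB") + _family_orfs(
        genome, hits, "sufC"
    )
    blocks = _group_blocks(block_members) if block_members else []

    contexts = []
    for orf in sufT_orfs:
        candidates = [
            (block_distance(orf, b), b)
            for b in blocks
            if block_distance(orf, b) is not UNLINKED
        ]
        if not candidates:
            contexts.append(
                OperonContext(
                    sufT_protein_id=qualify(genome.genome_id, orf.protein_id),
                    associated=False,
                    orf_distance=UNLINKED,
                    same_strand=False,
                    co_promoter=False,
                    max_intergenic_gap_bp=None,
                    neighbor_families=neighbor_context(
                        genome, hits, orf, max_orf_distance, gap_max_bp
                    ),
                )
            )
            continue
        dist, block = min(
            candidates, key=lambda db: (db[0], min(m.start for m in db[1]))
        )
        replicon = genome.replicons[orf.replicon_id]
        chain = _chain(replicon, orf, block)
        nearest = min(block, key=lambda m: (abs(m.rank - orf.rank), m.start))
        gaps = intergenic_gaps(chain)
        is_co = co_promoter(chain, gap_max_bp)
        contexts.append(
            OperonContext(
                sufT_protein_id=qualify(genome.genome_id, orf.protein_id),
                associated=(dist <= max_orf_distance) and is_co,
                orf_distance=dist,
                same_strand=orf.strand == nearest.strand,
                co_promoter=is_co,
                max_intergenic_gap_bp=max(gaps) if gaps else 0,
                neighbor_families=neighbor_context(
                    genome, hits, orf, max_orf_distance, gap_max_bp
                ),
            )
        )
    return contexts


def partition(contexts: list[OperonContext]) -> AssociationPartition:
    """Count associated vs non-associated homologs."""
    n_assoc = sum(c.associated for c in contexts)
    return AssociationPartition(
        n_associated=n_assoc, n_non_associated=len(contexts) - n_assoc
    )


def neighbor_context(
    genome: GenomeAnnotation,
    hits: pd.DataFrame,
    focal: Orf,
    window: int = 4,
    gap_max_bp: int = 150,
) -> list[str]:
    """Family labels of putative co-transcribed neighbors of ``focal``.

    Walks outward from the focal gene within ``window`` ranks, extending in
    each direction only while the strand matches and the intergenic gap stays
    within ``gap_max_bp`` (i.e. the neighbors form one co-promoter chain with
    the focal gene). Labels come from the hit table; unannotated neighbors
    are skipped. Order follows replicon gene order.
    """
    replicon = genome.replicons[focal.replicon_id]
    protein_family: dict[str, str] = {}
    for row in hits.itertuples():
        protein_family.setdefault(row.protein_id, row.family)

    def label(orf: Orf) -> str | None:
        return protein_family.get(
            qualify(genome.genome_id, orf.protein_id)
        ) or protein_family.get(orf.protein_id)

    members: list[Orf] = []
    # extend left
    i = focal.rank
    while i > 0 and focal.rank - (i - 1) <= window:
        prev, cur = replicon[i - 1], replicon[i]
        if prev.strand != focal.strand or cur.start - prev.end - 1 > gap_max_bp:
            break
        members.insert(0, prev)
        i -= 1
    # extend right
    i = focal.rank
    while i < len(replicon) - 1 and (i + 1) - focal.rank <= window:
        cur, nxt = replicon[i], replicon[i + 1]
        if nxt.strand != focal.strand or nxt.start - cur.end - 1 > gap_max_bp:
            break
        members.append(nxt)
        i += 1
    return [fam for orf in members if (fam := label(orf)) is not None]


def contexts_frame(contexts: list[OperonContext]) -> pd.DataFrame:
    """Per-homolog TSV-ready table of association evidence."""
    rows = [
        {
            "protein_id": c.sufT_protein_id,
            "associated": c.associated,
            "orf_distance": "unlinked" if c.orf_distance is UNLINKED else c.orf_distance,
            "same_strand": c.same_strand,
            "co_promoter": c.co_promoter,
            "max_gap_bp": "" if c.max_intergenic_gap_bp is None else c.max_intergenic_gap_bp,
            "neighbors": ",".join(c.neighbor_families),
        }
        for c in contexts
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "associated", "orf_distance", "same_strand",
            "co_promoter", "max_gap_bp", "neighbors",
        ],
    )
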