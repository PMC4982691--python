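"""Synthetic-data generation with known ground truth for every pipeline stage.

The generator emulates the study conditions of a prokaryotic comparative
screen: a cohort of annotated genomes with or without the sufBC scaffold
genes, sufT homologs planted inside or outside the suf neighborhood (with an
explicit mode for every way a homolog can fail the association rule),
lactobacilli-style scaffold-free genomes whose sufT sits in an operon with
an FeS-requiring enzyme, DUF59 proteins drawn from the S1–S9 modular
classes, binary traits evolved along a Yule tree under a two-state
continuous-time Markov model, and alignments with planted invariant columns.

Everything is deterministic per seed (pure ``random.Random`` integer-state
RNG; no global or time-based seeding), and every emitted file parses with
the package's own readers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .architecture import MOTIF_CLASSES, DomainHitRecord
from .model import (
    Alignment,
    DataError,
    GenomeAnnotation,
    TraitMap,
    build_annotation,
    qualify,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: explicit ways a sufT homolog can fail the operon-association rule
NON_ASSOCIATION_MODES = ("far", "opposite_strand", "big_gap", "other_replicon")


@dataclass
class SimulationConfig:
    """Study-condition parameters for cohort simulation.

    Defaults mirror the frequencies of the genome screen the pipeline
    targets: ~65% of genomes carry sufBC, ~70% of those also carry sufT, and
    about half of the sufT homologs in sufBC genomes sit in the suf
    neighborhood.
    """

    seed: int = 0
    n_genomes: int = 200
    p_sufBC: float = 0.654
    p_sufT_given_sufBC: float = 0.697
    p_sufT_given_no_sufBC: float = 0.118
    p_associated_given_both: float = 0.4915
    p_iscU: float = 0.45
    p_nifU: float = 0.2
    n_lacto_genomes: int = 3
    p_decoy_hit: float = 0.1
    genome_n_orfs: int = 50
    gap_bp_range: tuple[int, int] = (5, 120)
    architecture_proportions: dict[str, float] = field(
        default_factory=lambda: {
            # proportions of the nine modular classes among DUF59 proteins
            "S1": 563 / 761, "S2": 88 / 761, "S3": 75 / 761, "S4": 20 / 761,
            "S5": 5 / 761, "S6": 4 / 761, "S7": 3 / 761, "S8": 2 / 761,
            "S9": 1 / 761,
        }
    )
    tree_n_tips: int = 100
    trait_gain_rate: float = 0.5
    trait_loss_rate: float = 0.5
    root_state: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_sufBC", "p_sufT_given_sufBC", "p_sufT_given_no_sufBC",
            "p_associated_given_both", "p_iscU", "p_nifU", "p_decoy_hit",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataError(f"{name}={v} outside [0, 1]")
        total = sum(self.architecture_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"architecture proportions sum to {total}, not 1")


@dataclass
class TraitEvent:
    """One simulated state change on a branch."""

    edge_child: str  # tip label or internal node id of the child end
    position: float  # distance from the branch's parent end
    from_state: int
    to_state: int


@dataclass
class GenomePlan:
    """Planted configuration of one simulated genome."""

    genome_id: str
    has_sufBC: bool = False
    has_iscU: bool = False
    has_nifU: bool = False
    sufT_modes: tuple[str, ...] = ()  # 'associated' or a NON_ASSOCIATION_MODE;
    # genomes without sufBC use mode 'no_block'
    lacto: bool = False


@dataclass
class GroundTruth:
    """Planted truth, field by field, for the emitted synthetic inputs."""

    presence: dict[str, dict[str, bool]] = field(default_factory=dict)
    association: dict[str, tuple[bool, str]] = field(default_factory=dict)
    lacto_partner: dict[str, str] = field(default_factory=dict)
    architecture: dict[str, str] = field(default_factory=dict)
    protein_length: dict[str, int] = field(default_factory=dict)
    trait_events: list[TraitEvent] = field(default_factory=list)
    conserved_columns: dict[int, str] = field(default_factory=dict)
    decoy_hits: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int, seed: int, ultrametric: bool = True
) -> dendropy.Tree:
    """Rooted binary Yule tree with unit root-to-tip depth.

    Tips are labeled T0001..Tn in a deterministic order; with
    ``ultrametric=False`` terminal branch lengths are jittered so tip depths
    vary (as in a tree of homologs rather than extant species).
    """
    if n_tips < 2:
        raise DataError("need at least 2 tips")
    rng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i:04d}"
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    if not ultrametric:
        for leaf in tree.leaf_node_iter():
            leaf.edge.length *= rng.uniform(0.5, 1.5)
    return tree


def simulate_trait(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    root_state: int,
    seed: int,
) -> tuple[TraitMap, list[TraitEvent]]:
    """Evolve a binary trait along the tree under a two-state CTMC.

    State 0 switches to 1 at ``gain_rate`` per unit branch length and back
    at ``loss_rate``. Every change is recorded with its branch (named by the
    child node) and position, so parsimony scores can be compared against
    the true number of events.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise DataError("rates must be non-negative")
    rng = random.Random(seed)
    rates = {0: gain_rate, 1: loss_rate}
    events: list[TraitEvent] = []
    states: dict[str, str] = {}
    node_state: dict[int, int] = {id(tree.seed_node): int(root_state)}
    internal_counter = 0
    node_name: dict[int, str] = {}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            name = "root"
        elif node.is_leaf():
            name = node.taxon.label
        else:
            internal_counter += 1
            name = f"node{internal_counter}"
        node_name[id(node)] = name
        if node is tree.seed_node:
            continue
        state = node_state[id(node.parent_node)]
        length = node.edge.length or 0.0
        t = 0.0
        while True:
            rate = rates[state]
            if rate == 0:
                break
            t += rng.expovariate(rate)
            if t >= length:
                break
            events.append(
                TraitEvent(
                    edge_child=name,
                    position=t,
                    from_state=state,
                    to_state=1 - state,
                )
            )
            state = 1 - state
        node_state[id(node)] = state
        if node.is_leaf():
            states[name] = str(state)

    traits = TraitMap(states=states, state_space=("0", "1"))
    return traits, events


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def plan_cohort(config: SimulationConfig, rng: random.Random) -> list[GenomePlan]:
    """Draw per-genome configurations from the cohort frequencies."""
    plans = []
    n_lacto_left = config.n_lacto_genomes
    for g in range(config.n_genomes):
        gid = f"G{g + 1:04d}"
        has_sufBC = rng.random() < config.p_sufBC
        modes: list[str] = []
        lacto = False
        if has_sufBC:
            if rng.random() < config.p_sufT_given_sufBC:
                if rng.random() < config.p_associated_given_both:
                    modes.append("associated")
                else:
                    modes.append(rng.choice(NON_ASSOCIATION_MODES))
            has_iscU = rng.random() < config.p_iscU
            has_nifU = rng.random() < config.p_nifU
        elif n_lacto_left > 0:
            lacto, n_lacto_left = True, n_lacto_left - 1
            modes.append("no_block")
            has_iscU = has_nifU = False
        else:
            if rng.random() < config.p_sufT_given_no_sufBC:
                modes.append("no_block")
            has_iscU = rng.random() < config.p_iscU
            has_nifU = rng.random() < config.p_nifU
        plans.append(
            GenomePlan(
                genome_id=gid,
                has_sufBC=has_sufBC,
                has_iscU=has_iscU,
                has_nifU=has_nifU,
                sufT_modes=tuple(modes),
                lacto=lacto,
            )
        )
    return plans


def plan_partition_cohort(
    n_associated: int, n_non_associated: int, rng: random.Random
) -> list[GenomePlan]:
    """One-homolog-per-genome cohort planting an exact association partition.

    Non-associated homologs cycle through every failure mode so each branch
    of the classifier is exercised.
    """
    plans = []
    for i in range(n_associated):
        plans.append(
            GenomePlan(
                genome_id=f"A{i + 1:04d}",
                has_sufBC=True,
                sufT_modes=("associated",),
            )
        )
    for i in range(n_non_associated):
        mode = NON_ASSOCIATION_MODES[i % len(NON_ASSOCIATION_MODES)]
        plans.append(
            GenomePlan(
                genome_id=f"N{i + 1:04d}",
                has_sufBC=True,
                sufT_modes=(mode,),
            )
        )
    rng.shuffle(plans)
    return plans


def _materialize_replicon(
    genome_id: str,
    replicon_id: str,
    n_orfs: int,
    strands: dict[int, str],
    gap_overrides: dict[int, int],
    rng: random.Random,
    gap_range: tuple[int, int],
    start_tag: int = 0,
) -> list[tuple[str, str, int, int, str, str]]:
    """Lay out ``n_orfs`` genes left to right, honoring per-rank strand and
    gap-before overrides. Returns build_annotation row tuples."""
    rows = []
    pos = 1
    for rank in range(n_orfs):
        gap = gap_overrides.get(rank, rng.randint(*gap_range))
        if rank > 0:
            pos += gap
        length = rng.randrange(300, 1500, 3)
        start, end = pos, pos + length - 1
        pos = end + 1
        strand = strands.get(rank, rng.choice("+-"))
        tag = f"{genome_id}_{replicon_id}_{rank + start_tag:04d}"
        rows.append((replicon_id, tag, start, end, strand, f"p_{tag}"))
    return rows


def simulate_genome(
    plan: GenomePlan,
    config: SimulationConfig,
    rng: random.Random,
) -> tuple[GenomeAnnotation, list[dict], GroundTruth]:
    """Materialize one genome from its plan.

    Returns the annotation, raw family-hit rows (dicts) and a GroundTruth
    fragment holding the planted presence and association truth for this
    genome.
    """
    near_modes = {"associated", "opposite_strand", "big_gap"}
    if sum(m in near_modes for m in plan.sufT_modes) > 1:
        raise DataError("at most one near-block sufT mode per genome")
    if plan.sufT_modes and not plan.has_sufBC:
        if any(m != "no_block" for m in plan.sufT_modes):
            raise DataError("near/far modes require a sufBC block")

    n = config.genome_n_orfs
    strands: dict[int, str] = {}
    gap_overrides: dict[int, int] = {}
    role: dict[int, str] = {}  # rank -> family
    plasmid_roles: dict[int, str] = {}
    truth = GroundTruth()
    gid = plan.genome_id
    mode_by_rank: dict[int, str] = {}
    mode_on_plasmid: list[str] = []

    free = set(range(n))

    def take(rank: int, family: str) -> None:
        role[rank] = family
        free.discard(rank)

    block_strand = rng.choice("+-")
    if plan.has_sufBC:
        b = rng.randint(5, n - 15)
        take(b, "sufB")
        take(b + 1, "sufC")
        strands[b] = strands[b + 1] = block_strand
        for m in plan.sufT_modes:
            if m == "associated":
                d = rng.randint(1, 4)
                t_rank = b + 1 + d
                for r in range(b, t_rank + 1):
                    strands[r] = block_strand
                take(t_rank, "sufT")
                mode_by_rank[t_rank] = m
            elif m == "opposite_strand":
                d = rng.randint(1, 4)
                t_rank = b + 1 + d
                for r in range(b, t_rank):
                    strands[r] = block_strand
                strands[t_rank] = "+" if block_strand == "-" else "-"
                take(t_rank, "sufT")
                mode_by_rank[t_rank] = m
            elif m == "big_gap":
                d = rng.randint(1, 4)
                t_rank = b + 1 + d
                for r in range(b, t_rank + 1):
                    strands[r] = block_strand
                gap_overrides[rng.randint(b + 2, t_rank)] = 400
                take(t_rank, "sufT")
                mode_by_rank[t_rank] = m
            elif m == "far":
                d = rng.randint(6, 10)
                t_rank = b + 1 + d if b + 1 + d < n else b - d
                take(t_rank, "sufT")
                mode_by_rank[t_rank] = m
            elif m == "other_replicon":
                mode_on_plasmid.append(m)
            else:
                raise DataError(f"unknown sufT mode {m!r}")
    else:
        for m in plan.sufT_modes:
            t_rank = rng.choice(sorted(free - {0, n - 1}))
            take(t_rank, "sufT")
            mode_by_rank[t_rank] = "no_block"
            if plan.lacto:
                partner = rng.choice(
                    ["anaerobic_RNR_activase", "serine_dehydratase"]
                )
                p_rank = t_rank + 1
                take(p_rank, f"other:{partner}")
                strands[t_rank] = strands[p_rank] = rng.choice("+-")
                gap_overrides[p_rank] = rng.randint(5, 60)
                truth.lacto_partner[gid] = f"other:{partner}"

    for fam, flag in (("iscU", plan.has_iscU), ("nifU", plan.has_nifU)):
        if flag:
            r = rng.choice(sorted(free))
            take(r, fam)

    rows = _materialize_replicon(
        gid, "chrom", n, strands, gap_overrides, rng, config.gap_bp_range
    )

    if mode_on_plasmid:
        p_n = 8
        p_strands: dict[int, str] = {}
        t_rank = rng.randint(1, p_n - 2)
        rows += _materialize_replicon(
            gid, "plasmid", p_n, p_strands, {}, rng, config.gap_bp_range,
            start_tag=n,
        )
        plasmid_roles[t_rank] = "sufT"

    annotation = build_annotation(gid, rows)

    hit_rows: list[dict] = []
    presence = {f: False for f in ("sufB", "sufC", "sufT", "iscU", "nifU")}

    def emit_hit(orf_pid: str, family: str) -> None:
        hit_rows.append(
            {
                "protein_id": qualify(gid, orf_pid),
                "family": family,
                "evalue": 10 ** -rng.uniform(10, 60),
                "score": round(rng.uniform(80, 900), 1),
            }
        )
        if family in presence:
            presence[family] = True

    chrom = annotation.replicons["chrom"]
    for rank, fam in role.items():
        emit_hit(chrom[rank].protein_id, fam)
        if fam == "sufT":
            truth.association[qualify(gid, chrom[rank].protein_id)] = (
                mode_by_rank[rank] == "associated",
                mode_by_rank[rank],
            )
    if plasmid_roles:
        plasmid = annotation.replicons["plasmid"]
        for rank, fam in plasmid_roles.items():
            emit_hit(plasmid[rank].protein_id, fam)
            truth.association[qualify(gid, plasmid[rank].protein_id)] = (
                False,
                "other_replicon",
            )

    if rng.random() < config.p_decoy_hit:
        # a hit too weak to survive the default e-value filter
        victim = chrom[rng.choice(sorted(free))]
        pid = qualify(gid, victim.protein_id)
        hit_rows.append(
            {
                "protein_id": pid,
                "family": "sufT",
                "evalue": 10 ** -rng.uniform(1.0, 4.0),
                "score": round(rng.uniform(20, 40), 1),
            }
        )
        truth.decoy_hits.append(pid)

    truth.presence[gid] = presence
    return annotation, hit_rows, truth


def simulate_genomes(
    config: SimulationConfig,
    plans: list[GenomePlan] | None = None,
) -> tuple[list[GenomeAnnotation], pd.DataFrame, GroundTruth]:
    """Simulate a whole cohort: annotations, family-hit table, ground truth.

    ``plans`` overrides the probabilistic cohort draw (used to plant exact
    counts). The returned hit table is raw (pre-filter); planted hits are
    well below any sensible e-value threshold, decoys well above.
    """
    rng = random.Random(config.seed)
    if plans is None:
        plans = plan_cohort(config, rng)
    annotations: list[GenomeAnnotation] = []
    all_hits: list[dict] = []
    truth = GroundTruth()
    for plan in plans:
        ann, hits, frag = simulate_genome(plan, config, rng)
        annotations.append(ann)
        all_hits.extend(hits)
        truth.presence.update(frag.presence)
        truth.association.update(frag.association)
        truth.lacto_partner.update(frag.lacto_partner)
        truth.decoy_hits.extend(frag.decoy_hits)
    hits_df = pd.DataFrame(
        all_hits, columns=["protein_id", "family", "evalue", "score"]
    )
    return annotations, hits_df, truth


# ---------------------------------------------------------------------------
# domain architectures
# ---------------------------------------------------------------------------

def _architecture_layout(
    label: str, rng: random.Random
) -> tuple[int, list[tuple[str, int, int]]]:
    """Protein length and (motif, start, end) hits realizing a class."""
    if label == "S1":
        return 100, [("DUF59", 1, 99)]
    motif = next(m for m, (lab, _) in MOTIF_CLASSES.items() if lab == label)
    side = MOTIF_CLASSES[motif][1]
    if side == "N":
        return 230, [(motif, 5, 100), ("DUF59", 120, 218)]
    return 310, [("DUF59", 1, 99), (motif, 130, 300)]


def simulate_architectures(
    proportions: dict[str, float] | None = None,
    n: int = 761,
    seed: int = 0,
    counts: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a domain-hit table realizing planted S1–S9 classes.

    Either draw ``n`` labels from ``proportions`` (multinomial) or plant
    exact ``counts``. Coordinates respect the classifier's side and flank
    rules, so classification recovers the planted label for every protein.
    """
    rng = random.Random(seed)
    if counts is not None:
        labels = [lab for lab, c in counts.items() for _ in range(c)]
    else:
        if proportions is None:
            raise DataError("need proportions or counts")
        pop, weights = zip(*sorted(proportions.items()))
        labels = rng.choices(pop, weights=weights, k=n)
    rng.shuffle(labels)

    truth = GroundTruth()
    rows = []
    for i, label in enumerate(labels, start=1):
        pid = f"duf59_{i:05d}"
        length, hits = _architecture_layout(label, rng)
        truth.architecture[pid] = label
        truth.protein_length[pid] = length
        for motif, start, end in hits:
            rows.append(
                {
                    "protein_id": pid,
                    "motif": motif,
                    "start": start,
                    "end": end,
                    "evalue": 10 ** -rng.uniform(4, 30),
                }
            )
        if rng.random() < 0.15:
            # sub-threshold noise hit; must never change a call
            rows.append(
                {
                    "protein_id": pid,
                    "motif": rng.choice(list(MOTIF_CLASSES)),
                    "start": 1,
                    "end": length,
                    "evalue": rng.uniform(0.05, 5.0),
                }
            )
    hits_df = pd.DataFrame(
        rows, columns=["protein_id", "motif", "start", "end", "evalue"]
    )
    return hits_df, truth


def domain_records(
    hits: pd.DataFrame, protein_id: str
) -> list[DomainHitRecord]:
    """Convert a protein's rows of a domain-hit table to records."""
    sub = hits[hits["protein_id"] == protein_id]
    return [
        DomainHitRecord(
            protein_id=r.protein_id,
            motif=r.motif,
            start=int(r.start),
            end=int(r.end),
            evalue=float(r.evalue),
        )
        for r in sub.itertuples()
    ]


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def simulate_alignment(
    n_seqs: int,
    length: int,
    conserved: dict[int, str] | None = None,
    seed: int = 0,
    reference_gapless: bool = True,
    gap_prob: float = 0.05,
) -> tuple[Alignment, GroundTruth]:
    """Random alignment with planted invariant columns.

    ``conserved`` maps 1-based column indices to the residue planted across
    all sequences; gaps are sprinkled elsewhere (never in conserved columns,
    and never in the reference if ``reference_gapless``). The first record
    is the reference.
    """
    conserved = dict(conserved or {})
    if any(not 1 <= c <= length for c in conserved):
        raise DataError("conserved column outside alignment length")
    rng = random.Random(seed)
    records = []
    for s in range(n_seqs):
        sid = f"seq{s + 1:03d}"
        chars = []
        for col in range(1, length + 1):
            if col in conserved:
                chars.append(conserved[col])
            elif s > 0 or not reference_gapless:
                if rng.random() < gap_prob:
                    chars.append("-")
                else:
                    chars.append(rng.choice(AMINO_ACIDS))
            else:
                chars.append(rng.choice(AMINO_ACIDS))
        records.append((sid, "".join(chars)))
    truth = GroundTruth(conserved_columns=dict(conserved))
    return Alignment(records=records, reference_id=records[0][0]), truth
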