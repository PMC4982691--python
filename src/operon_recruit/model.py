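"""Core domain types shared across the pipeline.

Conventions used everywhere in this package:

* genomic and protein coordinates are 1-based and inclusive (GFF3 dialect);
* gene-order ranks within a replicon are 0-based and contiguous, assigned by
  sorting on the start coordinate;
* protein identifiers are namespaced ``<genome_id>|<protein_id>`` as soon as
  annotations from several genomes are pooled, so that homologs from
  different genomes never collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

GAP = "-"

#: gene families tracked explicitly in presence/absence screens; anything
#: else is carried as ``other:<label>``.
KNOWN_FAMILIES = ("sufB", "sufC", "sufT", "iscU", "nifU")

#: motif labels with a defined DUF59 modular-architecture class.
KNOWN_MOTIFS = (
    "DUF59",
    "unknown_N",
    "U_type_scaffold",
    "rieske_ferredoxin",
    "cysE",
    "paaJ_acetyltransferase",
    "ploop_ntpase",
    "DUF1858",
    "pqqD",
)


class DataError(ValueError):
    """Raised for malformed or internally inconsistent input data."""


def qualify(genome_id: str, protein_id: str) -> str:
    """Namespace a protein id by its genome (``genome|protein``)."""
    if "|" in protein_id:
        return protein_id
    return f"{genome_id}|{protein_id}"


def normalize_family(label: str) -> str:
    """Map a raw family label onto the tracked vocabulary.

    Known families pass through; anything else becomes ``other:<label>``
    (idempotently, so already-normalized labels survive a round trip).
    """
    if label in KNOWN_FAMILIES or label.startswith("other:"):
        return label
    return f"other:{label}"


@dataclass(frozen=True)
class Orf:
    """A single open reading frame on a replicon.

    ``rank`` is the 0-based position in the replicon's gene order (sorted by
    ``start``); ``start``/``end`` are 1-based inclusive nucleotide
    coordinates.
    """

    locus_tag: str
    replicon_id: str
    rank: int
    start: int
    end: int
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"ORF {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"ORF {self.locus_tag}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Ordered ORFs of one genome, grouped by replicon.

    ``replicons`` maps replicon id to the ORF list sorted by start
    coordinate; ranks are contiguous 0..n-1 within each replicon.
    """

    genome_id: str
    replicons: dict[str, list[Orf]]

    def __post_init__(self) -> None:
        seen_tags: set[str] = set()
        for rid, orfs in self.replicons.items():
            for i, orf in enumerate(orfs):
                if orf.replicon_id != rid:
                    raise DataError(
                        f"ORF {orf.locus_tag} filed under replicon {rid} but "
                        f"claims {orf.replicon_id}"
                    )
                if orf.rank != i:
                    raise DataError(
                        f"replicon {rid}: rank {orf.rank} at position {i}; "
                        "ranks must be contiguous 0..n-1 in start order"
                    )
                if i and orfs[i - 1].start > orf.start:
                    raise DataError(
                        f"replicon {rid}: ORFs not sorted by start coordinate"
                    )
                if orf.locus_tag in seen_tags:
                    raise DataError(f"duplicate locus_tag {orf.locus_tag}")
                seen_tags.add(orf.locus_tag)

    def orfs(self) -> Iterable[Orf]:
        for orfs in self.replicons.values():
            yield from orfs

    def protein_ids(self) -> list[str]:
        return [qualify(self.genome_id, o.protein_id) for o in self.orfs()]

    def find_protein(self, protein_id: str) -> Orf | None:
        """Locate an ORF by (possibly genome-qualified) protein id."""
        bare = protein_id.split("|", 1)[-1]
        for orf in self.orfs():
            if orf.protein_id in (protein_id, bare):
                return orf
        return None


def build_annotation(
    genome_id: str,
    orf_rows: Sequence[tuple[str, str, int, int, str, str]],
) -> GenomeAnnotation:
    """Assemble a :class:`GenomeAnnotation` from unranked ORF tuples.

    Each row is ``(replicon_id, locus_tag, start, end, strand, protein_id)``;
    ranks are assigned here by sorting on start within each replicon, with
    replicons kept in first-appearance order.
    """
    by_replicon: dict[str, list[tuple[str, str, int, int, str, str]]] = {}
    for row in orf_rows:
        by_replicon.setdefault(row[0], []).append(row)
    replicons: dict[str, list[Orf]] = {}
    for rid, rows in by_replicon.items():
        rows = sorted(rows, key=lambda r: (r[2], r[3], r[1]))
        replicons[rid] = [
            Orf(
                locus_tag=tag,
                replicon_id=rid,
                rank=i,
                start=start,
                end=end,
                strand=strand,
                protein_id=pid,
            )
            for i, (_, tag, start, end, strand, pid) in enumerate(rows)
        ]
    return GenomeAnnotation(genome_id=genome_id, replicons=replicons)


@dataclass
class Alignment:
    """A gapped amino-acid multiple alignment with a designated reference.

    Columns are indexed 1-based throughout; all records have equal gapped
    length.
    """

    records: list[tuple[str, str]]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("alignment has no records")
        length = len(self.records[0][1])
        for sid, seq in self.records:
            if len(seq) != length:
                raise DataError(
                    f"alignment record {sid} has length {len(seq)} != {length}"
                )
        if self.reference_id not in self.ids():
            raise DataError(
                f"reference_id {self.reference_id!r} not among records"
            )

    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, sid: str) -> str:
        for rid, seq in self.records:
            if rid == sid:
                return seq
        raise KeyError(sid)

    @property
    def reference(self) -> str:
        return self.sequence(self.reference_id)


@dataclass
class TraitMap:
    """Tip label -> discrete character state, with an ordered state space."""

    states: dict[str, str]
    state_space: tuple[str, ...]

    def __post_init__(self) -> None:
        space = set(self.state_space)
        bad = {s for s in self.states.values() if s not in space}
        if bad:
            raise DataError(f"states outside state_space: {sorted(bad)}")

    @classmethod
    def from_states(cls, states: Mapping[str, str]) -> "TraitMap":
        return cls(dict(states), tuple(sorted(set(states.values()))))

    def is_binary(self) -> bool:
        return set(self.state_space) <= {"0", "1"}
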