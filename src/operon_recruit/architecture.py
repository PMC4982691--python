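"""Core-region truncation, conserved-residue scans, and modular-architecture
classification of DUF59 proteins.

DUF59 proteins fall into modular structures S1–S9: S1 is the bare DUF59
domain; S2, S5, S7 and S9 carry an N-terminal motif (unannotated, U-type FeS
scaffold, Rieske ferredoxin and CysE serine acetyltransferase respectively);
S3, S4, S6 and S8 carry a C-terminal motif (PaaJ/acetyl-CoA
acetyltransferase, P-loop NTPase, DUF1858 and PqqD respectively). Proteins
with qualifying motifs on both flanks are reported as ``composite``;
configurations outside the scheme are ``unclassified``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import Alignment, DataError, GAP

#: motif label -> (architecture class, canonical side)
MOTIF_CLASSES: Mapping[str, tuple[str, str]] = {
    "unknown_N": ("S2", "N"),
    "paaJ_acetyltransferase": ("S3", "C"),
    "ploop_ntpase": ("S4", "C"),
    "U_type_scaffold": ("S5", "N"),
    "DUF1858": ("S6", "C"),
    "rieske_ferredoxin": ("S7", "N"),
    "pqqD": ("S8", "C"),
    "cysE": ("S9", "N"),
}

ARCHITECTURE_LABELS = (
    "S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9",
    "composite", "unclassified",
)


@dataclass(frozen=True)
class CoreRegion:
    """Alignment-column window covering reference positions ref_start..ref_end.

    ``ref_start``/``ref_end`` are 1-based ungapped positions in the
    reference sequence; ``column_start``/``column_end`` are 1-based
    alignment column indices.
    """

    reference_id: str
    ref_start: int
    ref_end: int
    column_start: int
    column_end: int


@dataclass(frozen=True)
class DomainHitRecord:
    """One motif hit in protein coordinates (1-based inclusive)."""

    protein_id: str
    motif: str
    start: int
    end: int
    evalue: float

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    label: str
    n_motif: str | None = None
    c_motif: str | None = None


def map_reference_positions(
    alignment: Alignment, ref_start: int, ref_end: int
) -> CoreRegion:
    """Find the smallest column window holding reference residues
    ``ref_start..ref_end``.

    Walks the gapped reference sequence counting non-gap characters; errors
    if the reference has fewer than ``ref_end`` residues.
    """
    if not 1 <= ref_start <= ref_end:
        raise DataError(f"bad reference range {ref_start}..{ref_end}")
    ref = alignment.reference
    col_start = col_end = None
    pos = 0
    for col, char in enumerate(ref, start=1):
        if char == GAP:
            continue
        pos += 1
        if pos == ref_start:
            col_start = col
        if pos == ref_end:
            col_end = col
            break
    if col_start is None or col_end is None:
        raise DataError(
            f"reference {alignment.reference_id} has only {pos} residues; "
            f"cannot map position {ref_end}"
        )
    return CoreRegion(
        reference_id=alignment.reference_id,
        ref_start=ref_start,
        ref_end=ref_end,
        column_start=col_start,
        column_end=col_end,
    )


def truncate_alignment(alignment: Alignment, region: CoreRegion) -> Alignment:
    """Slice all records to the core-region columns, preserving order.

    Records that become all-gap are retained (the caller can detect them via
    the gap content); widths always equal the window size.
    """
    if region.column_end > alignment.length:
        raise DataError("core region exceeds alignment width")
    lo, hi = region.column_start - 1, region.column_end
    return Alignment(
        records=[(sid, seq[lo:hi]) for sid, seq in alignment.records],
        reference_id=alignment.reference_id,
    )


def conserved_columns(
    alignment: Alignment,
    residue: str,
    min_fraction: float = 1.0,
) -> list[tuple[int, int | None]]:
    """Columns where ``residue`` reaches ``min_fraction`` of non-gap chars.

    Gaps are excluded from the denominator; all-gap columns never qualify.
    Returned as (1-based column, 1-based ungapped reference position or None
    if the reference is gapped at that column).
    """
    if not 0 < min_fraction <= 1:
        raise DataError("min_fraction must lie in (0, 1]")
    ref = alignment.reference
    ref_pos = 0
    out = []
    for col in range(1, alignment.length + 1):
        chars = [seq[col - 1] for _, seq in alignment.records]
        at_ref = ref[col - 1] != GAP
        if at_ref:
            ref_pos += 1
        non_gap = [c for c in chars if c != GAP]
        if not non_gap:
            continue
        if sum(c == residue for c in non_gap) / len(non_gap) >= min_fraction:
            out.append((col, ref_pos if at_ref else None))
    return out


def classify_architecture(
    protein_length: int,
    domain_hits: Sequence[DomainHitRecord],
    min_flank_aa: int = 30,
    cdd_evalue_max: float = 0.01,
) -> ArchitectureCall:
    """Assign a modular-structure label from a protein's domain hits.

    Requires exactly one DUF59 hit. Motif side is decided by the motif
    midpoint relative to the DUF59 span (hits whose midpoint falls inside
    DUF59 are ignored as ambiguous). A long (>= ``min_flank_aa``) N-terminal
    flank with no annotated motif counts as the S2-style unannotated motif;
    a long bare C-terminal flank is unclassified. Qualifying motifs on both
    flanks give ``composite``; a qualifying motif observed on the side
    opposite its canonical class gives ``unclassified``. Hits above
    ``cdd_evalue_max`` are ignored, so sub-threshold hits never change the
    call.
    """
    hits = [h for h in domain_hits if h.evalue <= cdd_evalue_max]
    duf59 = [h for h in hits if h.motif == "DUF59"]
    if len(duf59) != 1:
        pid = domain_hits[0].protein_id if domain_hits else "?"
        raise DataError(
            f"protein {pid}: expected exactly one DUF59 hit, got {len(duf59)}"
        )
    core = duf59[0]
    if not 1 <= core.start <= core.end <= protein_length:
        raise DataError(
            f"protein {core.protein_id}: DUF59 span {core.start}-{core.end} "
            f"outside protein of length {protein_length}"
        )

    n_hits, c_hits = [], []
    for h in hits:
        if h.motif == "DUF59" or h.motif not in MOTIF_CLASSES:
            continue
        if h.midpoint < core.start:
            n_hits.append(h)
        elif h.midpoint > core.end:
            c_hits.append(h)
        # midpoint inside the DUF59 span: side ambiguous, ignored

    def best(side_hits: list[DomainHitRecord]) -> DomainHitRecord | None:
        return min(side_hits, key=lambda h: (h.evalue, h.start)) if side_hits else None

    n_best, c_best = best(n_hits), best(c_hits)
    pid = core.protein_id

    if n_best and c_best:
        return ArchitectureCall(pid, "composite", n_best.motif, c_best.motif)
    if n_best or c_best:
        hit = n_best or c_best
        label, canonical_side = MOTIF_CLASSES[hit.motif]
        observed_side = "N" if hit is n_best else "C"
        if observed_side != canonical_side:
            return ArchitectureCall(
                pid, "unclassified",
                n_motif=hit.motif if observed_side == "N" else None,
                c_motif=hit.motif if observed_side == "C" else None,
            )
        return ArchitectureCall(
            pid, label,
            n_motif=hit.motif if canonical_side == "N" else None,
            c_motif=hit.motif if canonical_side == "C" else None,
        )

    # no annotated flank motif: judge by flank lengths
    n_flank = core.start - 1
    c_flank = protein_length - core.end
    if n_flank < min_flank_aa and c_flank < min_flank_aa:
        return ArchitectureCall(pid, "S1")
    if n_flank >= min_flank_aa:
        return ArchitectureCall(pid, "S2", n_motif="unknown_N")
    return ArchitectureCall(pid, "unclassified")


def architecture_counts(calls: Iterable[ArchitectureCall]) -> dict[str, int]:
    """Label -> count over a collection of calls (zero-count labels omitted)."""
    counts = Counter(c.label for c in calls)
    return {label: counts[label] for label in ARCHITECTURE_LABELS if counts[label]}
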