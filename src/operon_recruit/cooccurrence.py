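"""Genome-wide presence/absence of FeS-cluster marker gene families.

Builds a boolean genome x family presence matrix from homology hit tables
and summarizes the co-occurrence patterns of the Suf machinery: how many
genomes encode the SufBC scaffold, how many of those also carry sufT, how
many carry sufT without sufBC, and how many carry sufT with no known FeS
scaffold (sufB, iscU or nifU) at all — the lactobacilli-style configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .model import DataError, GenomeAnnotation, KNOWN_FAMILIES

REQUIRED_FAMILIES = KNOWN_FAMILIES  # sufB, sufC, sufT, iscU, nifU


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Genome-level co-occurrence counts for the suf marker families.

    ``n_sufBC`` requires both sufB and sufC (the scaffold is treated as a
    unit); ``n_sufT_without_any_scaffold`` counts genomes with sufT but none
    of sufB, iscU or nifU.
    """

    n_total: int
    n_sufBC: int
    n_sufT_given_sufBC: int
    n_sufT_without_sufBC: int
    n_sufT_without_any_scaffold: int

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_sufBC <= self.n_total
            and 0 <= self.n_sufT_given_sufBC <= self.n_sufBC
        ):
            raise DataError(f"inconsistent co-occurrence counts: {self}")


def build_presence_matrix(
    annotations: Iterable[GenomeAnnotation],
    hits: pd.DataFrame,
    families: Sequence[str] = REQUIRED_FAMILIES,
) -> pd.DataFrame:
    """Boolean genome x family matrix from retained homology hits.

    A family is present in a genome iff at least one retained hit maps to a
    protein annotated in that genome (any replicon). Hits whose protein id
    cannot be resolved to an input genome raise an error listing the
    orphans.
    """
    annotations = list(annotations)
    protein_to_genome: dict[str, str] = {}
    for ann in annotations:
        for pid in ann.protein_ids():
            protein_to_genome[pid] = ann.genome_id

    genome_ids = [ann.genome_id for ann in annotations]
    columns = list(dict.fromkeys(list(families) + sorted(hits["family"].unique())))
    matrix = pd.DataFrame(False, index=genome_ids, columns=columns, dtype=bool)
    matrix.index.name = "genome_id"

    orphans = []
    for row in hits.itertuples():
        genome = protein_to_genome.get(row.protein_id)
        if genome is None:
            orphans.append(row.protein_id)
            continue
        matrix.loc[genome, row.family] = True
    if orphans:
        raise DataError(
            "hits reference proteins absent from all annotations: "
            + ", ".join(sorted(set(orphans))[:10])
        )
    return matrix


def summarize_cooccurrence(matrix: pd.DataFrame) -> CooccurrenceSummary:
    """Compute the co-occurrence counts from a presence matrix."""
    missing = set(REQUIRED_FAMILIES) - set(matrix.columns)
    if missing:
        raise DataError(f"presence matrix missing columns {sorted(missing)}")
    sufBC = matrix["sufB"] & matrix["sufC"]
    sufT = matrix["sufT"]
    no_scaffold = ~(matrix["sufB"] | matrix["iscU"] | matrix["nifU"])
    return CooccurrenceSummary(
        n_total=len(matrix),
        n_sufBC=int(sufBC.sum()),
        n_sufT_given_sufBC=int((sufT & sufBC).sum()),
        n_sufT_without_sufBC=int((sufT & ~sufBC).sum()),
        n_sufT_without_any_scaffold=int((sufT & no_scaffold).sum()),
    )


def percentage(numerator: int, denominator: int) -> float:
    """Percent to one decimal place, round-half-even.

    e.g. ``percentage(1092, 1669) == 65.4``.
    """
    if denominator <= 0:
        raise DataError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise DataError("numerator must lie in [0, denominator]")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def summary_frame(summary: CooccurrenceSummary) -> pd.DataFrame:
    """Tabular form of a summary with the derived percentages."""
    rows = [
        ("n_total", summary.n_total, ""),
        ("n_sufBC", summary.n_sufBC,
         percentage(summary.n_sufBC, summary.n_total)
         if summary.n_total else ""),
        ("n_sufT_given_sufBC", summary.n_sufT_given_sufBC,
         percentage(summary.n_sufT_given_sufBC, summary.n_sufBC)
         if summary.n_sufBC else ""),
        ("n_sufT_without_sufBC", summary.n_sufT_without_sufBC, ""),
        ("n_sufT_without_any_scaffold", summary.n_sufT_without_any_scaffold, ""),
    ]
    return pd.DataFrame(rows, columns=["quantity", "count", "percent"])
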