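"""Readers and writers for all pipeline inputs and outputs.

Formats handled: GFF3 or plain TSV genome annotations, TSV gene-family and
domain hit tables, aligned FASTA, newick trees (via dendropy) and TSV trait
maps. Every reader has a writer such that ``write(read(x))`` parses back to
an equal object, and identical inputs always serialize byte-identically.
"""

from __future__ import annotations

import os
from pathlib import Path

import dendropy
import gffutils
import pandas as pd
from Bio import AlignIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Alignment,
    DataError,
    GenomeAnnotation,
    TraitMap,
    build_annotation,
    normalize_family,
)

ANNOTATION_TSV_COLUMNS = [
    "replicon_id",
    "locus_tag",
    "start",
    "end",
    "strand",
    "protein_id",
]

FAMILY_HIT_COLUMNS = ["protein_id", "family", "evalue", "score"]
DOMAIN_HIT_COLUMNS = ["protein_id", "motif", "start", "end", "evalue"]


# ---------------------------------------------------------------------------
# genome annotations
# ---------------------------------------------------------------------------

def _gff3_attribute(feature: gffutils.Feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def _prevalidate_gff3(path: str | Path) -> None:
    """Scan a GFF3 file for malformed coordinates, reporting line numbers.

    gffutils does not retain line numbers, so coordinate sanity is checked
    here first and errors name the offending line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise DataError(f"{path}:{lineno}: expected 9 GFF3 columns")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise DataError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start > end:
                raise DataError(
                    f"{path}:{lineno}: start {start} > end {end}"
                )


def read_annotation(
    path: str | Path,
    dialect: str = "gff3",
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Read a genome annotation from GFF3 or TSV into ranked ORF lists.

    Only CDS (or, if absent, gene) features are used from GFF3. Ranks are
    assigned by start coordinate within each replicon, so the result is
    deterministic regardless of feature order in the file.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    if dialect == "gff3":
        _prevalidate_gff3(path)
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        featuretypes = set(db.featuretypes())
        ftype = "CDS" if "CDS" in featuretypes else "gene"
        rows = []
        for feat in db.features_of_type(ftype):
            tag = _gff3_attribute(feat, "locus_tag", "ID") or feat.id
            pid = _gff3_attribute(feat, "protein_id", "ID") or tag
            rows.append((feat.seqid, tag, feat.start, feat.end, feat.strand, pid))
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(ANNOTATION_TSV_COLUMNS) - set(df.columns)
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        rows = [
            (r.replicon_id, r.locus_tag, int(r.start), int(r.end), r.strand,
             r.protein_id)
            for r in df.itertuples()
        ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return build_annotation(genome_id, rows)


def write_annotation_tsv(annotation: GenomeAnnotation, path: str | Path) -> None:
    rows = [
        {
            "replicon_id": o.replicon_id,
            "locus_tag": o.locus_tag,
            "start": o.start,
            "end": o.end,
            "strand": o.strand,
            "protein_id": o.protein_id,
        }
        for o in annotation.orfs()
    ]
    pd.DataFrame(rows, columns=ANNOTATION_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_annotation_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in annotation.orfs():
            attrs = (
                f"ID={orf.locus_tag};locus_tag={orf.locus_tag};"
                f"protein_id={orf.protein_id}"
            )
            fh.write(
                "\t".join(
                    [
                        orf.replicon_id,
                        "operon_recruit",
                        "CDS",
                        str(orf.start),
                        str(orf.end),
                        ".",
                        orf.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def read_family_hits(path: str | Path, evalue_max: float = 1e-5) -> pd.DataFrame:
    """Read a protein -> gene-family hit table, filter, and deduplicate.

    Rows with e-value above ``evalue_max`` are dropped; of multiple hits for
    the same (protein, family) pair only the lowest-e-value one is kept.
    Family labels outside the tracked vocabulary are retained as
    ``other:<label>``.
    """
    df = pd.read_csv(
        path, sep="\t",
        dtype={"protein_id": str, "family": str, "evalue": float, "score": float},
    )
    missing = set(FAMILY_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if len(df) and (df["evalue"] < 0).any():
        bad = df.loc[df["evalue"] < 0, "protein_id"].iloc[0]
        raise DataError(f"{path}: negative evalue for protein {bad}")
    df["family"] = df["family"].map(normalize_family)
    df = df[df["evalue"] <= evalue_max]
    df = (
        df.sort_values(["protein_id", "family", "evalue", "score"])
        .drop_duplicates(["protein_id", "family"], keep="first")
        .reset_index(drop=True)
    )
    return df[FAMILY_HIT_COLUMNS]


def write_family_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits[FAMILY_HIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_domain_hits(path: str | Path, evalue_max: float = 0.01) -> pd.DataFrame:
    """Read a per-protein motif hit table (CDD-style, protein coordinates).

    Hits are retained only at e-value <= ``evalue_max`` (default 0.01, the
    conventional CDD screening threshold used for these motif calls).
    """
    df = pd.read_csv(
        path, sep="\t",
        dtype={"protein_id": str, "motif": str, "start": int, "end": int,
               "evalue": float},
    )
    missing = set(DOMAIN_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if len(df):
        if (df["evalue"] < 0).any():
            raise DataError(f"{path}: negative evalue")
        bad = df[(df["start"] < 1) | (df["start"] > df["end"])]
        if len(bad):
            raise DataError(
                f"{path}: bad protein coordinates for "
                f"{bad['protein_id'].iloc[0]}"
            )
    df = df[df["evalue"] <= evalue_max].reset_index(drop=True)
    return df[DOMAIN_HIT_COLUMNS]


def write_domain_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits[DOMAIN_HIT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, reference_id: str | None = None) -> Alignment:
    """Read an aligned FASTA; the reference defaults to the first record."""
    msa = AlignIO.read(str(path), "fasta")
    records = [(rec.id, str(rec.seq)) for rec in msa]
    if reference_id is None:
        reference_id = records[0][0]
    return Alignment(records=records, reference_id=reference_id)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in alignment.records
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a newick tree; accepts a path or a newick string.

    A tree whose root has exactly two children is flagged rooted; a basal
    trifurcation (or higher polytomy) is flagged unrooted. Parse errors
    carry the position reported by the newick parser.
    """
    if isinstance(source, str) and not os.path.exists(source) and "(" in source:
        kwargs = {"data": source, "schema": "newick"}
    else:
        kwargs = {"path": str(source), "schema": "newick"}
    try:
        tree = dendropy.Tree.get(
            suppress_internal_node_taxa=True, preserve_underscores=True, **kwargs
        )
    except Exception as exc:  # dendropy raises several error classes
        raise DataError(f"newick parse error: {exc}") from exc
    tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise DataError("duplicate tip labels in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree to newick; writes to ``path`` if given."""
    newick = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(newick)
    return newick


# ---------------------------------------------------------------------------
# trait maps
# ---------------------------------------------------------------------------

def read_trait_map(path: str | Path) -> TraitMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"tip_label", "state"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    states = dict(zip(df["tip_label"], df["state"]))
    if len(states) != len(df):
        raise DataError(f"{path}: duplicate tip labels")
    return TraitMap.from_states(states)


def write_trait_map(traits: TraitMap, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(traits.states.items()), columns=["tip_label", "state"]
    )
    df.to_csv(path, sep="\t", index=False)
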