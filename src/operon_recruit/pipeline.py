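"""End-to-end pipeline orchestration and combined reporting.

Runs the toggled stages — co-occurrence screen, operon association,
architecture classification, trait/parsimony analysis — on a directory of
input files, writing per-stage TSVs plus a combined human-readable report
and its machine-readable JSON twin (every number in the text report is also
in the JSON). Reruns with identical inputs and config produce byte-identical
machine-readable output.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import architecture as arch_mod
from . import cooccurrence as cooc_mod
from . import io as io_mod
from . import neighborhood as nbh_mod
from . import trait_phylo
from .model import DataError, TraitMap
from .simulate import domain_records

logger = logging.getLogger("operon_recruit")


def _setup_logging() -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """Paths, stage toggles and thresholds for a pipeline run.

    Thresholds default to the screening constants the pipeline is built
    around: association within 4 ORFs, CDD-style motif hits at e-value 0.01,
    core reference range 1–99.
    """

    out_dir: str = "results"
    annotations_dir: str | None = None
    family_hits: str | None = None
    domain_hits: str | None = None
    protein_lengths: str | None = None
    alignment: str | None = None
    tree: str | None = None
    traits: str | None = None
    run_cooccur: bool = True
    run_assoc: bool = True
    run_arch: bool = True
    run_trait: bool = True
    evalue_max: float = 1e-5
    cdd_evalue_max: float = 0.01
    max_orf_distance: int = 4
    gap_max_bp: int = 150
    min_flank_aa: int = 30
    ref_start: int = 1
    ref_end: int = 99
    conserved_residue: str = "C"
    n_perm: int = 999
    resolution: str = "ACCTRAN"
    root_state: str = "MP"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("evalue_max", "cdd_evalue_max", "max_orf_distance",
                     "gap_max_bp", "min_flank_aa", "ref_start", "ref_end",
                     "n_perm"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")


def _load_annotations(directory: str):
    paths = sorted(Path(directory).glob("*.gff3")) + sorted(
        Path(directory).glob("*.tsv")
    )
    return [
        io_mod.read_annotation(
            p, dialect="gff3" if p.suffix == ".gff3" else "tsv"
        )
        for p in paths
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages; returns the machine-readable report dict.

    Writes per-stage TSVs, ``report.json`` and ``report.txt`` under
    ``config.out_dir``. Raises on stage errors after logging the stage name;
    partial outputs written so far are preserved.
    """
    _setup_logging()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        k: v for k, v in vars(config).items() if not k.startswith("_")
    }}
    lines: list[str] = ["operon-recruit pipeline report", ""]

    annotations = None
    hits = None
    if config.run_cooccur or config.run_assoc:
        stage = "load"
        try:
            if config.annotations_dir is None or config.family_hits is None:
                raise DataError(
                    "annotations_dir and family_hits are required for the "
                    "cooccur/assoc stages"
                )
            annotations = _load_annotations(config.annotations_dir)
            hits = io_mod.read_family_hits(
                config.family_hits, evalue_max=config.evalue_max
            )
            logger.info(
                "%s: %d genomes, %d retained family hits",
                stage, len(annotations), len(hits),
            )
        except Exception:
            logger.error("stage %s failed", stage)
            raise

    if config.run_cooccur:
        stage = "cooccur"
        try:
            matrix = cooc_mod.build_presence_matrix(annotations, hits)
            summary = cooc_mod.summarize_cooccurrence(matrix)
            matrix.astype(int).to_csv(out / "presence_matrix.tsv", sep="\t")
            cooc_mod.summary_frame(summary).to_csv(
                out / "cooccurrence_summary.tsv", sep="\t", index=False
            )
            report["cooccurrence"] = {
                "n_total": summary.n_total,
                "n_sufBC": summary.n_sufBC,
                "pct_sufBC": cooc_mod.percentage(
                    summary.n_sufBC, summary.n_total
                ) if summary.n_total else None,
                "n_sufT_given_sufBC": summary.n_sufT_given_sufBC,
                "pct_sufT_given_sufBC": cooc_mod.percentage(
                    summary.n_sufT_given_sufBC, summary.n_sufBC
                ) if summary.n_sufBC else None,
                "n_sufT_without_sufBC": summary.n_sufT_without_sufBC,
                "n_sufT_without_any_scaffold":
                    summary.n_sufT_without_any_scaffold,
            }
            c = report["cooccurrence"]
            lines += [
                "Co-occurrence screen:",
                f"  genomes screened: {c['n_total']}",
                f"  with sufBC: {c['n_sufBC']} ({c['pct_sufBC']}%)",
                f"  with sufT among sufBC genomes: {c['n_sufT_given_sufBC']}"
                f" ({c['pct_sufT_given_sufBC']}%)",
                f"  sufT without sufBC: {c['n_sufT_without_sufBC']}",
                "  sufT without any scaffold (sufB/iscU/nifU): "
                f"{c['n_sufT_without_any_scaffold']}",
                "",
            ]
            logger.info("cooccur: done")
        except Exception:
            logger.error("stage %s failed", stage)
            raise

    if config.run_assoc:
        stage = "assoc"
        try:
            contexts = []
            for ann in annotations:
                contexts.extend(
                    nbh_mod.classify_association(
                        ann, hits,
                        max_orf_distance=config.max_orf_distance,
                        gap_max_bp=config.gap_max_bp,
                    )
                )
            part = nbh_mod.partition(contexts)
            nbh_mod.contexts_frame(contexts).to_csv(
                out / "association_contexts.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                [
                    {"quantity": "n_associated", "count": part.n_associated},
                    {"quantity": "n_non_associated",
                     "count": part.n_non_associated},
                    {"quantity": "n_total", "count": part.n_total},
                ]
            ).to_csv(out / "association_partition.tsv", sep="\t", index=False)
            if contexts:
                assoc_traits = TraitMap(
                    states={
                        c.sufT_protein_id: "1" if c.associated else "0"
                        for c in contexts
                    },
                    state_space=("0", "1"),
                )
                trait_phylo.export_colorstrip(
                    assoc_traits, out / "itol_association.txt",
                    dataset_label="suf operon association",
                )
            report["association"] = {
                "n_associated": part.n_associated,
                "n_non_associated": part.n_non_associated,
                "n_homologs": part.n_total,
            }
            lines += [
                "Operon association of sufT homologs:",
                f"  associated: {part.n_associated}",
                f"  non-associated: {part.n_non_associated}",
                f"  total homologs: {part.n_total}",
                "",
            ]
            logger.info("assoc: done")
        except Exception:
            logger.error("stage %s failed", stage)
            raise

    if config.run_arch and config.domain_hits is not None:
        stage = "arch"
        try:
            dom = io_mod.read_domain_hits(
                config.domain_hits, evalue_max=config.cdd_evalue_max
            )
            if config.protein_lengths is None:
                raise DataError("arch stage requires protein_lengths TSV")
            lengths = pd.read_csv(config.protein_lengths, sep="\t")
            calls = []
            for row in lengths.itertuples():
                calls.append(
                    arch_mod.classify_architecture(
                        int(row.length),
                        domain_records(dom, row.protein_id),
                        min_flank_aa=config.min_flank_aa,
                        cdd_evalue_max=config.cdd_evalue_max,
                    )
                )
            counts = arch_mod.architecture_counts(calls)
            pd.DataFrame(
                [
                    {"protein_id": c.protein_id, "label": c.label,
                     "n_motif": c.n_motif or "", "c_motif": c.c_motif or ""}
                    for c in calls
                ]
            ).to_csv(out / "architecture_calls.tsv", sep="\t", index=False)
            pd.DataFrame(
                sorted(counts.items()), columns=["label", "count"]
            ).to_csv(out / "architecture_counts.tsv", sep="\t", index=False)
            arch_traits = TraitMap.from_states(
                {c.protein_id: c.label for c in calls}
            )
            trait_phylo.export_colorstrip(
                arch_traits, out / "itol_architecture.txt",
                dataset_label="DUF59 modular structure",
            )
            report["architecture"] = {
                "counts": counts,
                "n_proteins": len(calls),
                "n_non_S1": sum(
                    v for k, v in counts.items() if k != "S1"
                ),
            }
            lines += ["DUF59 modular structures:"]
            lines += [f"  {k}: {v}" for k, v in sorted(counts.items())]
            lines += [
                f"  non-S1 total: {report['architecture']['n_non_S1']}", ""
            ]
            if config.alignment:
                aln = io_mod.read_alignment(config.alignment)
                region = arch_mod.map_reference_positions(
                    aln, config.ref_start, config.ref_end
                )
                core = arch_mod.truncate_alignment(aln, region)
                io_mod.write_alignment(core, out / "core_alignment.fasta")
                cons = arch_mod.conserved_columns(
                    core, config.conserved_residue
                )
                pd.DataFrame(
                    cons, columns=["column", "reference_position"]
                ).to_csv(out / "conserved_columns.tsv", sep="\t", index=False)
                report["architecture"]["n_conserved_columns"] = len(cons)
                lines += [
                    f"  strictly conserved '{config.conserved_residue}' "
                    f"columns in core: {len(cons)}",
                    "",
                ]
            logger.info("arch: done")
        except Exception:
            logger.error("stage %s failed", stage)
            raise

    if config.run_trait:
        stage = "trait"
        try:
            if config.tree is None or config.traits is None:
                raise DataError("trait stage requires tree and traits paths")
            tree = io_mod.read_tree(config.tree)
            traits = io_mod.read_trait_map(config.traits)
            result = trait_phylo.fitch_score(tree, traits)
            rows = [
                {"quantity": "fitch_score", "value": result.score},
            ]
            report["trait"] = {"fitch_score": result.score}
            if traits.is_binary():
                ev = trait_phylo.count_events(
                    tree, traits,
                    resolution=config.resolution,
                    root_state=config.root_state,
                )
                rows += [
                    {"quantity": "n_gains", "value": ev.n_gains},
                    {"quantity": "n_losses", "value": ev.n_losses},
                ]
                report["trait"].update(
                    n_gains=ev.n_gains, n_losses=ev.n_losses,
                    resolution=config.resolution,
                )
            test = trait_phylo.clustering_permutation_test(
                tree, traits, n_perm=config.n_perm, seed=config.seed
            )
            pd.DataFrame(
                {"null_score": list(test.null_scores)}
            ).to_csv(out / "null_distribution.tsv", sep="\t", index=False)
            rows.append({"quantity": "clustering_p", "value": test.p_value})
            pd.DataFrame(rows).to_csv(
                out / "parsimony.tsv", sep="\t", index=False
            )
            trait_phylo.overlay_export(
                tree, traits, out / "itol_trait.txt"
            )
            report["trait"].update(
                clustering_p=test.p_value, n_perm=test.n_perm,
            )
            lines += [
                "Trait evolution on tree:",
                f"  parsimony score: {result.score}",
            ]
            if traits.is_binary():
                lines += [
                    f"  gains/losses ({config.resolution}): "
                    f"{report['trait']['n_gains']}/"
                    f"{report['trait']['n_losses']}",
                ]
            lines += [
                f"  clustering p-value ({test.n_perm} permutations): "
                f"{test.p_value:.6g}",
                "",
            ]
            logger.info("trait: done")
        except Exception:
            logger.error("stage %s failed", stage)
            raise

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", out)
    return report
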