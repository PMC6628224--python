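"""End-to-end pipeline: concatenate loci, collapse haplotypes, summarise
polymorphism, infer (or accept) the two-clade partition, test the 10x rule,
tally geography, and design PCR-RFLP assays — emitting a reproducible report
bundle.

All stochastic steps (bootstrap) take their seed from the config; two runs
with the same config and inputs produce byte-identical reports (no
timestamps are written).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from . import __version__
from .alignment_io import (
    Alignment,
    SampleTable,
    concatenate_loci,
    read_fasta,
    read_metadata,
)
from .clade_inference import assign_clades, split_bootstrap
from .diversity_stats import (
    clade_divergence,
    collapse_haplotypes,
    diversity_summary,
    divergence_report,
    ten_x_rule,
)
from .geography import syntopy_rate, tally_by_site, write_summary_json
from .rflp_design import (
    GelParams,
    PrimerPair,
    assay_report_json,
    design_assays,
    expected_fragment_table,
    load_enzyme_table,
    packaged_enzymes,
    read_primer_pair,
)

__all__ = ["PipelineConfig", "ReportBundle", "StageError", "run_full_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs.  ``seed`` is mandatory (bootstrap)."""

    fasta_paths: tuple[str, ...]
    outdir: str
    seed: int
    metadata_path: str | None = None
    labels_path: str | None = None  # CSV individual_id,clade; overrides inference
    metric: Literal["p", "k2p"] = "p"
    collapse_policy: Literal["strict", "compatibility"] = "compatibility"
    bootstrap_replicates: int = 1000
    enzyme_path: str | None = None  # default: packaged TaqI/BsaI/DdeI table
    primer_path: str | None = None  # skip assay design when absent
    gel: GelParams = field(default_factory=GelParams)
    pair_search: bool = True
    dataset_name: str = "dataset"


@dataclass
class ReportBundle:
    """In-memory results plus the paths of everything written."""

    alignment: Alignment
    haplotypes: dict[str, list[str]]
    labels: dict[str, str]
    diversity: pd.DataFrame
    ten_x: bool
    bootstrap_support: float
    tree_newick: str
    tally: object | None
    syntopy: object | None
    assays: list | None
    paths: dict[str, Path]
    log_lines: list[str]


def _load_labels_csv(path: str) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if not {"individual_id", "clade"} <= set(df.columns):
        raise ValueError("labels CSV needs columns individual_id,clade")
    return dict(zip(df.individual_id, df.clade))


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and write the report bundle into ``config.outdir``.

    Stage order: concatenate -> collapse -> diversity -> clades (user labels
    override inference) -> divergence/10x -> tallies/syntopy (skipped with a
    warning when metadata is absent) -> RFLP design (skipped when no primer
    file is given).  Errors propagate as :class:`StageError` with the stage
    name; outputs written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"passalus {__version__}",
        f"seed {config.seed}",
        f"metric {config.metric}; collapse {config.collapse_policy}; "
        f"bootstrap B={config.bootstrap_replicates}",
        f"gel min_visible_bp={config.gel.min_visible_bp} "
        f"min_separation_pct={config.gel.min_separation_pct}",
        "pad char 'N'; pairwise deletion; ambiguity codes undetermined; "
        "P statistics over individuals; 10x threshold inclusive",
    ]
    paths: dict[str, Path] = {}

    def stage(name: str):
        log.append(f"stage {name}")

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log.append(f"stage {name} FAILED: {exc}")
                    _write_log(outdir, log, paths)
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("read"):
        parts = [read_fasta(p) for p in config.fasta_paths]
        aln = concatenate_loci(parts) if len(parts) > 1 else parts[0]
        log.append(
            f"alignment: {aln.n_sequences} sequences x {aln.length} bp "
            f"({len(parts)} locus/loci)"
        )

    with stage("collapse"):
        haplotypes = collapse_haplotypes(aln, config.collapse_policy)
        log.append(f"haplotypes: {len(haplotypes)} non-redundant ({config.collapse_policy})")

    with stage("clades"):
        if config.labels_path:
            labels = _load_labels_csv(config.labels_path)
            log.append("clade labels: user-supplied (inference skipped)")
            _, tree = assign_clades(aln, config.metric)
        else:
            labels, tree = assign_clades(aln, config.metric)
            log.append("clade labels: inferred from NJ + midpoint basal split")
        support = split_bootstrap(
            aln, config.metric, config.bootstrap_replicates, seed=config.seed
        )
        sup = "NA" if math.isnan(support) else f"{support:.3f}"
        log.append(f"basal split bootstrap support: {sup} (B={config.bootstrap_replicates})")
        for child in tree.children:
            child.name = None if math.isnan(support) else f"{support:.3f}"
        newick = str(tree)
        paths["tree"] = outdir / "tree.nwk"
        paths["tree"].write_text(newick if newick.endswith("\n") else newick + "\n")
        paths["clades"] = outdir / "clades.csv"
        pd.DataFrame(
            {"individual_id": list(labels), "clade": [labels[i] for i in labels]}
        ).to_csv(paths["clades"], index=False)

    with stage("diversity"):
        report = divergence_report({config.dataset_name: (aln, labels)}, metric=config.metric)
        cd = clade_divergence(aln, labels, metric=config.metric)
        flag = ten_x_rule(cd)
        log.append(
            f"P_between={cd.p_between:.4f} P_within_mean={cd.p_within_mean:.4f} "
            f"ratio={cd.ratio:.2f} 10x_flag={flag}"
        )
        paths["diversity"] = outdir / "diversity.tsv"
        report.to_csv(paths["diversity"], sep="\t")

    tally = syntopy = None
    if config.metadata_path:
        with stage("geography"):
            table = read_metadata(config.metadata_path)
            if table.df.clade.isna().any():
                table = table.with_labels(labels)
            tally = tally_by_site(table)
            paths["tally"] = outdir / "tally.csv"
            tally.to_frame().to_csv(paths["tally"], index=False)
            try:
                syntopy = syntopy_rate(table)
            except Exception as e:  # per-log data genuinely optional
                log.append(f"syntopy skipped: {e}")
                syntopy = None
            paths["summary"] = outdir / "summary.json"
            write_summary_json(tally, syntopy, paths["summary"])
    else:
        log.append("geography skipped: no metadata provided")

    assays = None
    if config.primer_path:
        with stage("rflp_design"):
            primers = read_primer_pair(config.primer_path)
            enzymes = (
                load_enzyme_table(config.enzyme_path)
                if config.enzyme_path
                else packaged_enzymes()
            )
            assays = design_assays(
                aln, labels, enzymes, primers, gel=config.gel, pair_search=config.pair_search
            )
            log.append(f"diagnostic assays found: {len(assays)}")
            if assays:
                paths["assays"] = outdir / "assays.tsv"
                expected_fragment_table(assays).to_csv(paths["assays"], sep="\t")
                paths["assays_json"] = outdir / "assays.json"
                assay_report_json(assays, paths["assays_json"])
    else:
        log.append("rflp design skipped: no primer file provided")

    _write_log(outdir, log, paths)
    cdiv = clade_divergence(aln, labels, metric=config.metric)
    return ReportBundle(
        alignment=aln,
        haplotypes=haplotypes,
        labels=labels,
        diversity=report,
        ten_x=ten_x_rule(cdiv),
        bootstrap_support=support,
        tree_newick=newick,
        tally=tally,
        syntopy=syntopy,
        assays=assays,
        paths=paths,
        log_lines=log,
    )


def _write_log(outdir: Path, log: list[str], paths: dict[str, Path]) -> None:
    p = outdir / "run.log"
    p.write_text("\n".join(log) + "\n")
    paths["log"] = p
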