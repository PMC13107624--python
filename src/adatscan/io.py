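"""Readers, writers, pipeline configuration and the end-to-end run.

All writers are deterministic: fixed column order, tab separator, ``.``
decimal, ``%.6g`` floats, LF line endings.  TSV files may start with ``#``
comment lines (the simulator writes the seed there); readers skip them.
Pileup coordinates are 1-based Sprinzl positions as provided upstream; codon
indices in recode reports are 0-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .codon_analysis import (
    BiasScore,
    CodingSequence,
    aggregate_usage,
    bias_score,
    build_adat_codon_model,
)
from .errors import AdatScanError, SchemaError, SequenceError
from .funnel import FunnelConfig, FunnelResult, funnel_report, run_funnel
from .inosine import (
    PILEUP_COLUMNS,
    TrnaPileup,
    estimate_inosine,
    estimates_to_frame,
    inosine_fold_change,
)
from .simulate import SimBundle, SimTruth
from .translation import (
    CONDITIONS,
    ExpressionMatrix,
    frame_to_records,
    records_to_frame,
    translation_efficiency,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# FASTA

def read_cds_fasta(path) -> tuple[list[CodingSequence], list[tuple[str, str]]]:
    """Read a multi-record CDS FASTA.

    The first whitespace token of each description is the gene_id; U is mapped
    to T.  Records violating the CDS invariants are rejected individually and
    returned as (gene_id, reason) pairs rather than aborting the whole file.

    Raises
    ------
    SchemaError
        If the file contains no records at all.
    """
    records: list[CodingSequence] = []
    rejected: list[tuple[str, str]] = []
    n_seen = 0
    # fasta-pearson also accepts leading ';' comment lines (the simulator
    # writes its seed there)
    for rec in SeqIO.parse(str(path), "fasta-pearson"):
        n_seen += 1
        try:
            records.append(CodingSequence(rec.id, str(rec.seq)))
        except SequenceError as exc:
            rejected.append((rec.id, str(exc)))
            logger.warning("read_cds_fasta: rejected %s (%s)", rec.id, exc)
    if n_seen == 0:
        raise SchemaError(f"no FASTA records in {path}")
    return records, rejected


def write_cds_fasta(records: Iterable[CodingSequence], path, comment: Optional[str] = None) -> None:
    with open(path, "w", newline="\n") as fh:
        if comment:
            fh.write(f";{comment}\n")
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# TSV tables

def write_tsv(df: pd.DataFrame, path, comment: Optional[str] = None) -> None:
    """Deterministic TSV writer (LF endings, %.6g floats, no index)."""
    with open(path, "w", newline="\n") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_counts_tsv(path) -> pd.DataFrame:
    """Counts table: first column gene_id, one column per sample."""
    df = _read_table(path)
    if df.columns[0] != "gene_id":
        raise SchemaError(f"{path}: first column must be gene_id, got {df.columns[0]!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    return df.set_index("gene_id")


def read_design_tsv(path) -> pd.DataFrame:
    """Design table: sample_id, assay, condition, replicate."""
    df = _read_table(path)
    missing = {"sample_id", "assay", "condition", "replicate"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: design missing columns {sorted(missing)}")
    unknown = set(df["condition"]) - set(CONDITIONS)
    if unknown:
        raise SchemaError(
            f"{path}: unknown condition labels {sorted(unknown)}; allowed: {list(CONDITIONS)}"
        )
    return df


def build_expression_matrix(counts: pd.DataFrame, design: pd.DataFrame, assay: str) -> ExpressionMatrix:
    """Assemble one assay's ExpressionMatrix from counts + design tables."""
    sel = design[design["assay"] == assay].reset_index(drop=True)
    if sel.empty:
        raise SchemaError(f"design has no samples for assay {assay!r}")
    cols = [s for s in sel["sample_id"] if s in counts.columns]
    if len(cols) != len(sel):
        missing = sorted(set(sel["sample_id"]) - set(counts.columns))
        raise SchemaError(f"counts table missing design samples {missing}")
    return ExpressionMatrix(assay=assay, counts=counts[cols], design=sel[["sample_id", "condition", "replicate"]])


def read_pileup_tsv(path) -> list[TrnaPileup]:
    """Pileup table: family_id, sprinzl_pos, ref_base, count_A..count_T."""
    df = _read_table(path)
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: pileup missing columns {sorted(missing)}")
    out = []
    for fam, sub in df.groupby("family_id", sort=True):
        out.append(TrnaPileup(str(fam), sub.drop(columns=["family_id"]).reset_index(drop=True)))
    return out


def write_pileups(pileups: list[TrnaPileup], path, comment: Optional[str] = None) -> None:
    frames = []
    for p in pileups:
        t = p.table.copy()
        t.insert(0, "family_id", p.family_id)
        frames.append(t)
    write_tsv(pd.concat(frames, ignore_index=True)[list(PILEUP_COLUMNS)], path, comment)


def read_tumor_tsv(path) -> pd.DataFrame:
    df = _read_table(path)
    if "gene_id" not in df.columns:
        raise SchemaError(f"{path}: tumor table must have a gene_id column")
    return df


def bias_scores_to_frame(scores: list[BiasScore], threshold: float = 1.5) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": b.gene_id,
                "dep_usage_gene": b.dep_usage_gene,
                "dep_usage_background": b.dep_usage_background,
                "fold_enrichment": b.fold_enrichment,
                "pass_1p5": b.passes(threshold),
            }
            for b in scores
        ]
    )


def frame_to_bias_scores(df: pd.DataFrame) -> list[BiasScore]:
    needed = {"gene_id", "dep_usage_gene", "dep_usage_background", "fold_enrichment"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"bias table missing columns {sorted(missing)}")
    return [
        BiasScore(
            gene_id=str(r.gene_id),
            dep_usage_gene=float(r.dep_usage_gene),
            dep_usage_background=float(r.dep_usage_background),
            fold_enrichment=float(r.fold_enrichment),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# simulated bundles

def write_bundle(bundle: SimBundle, out_dir) -> None:
    """Write a SimBundle to disk (cds.fa, rna/ribo/design TSVs, per-condition
    pileups, tumor table, truth.json).  Every file carries the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_note = f"adatscan simulation seed={bundle.truth.seed}"
    write_cds_fasta(bundle.cds, out / "cds.fa", comment=seed_note)

    rna = bundle.rna.counts.reset_index()
    ribo = bundle.ribo.counts.reset_index()
    write_tsv(rna, out / "rna.tsv", seed_note)
    write_tsv(ribo, out / "ribo.tsv", seed_note)
    design = pd.concat(
        [bundle.rna.design.assign(assay="rna"), bundle.ribo.design.assign(assay="ribo")],
        ignore_index=True,
    )[["sample_id", "assay", "condition", "replicate"]]
    write_tsv(design, out / "design.tsv", seed_note)
    for cond, pileups in bundle.pileups.items():
        write_pileups(pileups, out / f"pileup_{cond}.tsv", seed_note)
    write_tsv(bundle.tumor, out / "tumor.tsv", seed_note)
    (out / "truth.json").write_text(truth_to_json(bundle.truth), newline="\n")


def truth_to_json(truth: SimTruth) -> str:
    d = dataclasses.asdict(truth)
    d["i_fraction_by_family_condition"] = {
        f"{fam}|{cond}": v
        for (fam, cond), v in sorted(truth.i_fraction_by_family_condition.items())
    }
    d["subset_families"] = list(truth.subset_families)
    return json.dumps(d, indent=2, sort_keys=True) + "\n"


def truth_from_json(text: str) -> SimTruth:
    d = json.loads(text)
    d["i_fraction_by_family_condition"] = {
        tuple(k.split("|")): v for k, v in d["i_fraction_by_family_condition"].items()
    }
    d["subset_families"] = tuple(d["subset_families"])
    return SimTruth(**d)


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration

@dataclass
class PipelineConfig:
    """Paths and settings for an end-to-end run."""

    cds_fasta: str
    rna_counts: str
    ribo_counts: str
    design: str
    out_dir: str
    pileup_case: Optional[str] = None
    pileup_control: Optional[str] = None
    tumor_table: Optional[str] = None
    bias_threshold: float = 1.5
    codon_subset: tuple[str, ...] = ("TCC", "CTC", "CGC")
    min_coverage: int = 100
    inosine_pseudocount: float = 0.01
    te_pseudocount: float = 0.5
    min_abs_log2fc: float = 0.0
    overexpression_alpha: float = 0.05
    ranking_key: str = "fold_enrichment"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "codon_subset" in data:
            data["codon_subset"] = tuple(data["codon_subset"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def run_all(cfg: PipelineConfig) -> FunnelResult:
    """Execute the full screen: inosine quantification (if pileups are given),
    TE + concordance, codon-bias scoring, funnel; write all outputs plus a run
    manifest.  Any stage failure aborts with the stage name and cause."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "inosine_quant"
        if cfg.pileup_case and cfg.pileup_control:
            case = [estimate_inosine(p, cfg.min_coverage) for p in read_pileup_tsv(cfg.pileup_case)]
            ctrl = [estimate_inosine(p, cfg.min_coverage) for p in read_pileup_tsv(cfg.pileup_control)]
            folds = inosine_fold_change(case, ctrl, cfg.inosine_pseudocount)
            write_tsv(estimates_to_frame(case), out / "inosine_case.tsv")
            write_tsv(estimates_to_frame(ctrl), out / "inosine_control.tsv")
            write_tsv(folds, out / "inosine_fold_change.tsv")

        stage = "translation_metrics"
        counts_rna = read_counts_tsv(cfg.rna_counts)
        counts_ribo = read_counts_tsv(cfg.ribo_counts)
        design = read_design_tsv(cfg.design)
        rna = build_expression_matrix(counts_rna, design, "rna")
        ribo = build_expression_matrix(counts_ribo, design, "ribo")
        te = translation_efficiency(rna, ribo, cfg.te_pseudocount, cfg.min_abs_log2fc)
        write_tsv(records_to_frame(te), out / "te.tsv")

        stage = "codon_analysis"
        model = build_adat_codon_model(cfg.codon_subset)
        cds, rejected = read_cds_fasta(cfg.cds_fasta)
        background = aggregate_usage(cds)
        scores = [bias_score(s, background, model) for s in cds]
        write_tsv(bias_scores_to_frame(scores, cfg.bias_threshold), out / "bias.tsv")

        stage = "candidate_funnel"
        tumor = read_tumor_tsv(cfg.tumor_table) if cfg.tumor_table else None
        fcfg = FunnelConfig(
            bias_threshold=cfg.bias_threshold,
            codon_subset=frozenset(cfg.codon_subset),
            overexpression_alpha=cfg.overexpression_alpha,
            ranking_key=cfg.ranking_key,
        )
        result = run_funnel(te, scores, tumor, fcfg)
        text, table = funnel_report(result)
        write_tsv(table, out / "funnel.tsv")
        (out / "report.txt").write_text(text, newline="\n")

        stage = "manifest"
        manifest = {
            "adatscan_version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "stage_sizes": list(result.stage_sizes),
            "tumor_filter_applied": result.tumor_filter_applied,
            "rejected_cds": [list(r) for r in rejected],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", newline="\n"
        )
    except AdatScanError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    logger.info(
        "run_all: stages %s -> %s -> %s", *result.stage_sizes
    )
    return result
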