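"""Three-stage candidate funnel.

Stage 1 keeps genes whose TE and Ribo-seq abundance rise under ADAT2
overexpression and fall under knockout (concordance).  Stage 2 keeps those
with A-to-I-dependent codon usage enriched above a fold threshold (default
1.5) over the background of all supplied coding sequences.  Stage 3 keeps
those overexpressed in tumor versus normal tissue; when no tumor table is
supplied stage 3 equals stage 2 and the result is flagged.

Candidates are ranked deterministically (bias fold enrichment descending by
default, ties broken lexicographically by gene id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .codon_analysis import BiasScore, build_adat_codon_model
from .errors import ConfigurationError, NoOverlapError, SchemaError
from .translation import TranslationRecord

logger = logging.getLogger(__name__)

RANKING_KEYS = ("fold_enrichment", "log2fc_te_oe")


@dataclass(frozen=True)
class FunnelConfig:
    """Tunable thresholds of the screen."""

    bias_threshold: float = 1.5
    codon_subset: frozenset = frozenset({"TCC", "CTC", "CGC"})
    overexpression_alpha: float = 0.05
    ranking_key: str = "fold_enrichment"

    def __post_init__(self) -> None:
        if self.bias_threshold < 0:
            raise ConfigurationError("bias_threshold must be >= 0")
        if not (0 < self.overexpression_alpha <= 1):
            raise ConfigurationError("overexpression_alpha must be in (0, 1]")
        if self.ranking_key not in RANKING_KEYS:
            raise ConfigurationError(f"ranking_key must be one of {RANKING_KEYS}")
        # validates the subset against the dependent-codon set
        build_adat_codon_model(self.codon_subset)


def evaluate_overexpression(
    tumor_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal overexpression calls.

    Accepts three schemas (first column gene_id):

    * a precomputed boolean column ``overexpressed``;
    * per-sample columns prefixed ``tumor_`` / ``normal_`` (>= 2 each): a
      two-sided rank-sum (Mann-Whitney) test per gene, Benjamini-Hochberg
      adjusted; overexpressed = log2FC > 0 and q <= alpha;
    * summary columns ``mean_tumor`` / ``mean_normal``: direction only.

    Returns a DataFrame indexed by gene_id with columns log2fc_tumor, qvalue,
    overexpressed.
    """
    if "gene_id" not in tumor_table.columns:
        raise SchemaError("tumor table must have a gene_id column")
    df = tumor_table.set_index("gene_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"duplicate gene_id in tumor table: {dup!r}")

    if "overexpressed" in df.columns:
        flag = df["overexpressed"].astype(bool)
        out = pd.DataFrame(
            {"log2fc_tumor": np.nan, "qvalue": np.nan, "overexpressed": flag}
        )
        return out

    tumor_cols = [c for c in df.columns if c.startswith("tumor_")]
    normal_cols = [c for c in df.columns if c.startswith("normal_")]
    if len(tumor_cols) >= 2 and len(normal_cols) >= 2:
        t = df[tumor_cols].to_numpy(float)
        n = df[normal_cols].to_numpy(float)
        eps = 1e-9
        l2fc = np.log2((t.mean(axis=1) + eps) / (n.mean(axis=1) + eps))
        # exact null distribution: the asymptotic approximation saturates
        # around p ~ 1e-4 for small cohorts, which BH over hundreds of genes
        # cannot distinguish from noise
        pvals = mannwhitneyu(t, n, axis=1, alternative="two-sided", method="exact").pvalue
        qvals = multipletests(pvals, method="fdr_bh")[1]
        return pd.DataFrame(
            {
                "log2fc_tumor": l2fc,
                "qvalue": qvals,
                "overexpressed": (l2fc > 0) & (qvals <= alpha),
            },
            index=df.index,
        )

    if {"mean_tumor", "mean_normal"} <= set(df.columns):
        eps = 1e-9
        l2fc = np.log2(
            (df["mean_tumor"].astype(float) + eps)
            / (df["mean_normal"].astype(float) + eps)
        )
        return pd.DataFrame(
            {"log2fc_tumor": l2fc, "qvalue": np.nan, "overexpressed": l2fc > 0}
        )

    raise SchemaError(
        "tumor table must provide 'overexpressed', tumor_*/normal_* sample "
        "columns, or mean_tumor/mean_normal"
    )


@dataclass
class FunnelResult:
    """Staged candidate lists with per-gene evidence.

    Invariants: stage3 ⊆ stage2 ⊆ stage1; ranked_candidates is a permutation
    of stage3_genes.
    """

    stage1_genes: list[str]
    stage2_genes: list[str]
    stage3_genes: list[str]
    ranked_candidates: list[str]
    per_gene_evidence: dict[str, dict]
    tumor_filter_applied: bool
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def stage_sizes(self) -> tuple[int, int, int]:
        return (len(self.stage1_genes), len(self.stage2_genes), len(self.stage3_genes))


def _rank_value(evidence: dict, key: str) -> float:
    v = evidence.get(key)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return -np.inf
    return float(v)


def run_funnel(
    te: list[TranslationRecord],
    bias: list[BiasScore],
    tumor_table: Optional[pd.DataFrame] = None,
    cfg: Optional[FunnelConfig] = None,
) -> FunnelResult:
    """Execute the three-stage screen.

    ``te`` defines the gene universe.  Stage-1 genes lacking a bias score are
    excluded from stage 2 with a logged reason; likewise stage-2 genes absent
    from the tumor table.  Ordering within every stage follows the ranking
    key (descending), ties broken lexicographically by gene_id.
    """
    cfg = cfg or FunnelConfig()
    te_by_gene = {r.gene_id: r for r in te}
    bias_by_gene = {b.gene_id: b for b in bias}
    if not te_by_gene:
        raise NoOverlapError("empty TE input")
    if not set(te_by_gene) & set(bias_by_gene):
        raise NoOverlapError("TE and bias-score inputs share no gene_id")

    oe_calls = None
    if tumor_table is not None:
        oe_calls = evaluate_overexpression(tumor_table, cfg.overexpression_alpha)

    evidence: dict[str, dict] = {}
    exclusions: dict[str, str] = {}
    for g, rec in te_by_gene.items():
        ev: dict = {
            "concordant": rec.concordant,
            "log2fc_te_oe": rec.log2fc_te_oe,
            "log2fc_te_ko": rec.log2fc_te_ko,
            "log2fc_ribo_oe": rec.log2fc_ribo_oe,
            "log2fc_ribo_ko": rec.log2fc_ribo_ko,
        }
        b = bias_by_gene.get(g)
        if b is not None:
            ev.update(
                dep_usage_gene=b.dep_usage_gene,
                dep_usage_background=b.dep_usage_background,
                fold_enrichment=b.fold_enrichment,
            )
        if oe_calls is not None and g in oe_calls.index:
            row = oe_calls.loc[g]
            ev.update(
                log2fc_tumor=float(row["log2fc_tumor"]),
                qvalue=float(row["qvalue"]),
                overexpressed=bool(row["overexpressed"]),
            )
        evidence[g] = ev

    def order(genes: list[str]) -> list[str]:
        return sorted(
            genes, key=lambda g: (-_rank_value(evidence[g], cfg.ranking_key), g)
        )

    stage1 = [g for g, ev in evidence.items() if ev["concordant"]]

    stage2 = []
    for g in stage1:
        ev = evidence[g]
        if "fold_enrichment" not in ev:
            exclusions[g] = "no bias score for stage-1 gene"
            logger.warning("funnel: %s excluded at stage 2 (%s)", g, exclusions[g])
            continue
        if ev["fold_enrichment"] > cfg.bias_threshold:
            stage2.append(g)

    tumor_applied = oe_calls is not None
    if not tumor_applied:
        stage3 = list(stage2)
    else:
        stage3 = []
        for g in stage2:
            ev = evidence[g]
            if "overexpressed" not in ev:
                exclusions[g] = "gene absent from tumor table"
                logger.warning("funnel: %s excluded at stage 3 (%s)", g, exclusions[g])
                continue
            if ev["overexpressed"]:
                stage3.append(g)

    stage1, stage2, stage3 = order(stage1), order(stage2), order(stage3)
    for g, ev in evidence.items():
        ev["stage_reached"] = (g in set(stage3)) + (g in set(stage2)) + (g in set(stage1))

    return FunnelResult(
        stage1_genes=stage1,
        stage2_genes=stage2,
        stage3_genes=stage3,
        ranked_candidates=list(stage3),
        per_gene_evidence=evidence,
        tumor_filter_applied=tumor_applied,
        exclusions=exclusions,
    )


_REPORT_COLUMNS = (
    "gene_id", "stage_reached", "rank", "concordant",
    "log2fc_te_oe", "log2fc_te_ko", "log2fc_ribo_oe", "log2fc_ribo_ko",
    "dep_usage_gene", "dep_usage_background", "fold_enrichment",
    "log2fc_tumor", "qvalue", "overexpressed", "exclusion_reason",
)


def funnel_report(result: FunnelResult) -> tuple[str, pd.DataFrame]:
    """Human-readable report and one-row-per-gene evidence table.

    The table covers the whole input universe with a ``stage_reached`` column
    (0–3) and is ordered stage-descending, then by final rank / gene id, so
    identical inputs yield byte-identical TSV output.
    """
    rank_of = {g: i + 1 for i, g in enumerate(result.ranked_candidates)}
    rows = []
    for g, ev in result.per_gene_evidence.items():
        rows.append(
            {
                "gene_id": g,
                "stage_reached": ev.get("stage_reached", 0),
                "rank": rank_of.get(g, np.nan),
                "concordant": ev.get("concordant", False),
                "log2fc_te_oe": ev.get("log2fc_te_oe", np.nan),
                "log2fc_te_ko": ev.get("log2fc_te_ko", np.nan),
                "log2fc_ribo_oe": ev.get("log2fc_ribo_oe", np.nan),
                "log2fc_ribo_ko": ev.get("log2fc_ribo_ko", np.nan),
                "dep_usage_gene": ev.get("dep_usage_gene", np.nan),
                "dep_usage_background": ev.get("dep_usage_background", np.nan),
                "fold_enrichment": ev.get("fold_enrichment", np.nan),
                "log2fc_tumor": ev.get("log2fc_tumor", np.nan),
                "qvalue": ev.get("qvalue", np.nan),
                "overexpressed": ev.get("overexpressed", ""),
                "exclusion_reason": result.exclusions.get(g, ""),
            }
        )
    df = pd.DataFrame(rows, columns=list(_REPORT_COLUMNS))
    df = df.sort_values(
        ["stage_reached", "fold_enrichment", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)

    n1, n2, n3 = result.stage_sizes
    lines = [
        "ADAT2 candidate funnel",
        "======================",
        f"gene universe           : {len(result.per_gene_evidence)}",
        f"stage 1 (TE/Ribo concordant) : {n1}",
        f"stage 2 (codon bias)         : {n2}",
        f"stage 3 (tumor overexpression{'' if result.tumor_filter_applied else ' — SKIPPED, no tumor table'}) : {n3}",
        "",
        "ranked candidates:",
    ]
    for i, g in enumerate(result.ranked_candidates, 1):
        ev = result.per_gene_evidence[g]
        lines.append(
            f"  {i:>3}. {g}  fold_enrichment={ev.get('fold_enrichment', float('nan')):.3f}  "
            f"log2fc_te_oe={ev.get('log2fc_te_oe', float('nan')):.3f}"
        )
    if not result.ranked_candidates:
        lines.append("  (none)")
    if result.exclusions:
        lines.append("")
        lines.append("exclusions:")
        for g in sorted(result.exclusions):
            lines.append(f"  {g}: {result.exclusions[g]}")
    return "\n".join(lines) + "\n", df
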