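"""Translation-efficiency metrics from RNA-seq / Ribo-seq count matrices.

Translation efficiency (TE) of a gene is the ratio of ribosome-footprint
abundance to mRNA abundance (Ribo-seq / RNA-seq).  Counts are normalized to
counts-per-million (CPM) per sample; CPM is sufficient here because the funnel
only compares within-gene ratios across assays and conditions, where
transcript length cancels.  Per condition,

    TE = (mean ribo CPM + pc) / (mean rna CPM + pc)

over replicates, with a small pseudocount ``pc`` keeping TE finite for
zero-count genes.  A gene is *concordant* when ADAT2 overexpression raises
both its TE and its Ribo-seq abundance while ADAT2 knockout lowers both —
a strict four-way sign test, optionally with a minimum |log2FC|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateSampleError,
    DesignError,
    InvalidLabelError,
    NoOverlapError,
    SchemaError,
)

CONDITIONS = ("control_oe", "adat2_oe", "control_ko", "adat2_ko")
ASSAYS = ("rna", "ribo")

#: polysome-gradient fraction labels -> translational state
POLYSOME_CLASSES = {
    "sub40S": "untranslated",
    "40S": "initiation",
    "60S": "initiation",
    "80S": "initiation",
    "polysome": "active",
}


@dataclass
class ExpressionMatrix:
    """A gene × sample count matrix with its sample design.

    ``counts``: DataFrame indexed by gene_id, one column per sample_id,
    non-negative.  ``design``: DataFrame with columns sample_id, condition
    (one of ``CONDITIONS``) and replicate, one row per counts column.
    """

    assay: str
    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise SchemaError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise SchemaError(f"duplicate gene_id in counts: {dup!r}")
        missing = {"sample_id", "condition", "replicate"} - set(self.design.columns)
        if missing:
            raise SchemaError(f"design missing columns {sorted(missing)}")
        unknown = set(self.design["condition"]) - set(CONDITIONS)
        if unknown:
            raise SchemaError(
                f"unknown condition labels {sorted(unknown)}; allowed: {list(CONDITIONS)}"
            )
        if set(self.design["sample_id"]) != set(self.counts.columns):
            raise SchemaError("design sample_ids do not match counts columns")
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise SchemaError("counts must be finite and non-negative")

    def samples_for(self, condition: str) -> list[str]:
        sel = self.design[self.design["condition"] == condition]
        return list(sel["sample_id"])


def normalize_counts(m: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million per sample.  Each column of the result sums to 1e6."""
    libsize = m.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample(s) with zero library size: {list(zero.index)}"
        )
    return m.counts / libsize * 1e6


@dataclass(frozen=True)
class TranslationRecord:
    """Per-gene TE by condition, condition log2 fold-changes, concordance."""

    gene_id: str
    te_by_condition: Mapping[str, float]
    log2fc_te_oe: float
    log2fc_te_ko: float
    log2fc_ribo_oe: float
    log2fc_ribo_ko: float
    concordant: bool


def _condition_means(m: ExpressionMatrix, cpm: pd.DataFrame) -> dict[str, pd.Series]:
    means = {}
    for cond in CONDITIONS:
        cols = m.samples_for(cond)
        if not cols:
            raise DesignError(
                f"{m.assay}: condition {cond!r} absent; the OE/KO concordance "
                f"design requires all of {list(CONDITIONS)}"
            )
        means[cond] = cpm[cols].mean(axis=1)
    return means


def translation_efficiency(
    rna: ExpressionMatrix,
    ribo: ExpressionMatrix,
    pseudocount: float = 0.5,
    min_abs_log2fc: float = 0.0,
) -> list[TranslationRecord]:
    """Compute per-gene TE, condition log2 fold-changes, and concordance.

    Genes are intersected between assays (RNA-seq order preserved).  Each
    condition's TE uses the mean CPM over that condition's replicates plus
    ``pseudocount``.  Log2 fold-changes are taken against the matched control
    (adat2_oe vs control_oe; adat2_ko vs control_ko).

    ``min_abs_log2fc`` optionally requires each of the four fold-changes to
    clear a magnitude threshold (default 0: direction only).
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    if min_abs_log2fc < 0:
        raise ConfigurationError("min_abs_log2fc must be >= 0")
    ribo_genes = set(ribo.counts.index)
    genes = [g for g in rna.counts.index if g in ribo_genes]
    if not genes:
        raise NoOverlapError("RNA and Ribo matrices share no gene_id")

    rna_cpm = normalize_counts(rna).loc[genes]
    ribo_cpm = normalize_counts(ribo).loc[genes]
    rna_mean = _condition_means(rna, rna_cpm)
    ribo_mean = _condition_means(ribo, ribo_cpm)

    te = {
        cond: (ribo_mean[cond] + pseudocount) / (rna_mean[cond] + pseudocount)
        for cond in CONDITIONS
    }
    l2_te_oe = np.log2(te["adat2_oe"] / te["control_oe"])
    l2_te_ko = np.log2(te["adat2_ko"] / te["control_ko"])
    l2_ribo_oe = np.log2(
        (ribo_mean["adat2_oe"] + pseudocount) / (ribo_mean["control_oe"] + pseudocount)
    )
    l2_ribo_ko = np.log2(
        (ribo_mean["adat2_ko"] + pseudocount) / (ribo_mean["control_ko"] + pseudocount)
    )
    t = min_abs_log2fc
    concordant = (l2_te_oe > t) & (l2_ribo_oe > t) & (l2_te_ko < -t) & (l2_ribo_ko < -t)

    records = []
    for g in genes:
        records.append(
            TranslationRecord(
                gene_id=g,
                te_by_condition={cond: float(te[cond].loc[g]) for cond in CONDITIONS},
                log2fc_te_oe=float(l2_te_oe.loc[g]),
                log2fc_te_ko=float(l2_te_ko.loc[g]),
                log2fc_ribo_oe=float(l2_ribo_oe.loc[g]),
                log2fc_ribo_ko=float(l2_ribo_ko.loc[g]),
                concordant=bool(concordant.loc[g]),
            )
        )
    return records


def records_to_frame(records: list[TranslationRecord]) -> pd.DataFrame:
    """Tabulate TranslationRecords for TSV output."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                **{f"te_{c}": r.te_by_condition[c] for c in CONDITIONS},
                "log2fc_te_oe": r.log2fc_te_oe,
                "log2fc_te_ko": r.log2fc_te_ko,
                "log2fc_ribo_oe": r.log2fc_ribo_oe,
                "log2fc_ribo_ko": r.log2fc_ribo_ko,
                "concordant": r.concordant,
            }
            for r in records
        ]
    )


def frame_to_records(df: pd.DataFrame) -> list[TranslationRecord]:
    """Rebuild TranslationRecords from a TSV round-trip."""
    needed = {"gene_id", "log2fc_te_oe", "log2fc_te_ko", "log2fc_ribo_oe", "log2fc_ribo_ko", "concordant"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"TE table missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        te = {c: float(row.get(f"te_{c}", np.nan)) for c in CONDITIONS}
        out.append(
            TranslationRecord(
                gene_id=str(row["gene_id"]),
                te_by_condition=te,
                log2fc_te_oe=float(row["log2fc_te_oe"]),
                log2fc_te_ko=float(row["log2fc_te_ko"]),
                log2fc_ribo_oe=float(row["log2fc_ribo_oe"]),
                log2fc_ribo_ko=float(row["log2fc_ribo_ko"]),
                concordant=bool(row["concordant"]),
            )
        )
    return out


def classify_polysome_fraction(fraction_label: str) -> str:
    """Map a sucrose-gradient fraction label to its translational state.

    sub40S → untranslated; 40S/60S/80S → initiation; polysome → active.
    """
    try:
        return POLYSOME_CLASSES[fraction_label]
    except KeyError:
        raise InvalidLabelError(
            f"unknown fraction label {fraction_label!r}; "
            f"allowed: {list(POLYSOME_CLASSES)}"
        ) from None
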