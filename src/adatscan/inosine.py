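"""Wobble-position inosine quantification from tRNA-seq pileups.

Inosine is read as guanosine by reverse transcriptases, so the inosine
fraction at the wobble base (Sprinzl position 34) of an ADAT-target tRNA is
estimated from the A→G mismatch fraction in a positional base-count pileup:

    i_fraction  = G / (A + G)        at position 34
    i_to_a_ratio = G / A             (infinite when A = 0)

C and T counts at position 34 are treated as sequencing error: they do not
enter ``i_fraction`` but do count toward coverage.  Families below a coverage
floor are flagged and excluded from condition fold-changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FamilyMismatchError,
    NoCommonFamilyError,
    PileupError,
)

WOBBLE_POSITION = 34

PILEUP_COLUMNS = ("family_id", "sprinzl_pos", "ref_base", "count_A", "count_C", "count_G", "count_T")


@dataclass
class TrnaPileup:
    """Positional base counts for one tRNA family.

    ``table`` columns: sprinzl_pos (int, 1-based Sprinzl numbering as given
    upstream — never renumbered here), ref_base, count_A..count_T.
    """

    family_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sprinzl_pos", "ref_base", "count_A", "count_C", "count_G", "count_T"} - set(
            self.table.columns
        )
        if missing:
            raise PileupError(f"{self.family_id}: pileup missing columns {sorted(missing)}")
        counts = self.table[["count_A", "count_C", "count_G", "count_T"]]
        if (counts.to_numpy() < 0).any():
            raise PileupError(f"{self.family_id}: negative base counts")


@dataclass(frozen=True)
class InosineEstimate:
    """Inosine estimate at the wobble position of one tRNA family."""

    family_id: str
    i_fraction: float
    i_to_a_ratio: float
    coverage: int
    flag_low_coverage: bool


def estimate_inosine(pileup: TrnaPileup, min_coverage: int = 100) -> InosineEstimate:
    """Estimate the inosine fraction at position 34 of an ADAT-target family.

    Raises
    ------
    PileupError
        If position 34 is absent from the pileup.
    FamilyMismatchError
        If the reference base at position 34 is not A.
    """
    if min_coverage < 1:
        raise ConfigurationError("min_coverage must be >= 1")
    rows = pileup.table[pileup.table["sprinzl_pos"] == WOBBLE_POSITION]
    if rows.empty:
        raise PileupError(
            f"{pileup.family_id}: position {WOBBLE_POSITION} missing from pileup"
        )
    row = rows.iloc[0]
    ref = str(row["ref_base"]).upper()
    if ref != "A":
        raise FamilyMismatchError(
            f"{pileup.family_id}: ref base at position {WOBBLE_POSITION} is {ref}, "
            "expected A for an ADAT-target family"
        )
    a, c, g, t = (int(row[f"count_{b}"]) for b in "ACGT")
    coverage = a + c + g + t
    if a + g > 0:
        i_fraction = g / (a + g)
    else:
        i_fraction = math.nan
    if a > 0:
        ratio = g / a
    elif g > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    return InosineEstimate(
        family_id=pileup.family_id,
        i_fraction=i_fraction,
        i_to_a_ratio=ratio,
        coverage=coverage,
        flag_low_coverage=coverage < min_coverage,
    )


def inosine_fold_change(
    case: list[InosineEstimate],
    control: list[InosineEstimate],
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-family I-to-A ratio fold-changes between two conditions.

    ``fold = (ratio_case + pseudocount) / (ratio_control + pseudocount)``,
    reported raw and on the log2 scale.  Families flagged for low coverage in
    either condition are excluded; the remaining families must intersect.

    Returns a DataFrame with columns family_id, i_fraction_case,
    i_fraction_control, ratio_case, ratio_control, fold_change,
    log2_fold_change, sorted by descending fold then family_id.
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    case_ok = {e.family_id: e for e in case if not e.flag_low_coverage}
    ctrl_ok = {e.family_id: e for e in control if not e.flag_low_coverage}
    common = sorted(set(case_ok) & set(ctrl_ok))
    if not common:
        raise NoCommonFamilyError(
            "no tRNA family passes coverage in both case and control"
        )
    rows = []
    for fam in common:
        rc, rn = case_ok[fam].i_to_a_ratio, ctrl_ok[fam].i_to_a_ratio
        fold = (rc + pseudocount) / (rn + pseudocount)
        rows.append(
            {
                "family_id": fam,
                "i_fraction_case": case_ok[fam].i_fraction,
                "i_fraction_control": ctrl_ok[fam].i_fraction,
                "ratio_case": rc,
                "ratio_control": rn,
                "fold_change": fold,
                "log2_fold_change": np.log2(fold),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["fold_change", "family_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def estimates_to_frame(estimates: list[InosineEstimate]) -> pd.DataFrame:
    """Tabulate estimates for TSV output."""
    return pd.DataFrame(
        [
            {
                "family_id": e.family_id,
                "i_fraction": e.i_fraction,
                "i_to_a_ratio": e.i_to_a_ratio,
                "coverage": e.coverage,
                "flag_low_coverage": e.flag_low_coverage,
            }
            for e in estimates
        ]
    )
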