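"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the data structure of an ADAT2 perturbation screen:

* **CDS set** — genes whose dependent-codon content is controlled by a simple
  composition model: each codon position is, with probability ``adat_aa_share``,
  one of the eight ADAT-family amino acids (codon then chosen Bernoulli between
  the family's strictly dependent codon and a non-dependent synonym), otherwise
  a uniform draw from the non-ADAT amino acids.  A gene's target
  dependent-codon fraction is therefore tunable up to ``adat_aa_share``.
* **tRNA pileups** — per-family positional base counts in which the G count at
  the wobble position is Binomial(depth, inosine fraction), with a small
  sequencing-error rate to C/T.
* **RNA/Ribo count matrices** — RNA counts are multinomial over log-normal
  gene abundances; ribosome loading multiplies abundance by
  ``2 ** (effect * mean_I34(condition) * dep_fraction_gene / dep_fraction_background)``
  so that planted responder genes gain TE when inosine supply rises (ADAT2
  overexpression) and lose it when supply falls (knockout).  This is a minimal
  multiplicative effect model — a testing harness, not an elongation simulator.
* **tumor table** — log-normal tumor/normal abundances with responders
  overexpressed in tumor samples.

One RNG stream (seeded) drives a whole bundle; regeneration with the same
seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codon_analysis import (
    AA3_TO_1,
    ALL_CODONS,
    GENETIC_CODE,
    STOP_CODONS,
    CodingSequence,
    aggregate_usage,
    build_adat_codon_model,
    codon_usage,
    dependent_fraction,
)
from .errors import ConfigurationError, InfeasibleFractionError
from .inosine import TrnaPileup
from .translation import CONDITIONS, ExpressionMatrix

_MODEL = build_adat_codon_model()
FAMILY_IDS: tuple[str, ...] = _MODEL.family_ids
#: families whose modification level responds most strongly to ADAT2
#: perturbation (decode TCC, CTC, CGC)
SUBSET_FAMILY_IDS: tuple[str, ...] = ("Ser-AGA", "Leu-AAG", "Arg-ACG")

_ADAT_AAS = tuple(AA3_TO_1[f.amino_acid] for f in _MODEL.families)
_DEP_CODON_BY_AA = {AA3_TO_1[f.amino_acid]: f.dependent_codon for f in _MODEL.families}
#: non-dependent synonyms per ADAT amino acid
_NONDEP_SYNONYMS = {
    aa: tuple(
        c
        for c in ALL_CODONS
        if GENETIC_CODE[c] == aa and c not in _MODEL.dependent_codons
    )
    for aa in _ADAT_AAS
}
#: codons of all non-ADAT amino acids (no stops)
_NON_ADAT_CODONS = tuple(
    c
    for c in ALL_CODONS
    if c not in STOP_CODONS and GENETIC_CODE[c] not in _ADAT_AAS
)


def _default_i_fractions() -> dict[tuple[str, str], float]:
    """Condition-dependent wobble inosine fractions.

    Controls sit at 0.5; overexpression pushes the three most responsive
    families to 0.9 (others 0.6); knockout drops them to 0.1 (others 0.4).
    """
    out: dict[tuple[str, str], float] = {}
    for fam in FAMILY_IDS:
        strong = fam in SUBSET_FAMILY_IDS
        out[(fam, "control_oe")] = 0.5
        out[(fam, "control_ko")] = 0.5
        out[(fam, "adat2_oe")] = 0.9 if strong else 0.6
        out[(fam, "adat2_ko")] = 0.1 if strong else 0.4
    return out


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    seed: int
    n_genes: int = 500
    length_codons: int = 300
    dep_fraction_background: float = 0.15
    adat_aa_share: float = 0.6
    planted_biased: dict[str, float] = field(default_factory=dict)       # gene -> dep fraction
    planted_responders: dict[str, float] = field(default_factory=dict)   # gene -> log2 effect
    i_fraction_by_family_condition: dict[tuple[str, str], float] = field(
        default_factory=_default_i_fractions
    )
    subset_families: tuple[str, ...] = SUBSET_FAMILY_IDS
    library_size: int = 1_000_000
    replicates: int = 3
    pileup_depth: int = 2000
    error_rate: float = 0.001
    tumor_replicates: int = 10
    tumor_log2_effect: float = 2.0
    tumor_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for (fam, cond), f in self.i_fraction_by_family_condition.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"i_fraction for {(fam, cond)} outside [0,1]: {f}")
        unknown = set(self.planted_responders) - set(self.gene_ids)
        unknown |= set(self.planted_biased) - set(self.gene_ids)
        if unknown:
            raise ConfigurationError(f"planted genes outside universe: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    def mean_i34(self, condition: str) -> float:
        return float(
            np.mean(
                [
                    self.i_fraction_by_family_condition[(fam, condition)]
                    for fam in self.subset_families
                ]
            )
        )


def default_truth(
    seed: int,
    n_genes: int = 500,
    length_codons: int = 300,
    n_responders: int = 5,
    responder_log2_effect: float = 1.0,
    planted_dep_fraction: float = 0.4,
    **overrides,
) -> SimTruth:
    """Study conditions used throughout: ``n_responders`` genes are planted
    both codon-biased (dependent fraction ``planted_dep_fraction`` vs 0.15
    background) and TE-responsive, drawn at random from the universe."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    chosen = sorted(rng.choice(n_genes, size=n_responders, replace=False))
    responders = [genes[i] for i in chosen]
    return SimTruth(
        seed=seed,
        n_genes=n_genes,
        length_codons=length_codons,
        planted_biased={g: planted_dep_fraction for g in responders},
        planted_responders={g: responder_log2_effect for g in responders},
        **overrides,
    )


def _draw_gene_codons(
    length_codons: int, dep_fraction: float, adat_aa_share: float, rng: np.random.Generator
) -> str:
    if not 0.0 <= dep_fraction <= 1.0:
        raise ConfigurationError(f"dependent-codon fraction outside [0,1]: {dep_fraction}")
    if dep_fraction > adat_aa_share:
        raise InfeasibleFractionError(
            f"target dependent-codon fraction {dep_fraction} exceeds the ADAT "
            f"amino-acid share {adat_aa_share}; unrealizable composition"
        )
    k = length_codons - 1  # first codon is the ATG start
    cat = rng.random(k)
    aa_idx = rng.integers(0, len(_ADAT_AAS), size=k)
    syn_lens = np.array([len(_NONDEP_SYNONYMS[aa]) for aa in _ADAT_AAS])
    syn_idx = rng.integers(0, syn_lens[aa_idx])
    other_idx = rng.integers(0, len(_NON_ADAT_CODONS), size=k)

    codons = np.empty(k, dtype="<U3")
    dep_mask = cat < dep_fraction
    adat_mask = (~dep_mask) & (cat < adat_aa_share)
    other_mask = ~dep_mask & ~adat_mask
    dep_arr = np.array([_DEP_CODON_BY_AA[aa] for aa in _ADAT_AAS])
    codons[dep_mask] = dep_arr[aa_idx[dep_mask]]
    for j in np.nonzero(adat_mask)[0]:
        aa = _ADAT_AAS[aa_idx[j]]
        codons[j] = _NONDEP_SYNONYMS[aa][syn_idx[j]]
    codons[other_mask] = np.array(_NON_ADAT_CODONS)[other_idx[other_mask]]
    return "ATG" + "".join(codons) + "TAA"


def _simulate_cds(truth: SimTruth, rng: np.random.Generator) -> list[CodingSequence]:
    out = []
    for g in truth.gene_ids:
        f = truth.planted_biased.get(g, truth.dep_fraction_background)
        out.append(
            CodingSequence(g, _draw_gene_codons(truth.length_codons, f, truth.adat_aa_share, rng))
        )
    return out


def simulate_cds(
    n_genes: int,
    length_codons: int,
    dep_fraction_background: float,
    planted: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> list[CodingSequence]:
    """Generate a CDS set with controlled dependent-codon fractions.

    Each gene starts with ATG, contains no internal stop, and ends with TAA;
    its realized dependent-codon fraction is within binomial sampling error of
    its target (``planted`` overrides the background per gene).
    """
    if length_codons < 10:
        raise ConfigurationError("length_codons must be >= 10")
    truth = SimTruth(
        seed=seed,
        n_genes=n_genes,
        length_codons=length_codons,
        dep_fraction_background=dep_fraction_background,
        planted_biased=dict(planted or {}),
    )
    return _simulate_cds(truth, np.random.default_rng(seed))


def _effect_log2(truth: SimTruth, cds: Sequence[CodingSequence]) -> dict[str, np.ndarray]:
    """Per-condition log2 ribosome-loading effects for every gene."""
    dep = np.array(
        [dependent_fraction(codon_usage(s), _MODEL.dependent_codons) for s in cds]
    )
    background = dependent_fraction(aggregate_usage(cds), _MODEL.dependent_codons)
    size = np.array([truth.planted_responders.get(s.gene_id, 0.0) for s in cds])
    out = {}
    for cond in CONDITIONS:
        out[cond] = size * truth.mean_i34(cond) * dep / background
    return out


def simulate_counts(
    cds: Sequence[CodingSequence],
    truth: SimTruth,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """RNA and Ribo count matrices under the multiplicative effect model.

    RNA counts per sample are Multinomial(library_size, p ∝ abundance); Ribo
    counts use p ∝ abundance × 2^effect(condition).  With all effects zero
    the expected TE is equal across conditions for every gene.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    n = len(cds)
    genes = [s.gene_id for s in cds]
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    effects = _effect_log2(truth, cds)
    p_rna = abundance / abundance.sum()

    rna_cols, ribo_cols, design_rows = {}, {}, []
    for cond in CONDITIONS:
        loading = abundance * np.exp2(effects[cond])
        p_ribo = loading / loading.sum()
        for rep in range(1, truth.replicates + 1):
            rna_id, ribo_id = f"rna_{cond}_{rep}", f"ribo_{cond}_{rep}"
            rna_cols[rna_id] = rng.multinomial(truth.library_size, p_rna)
            ribo_cols[ribo_id] = rng.multinomial(truth.library_size, p_ribo)
            design_rows.append({"sample_id": rna_id, "assay": "rna", "condition": cond, "replicate": rep})
            design_rows.append({"sample_id": ribo_id, "assay": "ribo", "condition": cond, "replicate": rep})

    design = pd.DataFrame(design_rows)
    rna = ExpressionMatrix(
        assay="rna",
        counts=pd.DataFrame(rna_cols, index=pd.Index(genes, name="gene_id")),
        design=design[design["assay"] == "rna"].reset_index(drop=True),
    )
    ribo = ExpressionMatrix(
        assay="ribo",
        counts=pd.DataFrame(ribo_cols, index=pd.Index(genes, name="gene_id")),
        design=design[design["assay"] == "ribo"].reset_index(drop=True),
    )
    return rna, ribo


def simulate_pileups(
    truth: SimTruth,
    depth: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[TrnaPileup]]:
    """Per-condition tRNA pileups around the anticodon (Sprinzl 32–36).

    At position 34 the G count is Binomial(depth, i_fraction) with error rate
    ``truth.error_rate`` to C and T each; flanking positions carry the
    reference base with the same error rate.
    """
    depth = depth if depth is not None else truth.pileup_depth
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    e = truth.error_rate
    bases = "ACGT"
    out: dict[str, list[TrnaPileup]] = {}
    for cond in CONDITIONS:
        pileups = []
        for fam in _MODEL.families:
            i_frac = truth.i_fraction_by_family_condition[(fam.family_id, cond)]
            ref_by_pos = {32: "C", 33: "T", 34: "A", 35: fam.anticodon[1], 36: fam.anticodon[2]}
            rows = []
            for pos in (32, 33, 34, 35, 36):
                ref = ref_by_pos[pos]
                if pos == 34:
                    p = np.array([(1 - i_frac) * (1 - 2 * e), (1 - i_frac) * e, i_frac, (1 - i_frac) * e])
                else:
                    p = np.full(4, e)
                    p[bases.index(ref)] = 1 - 3 * e
                cA, cC, cG, cT = rng.multinomial(depth, p)
                rows.append(
                    {"sprinzl_pos": pos, "ref_base": ref,
                     "count_A": cA, "count_C": cC, "count_G": cG, "count_T": cT}
                )
            pileups.append(TrnaPileup(fam.family_id, pd.DataFrame(rows)))
        out[cond] = pileups
    return out


def simulate_tumor_table(
    truth: SimTruth, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Tumor/normal expression with planted responders overexpressed in tumor."""
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    genes = truth.gene_ids
    n, m = len(genes), truth.tumor_replicates
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n)
    effect = np.array(
        [truth.tumor_log2_effect if g in truth.planted_responders else 0.0 for g in genes]
    )
    noise_t = rng.normal(0.0, truth.tumor_noise_sd, size=(n, m))
    noise_n = rng.normal(0.0, truth.tumor_noise_sd, size=(n, m))
    tumor = base[:, None] * np.exp2(effect[:, None] + noise_t)
    normal = base[:, None] * np.exp2(noise_n)
    df = pd.DataFrame({"gene_id": genes})
    for j in range(m):
        df[f"tumor_{j + 1}"] = tumor[:, j]
    for j in range(m):
        df[f"normal_{j + 1}"] = normal[:, j]
    return df


@dataclass
class SimBundle:
    """All inputs of one simulated study plus its ground truth."""

    truth: SimTruth
    cds: list[CodingSequence]
    rna: ExpressionMatrix
    ribo: ExpressionMatrix
    pileups: dict[str, list[TrnaPileup]]
    tumor: pd.DataFrame


def simulate_bundle(seed: int = 0, **truth_kwargs) -> SimBundle:
    """Generate a complete, gene-consistent study from one RNG stream.

    ``truth_kwargs`` are forwarded to :func:`default_truth` (e.g. ``n_genes``,
    ``n_responders``, ``library_size``).
    """
    truth = default_truth(seed, **truth_kwargs)
    rng = np.random.default_rng(seed)
    cds = _simulate_cds(truth, rng)
    rna, ribo = simulate_counts(cds, truth, rng)
    pileups = simulate_pileups(truth, rng=rng)
    tumor = simulate_tumor_table(truth, rng)
    return SimBundle(truth=truth, cds=cds, rna=rna, ribo=ribo, pileups=pileups, tumor=tumor)
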