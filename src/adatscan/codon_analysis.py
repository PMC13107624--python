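"""ADAT wobble-decoding model, codon-usage bias scoring, and synonymous recoding.

The ADAT2/ADAT3 heterodimer deaminates adenosine 34 (the wobble base) to
inosine in eight human tRNA families.  Inosine-34 pairs with C, U and A at the
third codon position, but the C-ending codon of each family is read *only*
through the I34:C wobble pair — no other isoacceptor decodes it efficiently.
Those eight C-ending codons are the "A-to-I-dependent" codons this module
derives, scores, and removes by synonymous recoding.

Anticodons are written 5'→3' with the wobble base (Sprinzl position 34) first,
e.g. Ser-AGA, so the decoded codon is ``complement(ac[2]) + complement(ac[1]) +
<third base>``; for the strictly dependent codon the third base is C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping, Optional

from .errors import ConfigurationError, SequenceError, UndefinedFoldError

# Standard genetic code, DNA alphabet; '*' marks stop codons.
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
STOP_CODONS: frozenset[str] = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

#: codons per amino acid (one-letter code), stops under '*'
SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon in ALL_CODONS:
    SYNONYMS.setdefault(GENETIC_CODE[_codon], ())
SYNONYMS = {
    aa: tuple(c for c in ALL_CODONS if GENETIC_CODE[c] == aa) for aa in SYNONYMS
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: three-letter -> one-letter amino acid codes for the eight ADAT families
AA3_TO_1 = {
    "Leu": "L", "Arg": "R", "Ser": "S", "Pro": "P",
    "Ala": "A", "Val": "V", "Ile": "I", "Thr": "T",
}

# (amino acid, anticodon 5'->3', wobble base first)
_FAMILY_SPECS: tuple[tuple[str, str], ...] = (
    ("Leu", "AAG"),
    ("Arg", "ACG"),
    ("Ser", "AGA"),
    ("Pro", "AGG"),
    ("Ala", "AGC"),
    ("Val", "AAC"),
    ("Ile", "AAT"),
    ("Thr", "AGT"),
)


def translate(sequence: str) -> str:
    """Translate an in-frame DNA string under the standard genetic code."""
    if len(sequence) % 3 != 0:
        raise SequenceError(f"length {len(sequence)} is not divisible by 3")
    return "".join(GENETIC_CODE[sequence[i : i + 3]] for i in range(0, len(sequence), 3))


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame CDS.

    The sequence is upper-cased and U is mapped to T on construction.
    Invariants: length >= 3, divisible by 3, alphabet {A,C,G,T}.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise SequenceError(f"{self.gene_id}: length {len(seq)} < 3")
        if len(seq) % 3 != 0:
            raise SequenceError(
                f"{self.gene_id}: length {len(seq)} not divisible by 3"
            )
        bad = set(seq) - set("ACGT")
        if bad:
            raise SequenceError(
                f"{self.gene_id}: invalid characters {sorted(bad)} (alphabet A/C/G/T)"
            )

    @property
    def codons(self) -> tuple[str, ...]:
        s = self.sequence
        return tuple(s[i : i + 3] for i in range(0, len(s), 3))

    def protein(self) -> str:
        return translate(self.sequence)


@dataclass(frozen=True)
class AdatFamily:
    """One ADAT-substrate tRNA family (amino acid + anticodon)."""

    amino_acid: str  # three-letter code
    anticodon: str   # 5'->3', wobble (position 34) first; always starts with A

    @property
    def family_id(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}"

    @property
    def dependent_codon(self) -> str:
        """The codon read exclusively via the I34:C wobble pair."""
        ac = self.anticodon
        return _COMPLEMENT[ac[2]] + _COMPLEMENT[ac[1]] + "C"


#: default synonymous replacements: NNC -> NNG (G-ending codons are read by
#: C34 isoacceptors, never I34), except Ile which lacks a G-ending codon and
#: maps ATC -> ATA (decoded by a distinct non-ADAT pathway in human cells).
DEFAULT_RECODE_MAP: dict[str, str] = {
    "TCC": "TCG", "CTC": "CTG", "CGC": "CGG", "CCC": "CCG",
    "GCC": "GCG", "GTC": "GTG", "ACC": "ACG", "ATC": "ATA",
}


@dataclass(frozen=True)
class AdatCodonModel:
    """The eight ADAT-substrate families, their strictly inosine-dependent
    codons, and the synonymous recoding map that removes the dependence."""

    families: tuple[AdatFamily, ...]
    dependent_codons: frozenset[str]
    recode_map: Mapping[str, str]
    scoring_subset: frozenset[str]

    @property
    def family_ids(self) -> tuple[str, ...]:
        return tuple(f.family_id for f in self.families)

    def family_for_codon(self, codon: str) -> AdatFamily:
        for fam in self.families:
            if fam.dependent_codon == codon:
                return fam
        raise KeyError(codon)


def build_adat_codon_model(codon_subset: Optional[Iterable[str]] = None) -> AdatCodonModel:
    """Build the wobble model for the eight ADAT-substrate anticodon families.

    Parameters
    ----------
    codon_subset
        Optional restriction of the codons used for bias scoring (e.g.
        ``{"TCC", "CTC", "CGC"}``, the subset whose tRNA modification levels
        respond most strongly to ADAT2 perturbation).  Must be a subset of the
        full dependent-codon set.

    Raises
    ------
    ConfigurationError
        If ``codon_subset`` contains a codon that is not A-to-I dependent.
    """
    families = tuple(AdatFamily(aa, ac) for aa, ac in _FAMILY_SPECS)
    dependent = frozenset(f.dependent_codon for f in families)

    # model self-checks: cheap, and they pin the invariants at construction
    assert len(families) == 8 and len(dependent) == 8
    for fam in families:
        assert fam.anticodon[0] == "A", "wobble base must be A (pre-editing)"
        assert fam.dependent_codon.endswith("C")
        assert GENETIC_CODE[fam.dependent_codon] == AA3_TO_1[fam.amino_acid]
    for old, new in DEFAULT_RECODE_MAP.items():
        assert GENETIC_CODE[old] == GENETIC_CODE[new], "recoding must be synonymous"
        assert new not in dependent, "replacement must not itself be dependent"
    assert set(DEFAULT_RECODE_MAP) == set(dependent)

    if codon_subset is None:
        subset = dependent
    else:
        subset = frozenset(str(c).upper().replace("U", "T") for c in codon_subset)
        extra = subset - dependent
        if extra:
            raise ConfigurationError(
                f"codon_subset contains non-A-to-I-dependent codons: {sorted(extra)}; "
                f"allowed: {sorted(dependent)}"
            )
    return AdatCodonModel(
        families=families,
        dependent_codons=dependent,
        recode_map=dict(DEFAULT_RECODE_MAP),
        scoring_subset=subset,
    )


def codon_usage(seq: CodingSequence) -> dict[str, int]:
    """Count all 64 codons in a CDS.  Counts sum to len/3 (stops included)."""
    counts = Counter(seq.codons)
    return {c: counts.get(c, 0) for c in ALL_CODONS}


def aggregate_usage(seqs: Iterable[CodingSequence]) -> dict[str, int]:
    """Summed codon-usage table over a collection of CDS (the background)."""
    total = Counter()
    for seq in seqs:
        total.update(seq.codons)
    return {c: total.get(c, 0) for c in ALL_CODONS}


def dependent_fraction(counts: Mapping[str, int], subset: Iterable[str]) -> float:
    """Fraction of non-stop codons that belong to ``subset``."""
    decoded = sum(n for c, n in counts.items() if c not in STOP_CODONS)
    if decoded == 0:
        return 0.0
    return sum(counts.get(c, 0) for c in subset) / decoded


@dataclass(frozen=True)
class BiasScore:
    """Per-gene enrichment of A-to-I-dependent codons over a background."""

    gene_id: str
    dep_usage_gene: float
    dep_usage_background: float
    fold_enrichment: float

    def passes(self, threshold: float = 1.5) -> bool:
        return self.fold_enrichment > threshold


def bias_score(
    seq: CodingSequence,
    background: Mapping[str, int],
    model: AdatCodonModel,
    codon_subset: Optional[Iterable[str]] = None,
) -> BiasScore:
    """Score a gene's usage of A-to-I-dependent codons against a background.

    ``fold_enrichment = dep_usage_gene / dep_usage_background``, with usage
    fractions taken over non-stop codons.  ``codon_subset`` (default: the
    model's scoring subset) restricts which dependent codons are counted.

    Raises
    ------
    UndefinedFoldError
        If the background never uses the scored codons.
    """
    if codon_subset is None:
        subset = model.scoring_subset
    else:
        subset = frozenset(str(c).upper().replace("U", "T") for c in codon_subset)
        extra = subset - model.dependent_codons
        if extra:
            raise ConfigurationError(
                f"codon_subset contains non-A-to-I-dependent codons: {sorted(extra)}"
            )
    bg = dependent_fraction(background, subset)
    if bg <= 0.0:
        raise UndefinedFoldError(
            f"background usage of {sorted(subset)} is zero; fold enrichment undefined"
        )
    gene = dependent_fraction(codon_usage(seq), subset)
    return BiasScore(
        gene_id=seq.gene_id,
        dep_usage_gene=gene,
        dep_usage_background=bg,
        fold_enrichment=gene / bg,
    )


@dataclass(frozen=True)
class RecodeEvent:
    """One codon replacement: 0-based codon index, old codon, new codon."""

    codon_index: int
    old_codon: str
    new_codon: str


def recode_sequence(
    seq: CodingSequence, model: AdatCodonModel
) -> tuple[CodingSequence, list[RecodeEvent]]:
    """Synonymously replace every A-to-I-dependent codon in a CDS.

    The output encodes the identical protein and contains no codon from
    ``model.dependent_codons``; applying the operation twice is a no-op.

    Returns the recoded sequence and the list of replacements made.
    """
    out: list[str] = []
    events: list[RecodeEvent] = []
    for i, codon in enumerate(seq.codons):
        if codon in model.dependent_codons:
            new = model.recode_map[codon]
            events.append(RecodeEvent(i, codon, new))
            out.append(new)
        else:
            out.append(codon)
    return CodingSequence(seq.gene_id, "".join(out)), events
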