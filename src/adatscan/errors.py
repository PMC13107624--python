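"""Exception hierarchy.

Every error carries a short machine-parsable ``code`` that the CLI prints as
``<code>: <message>`` before exiting nonzero.
"""


class AdatScanError(Exception):
    """Base class for all adatscan errors."""

    code = "error"


class SequenceError(AdatScanError):
    """A coding sequence violates its invariants (length, frame, alphabet)."""

    code = "invalid_sequence"


class ConfigurationError(AdatScanError):
    """An option or configuration value is out of its documented range."""

    code = "invalid_configuration"


class UndefinedFoldError(AdatScanError):
    """Background dependent-codon usage is zero; fold enrichment undefined."""

    code = "undefined_fold"


class PileupError(AdatScanError):
    """A tRNA pileup table is malformed (e.g. wobble position missing)."""

    code = "malformed_pileup"


class FamilyMismatchError(PileupError):
    """The reference base at position 34 is not A for an ADAT-target family."""

    code = "family_mismatch"


class NoCommonFamilyError(AdatScanError):
    """Case and control estimates share no usable tRNA family."""

    code = "no_common_family"


class DegenerateSampleError(AdatScanError):
    """A sample has zero library size and cannot be normalized."""

    code = "degenerate_sample"


class DesignError(AdatScanError):
    """A condition is missing its matched control (or is absent entirely)."""

    code = "unmatched_design"


class NoOverlapError(AdatScanError):
    """Gene universes of two inputs do not intersect."""

    code = "no_overlap"


class InvalidLabelError(AdatScanError):
    """An unknown polysome-fraction or condition label."""

    code = "invalid_label"


class SchemaError(AdatScanError):
    """An input table does not match its documented schema."""

    code = "schema_error"


class InfeasibleFractionError(AdatScanError):
    """A requested dependent-codon fraction cannot be realized."""

    code = "infeasible_fraction"
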