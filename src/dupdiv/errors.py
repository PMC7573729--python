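"""Exception hierarchy shared across the package."""


class DupdivError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(DupdivError):
    """Sequences in an alignment do not all have the same length."""


class AlphabetError(DupdivError):
    """A sequence contains a character outside its declared alphabet."""


class IdError(DupdivError):
    """Duplicate, empty or unknown identifiers."""


class ParseError(DupdivError):
    """Malformed input file (FASTA/Newick/TSV)."""


class TreeError(DupdivError):
    """Invalid tree structure (e.g. missing branch lengths)."""


class IncompleteMatrixError(DupdivError):
    """An operation requiring a complete distance matrix met masked entries."""


class InsufficientDataError(DupdivError):
    """Too few usable sites, pairs or points for the requested computation."""


class DegeneratePredictorError(DupdivError):
    """Regression predictor has zero variance."""


class ConfigError(DupdivError):
    """Pipeline configuration invalid; carries the full list of violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )
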