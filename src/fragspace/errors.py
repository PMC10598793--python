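"""Exception types shared across the package."""


class FragspaceError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(FragspaceError):
    """Raised when a SMILES string cannot be parsed into a molecule.

    The offending input is kept on the ``smiles`` attribute so batch
    runners can report exactly which record failed.
    """

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class KindMismatchError(FragspaceError):
    """Raised when an operation receives a fragment of the wrong kind
    (e.g. an AF profile requested for a ring fragment)."""


class ScoringUnavailableError(FragspaceError):
    """Raised when the SAscore/NPscore contribution data cannot be
    located.  Scores are never silently reported as zero."""


class ConfigurationError(FragspaceError):
    """Raised for invalid run configurations (empty reference sets,
    zero-sized activity subsets, unattainable planted ratios, ...)."""
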