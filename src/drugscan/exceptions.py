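"""Exception hierarchy shared across the package."""


class DrugscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DrugscanError):
    """An option, threshold or model configuration is invalid."""


class ParseError(DrugscanError, ValueError):
    """An input record or structure string could not be parsed."""


class MoleculeParseError(ParseError):
    """A SMILES string did not yield a valid molecule."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"could not parse SMILES: {smiles!r}")


class UsageError(DrugscanError):
    """An operation was called with inputs that violate its contract."""


class IntegrityError(DrugscanError):
    """Cross-table references do not resolve or uniqueness is violated."""


class UndefinedMetricError(DrugscanError):
    """A metric is undefined for the given inputs (e.g. zero variance)."""


class DivergenceError(DrugscanError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")
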