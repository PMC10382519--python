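"""Exception hierarchy for the fbp_pheno pipeline.

Every stage raises a subclass of :class:`FbpPhenoError` so callers can catch
pipeline failures without masking programming errors.
"""


class FbpPhenoError(Exception):
    """Base class for all fbp_pheno errors."""


class UnsupportedNotationError(FbpPhenoError):
    """HGVS notation outside the simple-substitution grammar (indels, splice)."""


class RefMismatchError(FbpPhenoError):
    """The coding sequence does not carry the stated reference base."""


class UndefinedVafError(FbpPhenoError):
    """Variant allele fraction requested at zero depth."""


class IncompletePedigreeError(FbpPhenoError):
    """Compound-het detection requires proband, father and mother."""


class StructureParseError(FbpPhenoError):
    """Malformed coordinate record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class MissingResidueError(FbpPhenoError):
    """Query residue absent from the structure model."""


class ContextUnavailableError(FbpPhenoError):
    """Position resolvable neither in a model nor in the packaged table."""


class DegenerateInputError(FbpPhenoError):
    """Statistic undefined on the input (zero variance, too few points)."""


class SimulationSpecError(FbpPhenoError):
    """Synthetic-data spec that cannot be satisfied (sizing, domain)."""
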