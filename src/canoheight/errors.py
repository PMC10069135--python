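"""Exception hierarchy for the canoheight pipeline."""


class CanoheightError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(CanoheightError):
    """Field-trial design parameters are inconsistent (non-positive counts, ...)."""


class InvalidParameterError(CanoheightError):
    """A simulation or processing parameter is outside its valid range."""


class FormatError(CanoheightError):
    """Unknown or unsupported point-cloud file format."""


class IncompleteDesignError(CanoheightError):
    """The genotype x treatment x replicate table is unbalanced or has missing cells."""

    def __init__(self, message, missing_cells=None):
        super().__init__(message)
        self.missing_cells = list(missing_cells or [])


class InsufficientDataError(CanoheightError):
    """Too few paired observations for the requested statistic."""


class ConfigError(CanoheightError):
    """Pipeline configuration failed validation; ``problems`` lists every violation."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in self.problems))
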