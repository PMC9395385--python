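"""Exception hierarchy for sfeperf."""


class SfeperfError(Exception):
    """Base class for all package errors."""


class UnsupportedDesignError(SfeperfError, ValueError):
    """Requested design is outside the supported family (three-factor CCD)."""


class DegenerateFactorError(SfeperfError, ValueError):
    """A factor has zero (or invalid) coding step."""


class RankDeficiencyError(SfeperfError, ValueError):
    """Model matrix is rank deficient; carries the collinear term names."""

    def __init__(self, collinear_terms):
        self.collinear_terms = list(collinear_terms)
        super().__init__(
            "model matrix is rank deficient; collinear terms: "
            + ", ".join(self.collinear_terms)
        )


class NotFittedError(SfeperfError, ValueError):
    """Operation requires a fitted model."""


class ConfigError(SfeperfError, ValueError):
    """Invalid or incomplete configuration."""


class NoFlashPointError(SfeperfError, ValueError):
    """Flash-point equation has no root in the search bracket."""


class MissingDataError(SfeperfError, ValueError):
    """A condition record is missing a required component."""
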