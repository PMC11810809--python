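"""Exception hierarchy for mrpath.

All package errors derive from :class:`MrPathError` so callers can catch a
single base class; the pipeline catches it per-exposure and logs rather than
aborting a whole scan.
"""


class MrPathError(Exception):
    """Base class for all mrpath errors."""


class ConfigurationError(MrPathError):
    """Invalid configuration value, missing column mapping, bad threshold."""


class ValidationError(MrPathError):
    """A domain object violates one of its invariants."""


class EmptyDatasetError(MrPathError):
    """A summary-statistics file yielded zero valid records."""


class EmptyOverlapError(MrPathError):
    """Exposure and outcome datasets share no SNPs."""

    def __init__(self, exposure_id: str, outcome_id: str):
        self.exposure_id = exposure_id
        self.outcome_id = outcome_id
        super().__init__(
            f"no shared SNPs between exposure {exposure_id!r} "
            f"and outcome {outcome_id!r}"
        )


class InsufficientInstrumentsError(MrPathError):
    """Fewer instruments than the estimator's minimum."""


class UndefinedRatioError(MrPathError):
    """Wald ratio requested for a SNP with zero exposure effect."""


class UndefinedProportionError(MrPathError):
    """Proportion mediated requested with a zero total effect."""


class CollinearityError(MrPathError):
    """Multivariable design matrix is rank deficient."""

    def __init__(self, trait_ids):
        self.trait_ids = tuple(trait_ids)
        super().__init__(
            "collinear instrument effects for traits: " + ", ".join(self.trait_ids)
        )


class UsageError(MrPathError):
    """API misuse, e.g. harmonizing records with different snp_ids."""
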