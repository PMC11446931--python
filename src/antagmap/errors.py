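"""Exception types shared across the pipeline stages."""


class AntagmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AntagmapError):
    """A configuration problem (missing column mapping, bad parameter)."""


class InputError(AntagmapError):
    """Invalid or degenerate input data (empty table, empty pool, ...)."""


class AlleleMismatchError(AntagmapError):
    """Neither allele of a summary-statistics record matches the target.

    Carries both allele pairs for diagnostics.
    """

    def __init__(self, record_alleles, target_allele, snp_id=None):
        self.record_alleles = tuple(record_alleles)
        self.target_allele = target_allele
        self.snp_id = snp_id
        super().__init__(
            f"alleles {self.record_alleles} of {snp_id or 'record'} do not "
            f"include target risk allele {target_allele!r}"
        )


class StrandAmbiguityError(AntagmapError):
    """A strand-ambiguous (A/T or C/G) variant under the 'exclude' policy."""
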