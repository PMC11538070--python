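"""Exception hierarchy for mr2step."""


class MRError(Exception):
    """Base class for all mr2step errors."""


class ConfigurationError(MRError):
    """A column map, scenario config, or plan is invalid."""


class InputError(MRError):
    """An input file is empty or unreadable as summary statistics."""


class NoInstrumentsError(MRError):
    """No SNP survives instrument selection; an MR fit is undefined."""


class InsufficientInstrumentsError(MRError):
    """Fewer retained SNPs than the estimator's minimum."""


class NoHarmonizableInstrumentsError(MRError):
    """Harmonization dropped every instrument."""


class UndefinedProportionError(MRError):
    """Proportion mediated is undefined because the total effect is zero."""


class PipelineError(MRError):
    """Every exposure-outcome pair in a pipeline run failed."""
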