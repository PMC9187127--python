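"""Exception hierarchy shared across the package."""


class SdmafError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SdmafError):
    """Invalid configuration: unsupported build, inconsistent run options."""


class ValidationError(SdmafError):
    """Malformed or inconsistent input data (files, tables, parameters)."""


class DataError(SdmafError):
    """Data that is structurally valid but unusable for the requested
    computation (empty strata, zero denominators, male heterozygotes in
    hemizygous regions under the strict policy)."""
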