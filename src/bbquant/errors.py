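"""Exception hierarchy used across the package."""


class BBQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BBQuantError):
    """A run configuration is inconsistent with the supplied data."""


class FormatError(BBQuantError):
    """An input file does not match the expected layout."""


class RoiValidationError(BBQuantError):
    """An ROI polygon is malformed (open, self-intersecting, out of grid)."""


class EmptyInputError(BBQuantError):
    """An operation received an empty mask or collection."""


class DegenerateInputError(BBQuantError):
    """Input is technically valid but the result is undefined (e.g. constant image)."""


class MappingError(BBQuantError):
    """A spreadsheet mapping stanza does not match the workbook layout."""
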