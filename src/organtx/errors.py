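"""Exception hierarchy for the pipeline.

All errors derive from :class:`OrgantxError` so callers can catch the whole
family; subclasses distinguish malformed files, inconsistent metadata,
invalid parameters, and numerical impossibilities.
"""


class OrgantxError(Exception):
    """Base class for all package errors."""


class FormatError(OrgantxError, ValueError):
    """A file or table violates its structural contract (duplicates, bad dtypes)."""


class ConsistencyError(OrgantxError, ValueError):
    """Two inputs that must agree do not (e.g. a sample missing from the sheet)."""


class ParameterError(OrgantxError, ValueError):
    """A parameter is outside its admissible range or makes a request infeasible."""


class DataError(OrgantxError, ValueError):
    """A data table is structurally fine but semantically unusable (missing reference)."""


class ComputationError(OrgantxError, ArithmeticError):
    """A computation cannot proceed (zero library size, constant vector, empty noise)."""
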