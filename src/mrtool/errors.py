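"""Exception hierarchy for mrtool."""


class MRToolError(Exception):
    """Base class for all mrtool errors."""


class FormatError(MRToolError):
    """Malformed input file (missing columns, non-square matrix, ...)."""


class IntegrityError(MRToolError):
    """Input violates a data invariant (duplicate SNP ids, asymmetric LD, ...)."""


class EmptyInputError(MRToolError):
    """Input file contained no usable rows."""


class RangeError(MRToolError):
    """Numeric value outside its admissible range."""


class EmptyHarmonizationError(MRToolError):
    """No SNP survived harmonization; the exposure-outcome pair must be skipped."""


class DegenerateInstrumentError(MRToolError):
    """An instrument with zero exposure effect cannot produce a Wald ratio."""


class InsufficientInstrumentsError(MRToolError):
    """Fewer instruments than the method requires."""


class ValidationError(MRToolError):
    """A configuration or simulation-truth object failed validation."""
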