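"""Exception hierarchy."""


class AmineReactError(Exception):
    """Base class for all package errors."""


class ParseError(AmineReactError):
    """A structure or charge file could not be parsed."""


class EmptyStructureError(AmineReactError):
    """No scorable atoms remain after parsing/cleaning."""


class LookupFailure(AmineReactError):
    """A requested residue, atom or site is absent from the model."""


class ConfigurationError(AmineReactError):
    """Invalid run configuration (unknown backend, bad threshold, ...)."""


class ClassificationError(AmineReactError):
    """A site reached the classifier with a missing parameter."""


class ReconciliationError(AmineReactError):
    """PQR atoms could not be matched to the PDB model for a site nitrogen."""
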