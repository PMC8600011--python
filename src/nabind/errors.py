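"""Exception hierarchy shared across the package."""


class NabindError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(NabindError):
    """Raised when PDB text cannot be parsed into a complex."""


class NoNucleicAcidError(NabindError):
    """Raised when an operation requires a nucleic-acid chain and none exists."""


class ResidueNotFoundError(NabindError, LookupError):
    """Raised when a (chain, residue number, insertion code) lookup fails."""


class MutationValidationError(NabindError, ValueError):
    """Raised for malformed or inconsistent mutation specifications."""


class ContractError(NabindError):
    """Raised when an internal pre/post-condition between modules is violated."""


class SchemaMismatchError(NabindError):
    """Raised when a feature table does not match the schema a model was trained on."""


class NotClassifiableError(NabindError):
    """Raised when a multi-point construct cannot be classified for additivity."""
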