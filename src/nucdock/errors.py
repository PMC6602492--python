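"""Exception hierarchy."""


class NucdockError(Exception):
    """Base class for all package errors."""


class PDBParseError(NucdockError):
    """Input text is not parseable as a PDB structure."""


class MissingChainError(NucdockError):
    """A requested chain id is absent from the parsed structure."""


class UnknownResidueError(NucdockError):
    """A residue name is outside the nucleic-acid alphabet (and alias table)."""


class ContractViolation(NucdockError):
    """A documented precondition was violated by the caller."""


class GridSizeError(NucdockError):
    """A grid would exceed the configured maximum cell count."""


class RestraintError(NucdockError):
    """A restraint specification is malformed or unresolvable."""
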