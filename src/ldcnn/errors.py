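"""Exception hierarchy. Every stage raises a subclass of LdcnnError so the CLI
and pipeline can report the failing stage by name."""


class LdcnnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LdcnnError):
    """A configuration object is internally inconsistent or infeasible."""


class IOFormatError(LdcnnError):
    """A file could not be read or written in the expected dialect."""


class ParameterError(LdcnnError):
    """An operation was called with parameters invalid for its input."""


class DegenerateSignalError(LdcnnError):
    """The input signal admits no meaningful result (e.g. zero variance)."""


class EmptyOutputError(LdcnnError):
    """An operation that must produce at least one item produced none."""


class MissingClassError(LdcnnError):
    """A class required by the operation has no samples."""


class StratificationError(LdcnnError):
    """A stratified split is impossible (some class too small)."""


class LabelError(LdcnnError):
    """A label index falls outside the class vocabulary."""


class ArchitectureError(LdcnnError):
    """Shape propagation failed or a layer specification is invalid."""


class InputShapeError(LdcnnError):
    """An array fed to the network does not match the architecture input."""


class TrainingError(LdcnnError):
    """Optimization diverged (non-finite loss)."""
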