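"""Exception hierarchy shared across the package."""


class AllopathError(Exception):
    """Base class for all package errors."""


class FormatError(AllopathError):
    """A file could not be parsed in the expected format."""


class InputError(AllopathError):
    """Invalid input data (empty file, length mismatch, bad argument)."""


class TopologyError(AllopathError):
    """Trajectory and topology disagree (e.g. atom-count mismatch)."""


class SelectionError(AllopathError):
    """A residue/atom selection could not be resolved or is empty."""


class LabelError(AllopathError):
    """Residue-label map is inconsistent (duplicate labels, bad keys)."""


class GeometryError(AllopathError):
    """Degenerate geometry (collinear dihedral, <3 fit atoms, ...)."""


class ParameterError(AllopathError):
    """Nonbonded parameters missing or invalid for requested atoms."""


class SpecError(AllopathError):
    """A synthetic-system specification is internally inconsistent."""


class ConfigError(AllopathError):
    """Workflow configuration invalid."""
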