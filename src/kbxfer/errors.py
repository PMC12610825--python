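"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
ModelError -> 4.
"""


class KbxferError(Exception):
    """Base class for all package errors."""


class ConfigError(KbxferError):
    """Invalid configuration: bad axis, unknown keys, infeasible settings."""


class DataError(KbxferError):
    """Invalid data: empty structures, grid mismatches, malformed files."""


class ModelError(KbxferError):
    """Invalid model state: untrained model, missing percentiles, bad band."""


class EmptyStructureError(DataError):
    """A structure mask submitted for DVH computation contains no voxels."""


class GridMismatchError(DataError):
    """Dose grid and structure mask shapes are not congruent."""


class SchemaVersionError(DataError):
    """Serialized artifact carries an unsupported schema version."""
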