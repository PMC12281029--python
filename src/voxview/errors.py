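"""Exception hierarchy shared across voxview."""


class VoxviewError(Exception):
    """Base class for all voxview errors."""


class ValidationError(VoxviewError, ValueError):
    """An argument or specification failed validation."""


class UnsupportedFormatError(VoxviewError):
    """The file is not in any format voxview can read."""


class CorruptFileError(VoxviewError):
    """The file was recognized but its contents are inconsistent."""


class CapacityError(VoxviewError):
    """A legacy format capacity limit was exceeded."""
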