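"""Exception hierarchy.

Every named error class in the public API derives from :class:`KvClampError`
so callers (and the CLI, which maps classes to exit codes) can discriminate
failure modes without string matching.
"""


class KvClampError(Exception):
    """Base class for all kvclamp errors."""


class ProtocolError(KvClampError):
    """A voltage protocol violates a structural invariant."""


class InfeasibleFrequencyError(ProtocolError):
    """Train frequency whose period is shorter than the pulse width."""


class SchemaError(KvClampError):
    """Serialized protocol/preset JSON does not match the expected schema."""


class InvalidSolutionError(KvClampError):
    """Non-physical recording solution (non-positive concentration etc.)."""


class UnknownPresetError(KvClampError):
    """Requested channel preset is not packaged and no file was given."""


class PresetError(KvClampError):
    """Channel preset parameters violate their invariants."""


class ProtocolMismatchError(KvClampError):
    """An analysis was applied to a trace set from the wrong protocol family."""


class DegenerateTraceError(KvClampError):
    """Trace carries no usable signal for the requested analysis."""


class BoundsError(KvClampError):
    """Requested analysis window lies outside the recorded trace."""


class InsufficientDataError(KvClampError):
    """Too few observations for the requested statistic or fit."""


class FitError(KvClampError):
    """Nonlinear fit failed to converge or the data are unidentifiable."""


class SingularRatioError(KvClampError):
    """GHK current ratio evaluated at (or too near) the reference reversal."""
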