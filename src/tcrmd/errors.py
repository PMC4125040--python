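"""Exception hierarchy for tcrmd."""


class TcrmdError(Exception):
    """Base class for all tcrmd errors."""


class FormatError(TcrmdError):
    """Structure/trajectory files are inconsistent with each other."""


class AnnotationError(TcrmdError):
    """A selection or region cannot be resolved against the structure."""


class EmptyEnsembleError(TcrmdError):
    """An operation removed every frame of an ensemble."""


class DegenerateFitError(TcrmdError):
    """Too few or collinear atoms for a rigid-body fit."""


class DegenerateFrameError(TcrmdError):
    """Domain coordinate frame cannot be constructed (collinear core, coincident anchors)."""


class UndefinedFluctuationError(TcrmdError):
    """Fluctuation statistics requested on a single-frame ensemble."""


class DegenerateDenominatorError(TcrmdError):
    """Trimmed pooled range is zero; normalized mean distance undefined."""


class InputError(TcrmdError):
    """Invalid user-supplied value (sequence, table entry, group sizes...)."""


class ConfigValidationError(TcrmdError):
    """Run configuration failed validation; carries every failure found."""

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))
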