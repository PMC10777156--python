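"""Exception hierarchy for peatstab.

All package errors derive from :class:`PeatstabError`; argument and
configuration problems are also ``ValueError`` subclasses so callers can
catch them generically.
"""

from __future__ import annotations


class PeatstabError(Exception):
    """Base class for all peatstab errors."""


class InvalidArgumentError(PeatstabError, ValueError):
    """An argument is outside its physically or logically valid range."""


class ConfigurationError(PeatstabError, ValueError):
    """A generator or pipeline configuration is incomplete or inconsistent."""


class InsufficientDataError(PeatstabError, ValueError):
    """Too few data points remain for the requested fit.

    Carries the number of points found and the number required.
    """

    def __init__(self, n_points: int, required: int, context: str = ""):
        self.n_points = n_points
        self.required = required
        msg = f"need at least {required} points, got {n_points}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class MissingPhaseError(PeatstabError, ValueError):
    """A required experimental phase is absent from a series."""

    def __init__(self, phase, mesocosm_id: str = ""):
        self.phase = phase
        self.mesocosm_id = mesocosm_id
        where = f" in mesocosm '{mesocosm_id}'" if mesocosm_id else ""
        super().__init__(f"required phase '{getattr(phase, 'value', phase)}' missing{where}")


class UndefinedBaselineError(PeatstabError, ValueError):
    """The acclimation-mean NEE is zero, so resistance is undefined."""


class PipelineError(PeatstabError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.__cause__ = cause
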