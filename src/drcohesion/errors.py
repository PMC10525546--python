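"""Exception hierarchy shared across the pipeline."""

from __future__ import annotations


class CohesionError(Exception):
    """Base class for all package errors."""


class RegistryError(CohesionError):
    """Invalid weight-registry document (duplicate name, bad weight, bad variable)."""


class UnknownLabelError(RegistryError):
    """A raw DR label did not resolve to any canonical registry entry."""

    def __init__(self, raw_label: str, candidates: list[str] | None = None):
        self.raw_label = raw_label
        self.candidates = candidates or []
        hint = f" (did you mean: {', '.join(self.candidates)}?)" if self.candidates else ""
        super().__init__(f"unknown discursive-repertoire label {raw_label!r}{hint}")


class RecordError(CohesionError):
    """A single occurrence/annotation record failed validation.

    Carries the record number (1-based, header excluded for CSV) so the
    offending line can be located in the source file.
    """

    def __init__(self, record_number: int, message: str):
        self.record_number = record_number
        super().__init__(f"record {record_number}: {message}")


class ConfigurationError(CohesionError):
    """Invalid user-supplied configuration (shares not summing to 1, empty keyword list, ...)."""


class EmptyWeekError(CohesionError):
    """No annotations fall inside the analysis week; the index is undefined."""


class StageError(CohesionError):
    """A pipeline stage failed; names the stage so the failure is locatable."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
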