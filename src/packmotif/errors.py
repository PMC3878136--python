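"""Exception hierarchy for the pipeline."""

from __future__ import annotations

__all__ = [
    "PackmotifError",
    "CifParseError",
    "GeometryError",
    "InferenceError",
    "GenerationError",
    "CorrespondenceError",
    "ConfigError",
]


class PackmotifError(Exception):
    """Base class for all pipeline errors."""


class CifParseError(PackmotifError):
    """A CIF document is missing a mandatory item or contains a malformed value."""


class GeometryError(PackmotifError):
    """Degenerate geometry (collinear plane set, non-positive-definite cell, ...)."""


class InferenceError(PackmotifError):
    """A derived quantity (e.g. Z) has no physically plausible value."""


class GenerationError(PackmotifError):
    """A synthetic crystal specification cannot be realized (e.g. steric clash)."""


class CorrespondenceError(PackmotifError):
    """No usable atom correspondence between two structures."""


class ConfigError(PackmotifError):
    """Invalid run configuration (unknown element radius, bad tolerance, ...)."""
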