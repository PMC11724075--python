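"""Exception hierarchy shared across the pipeline."""


class DimerScreenError(Exception):
    """Base class for all pipeline errors."""


class DataError(DimerScreenError, ValueError):
    """Malformed or non-finite input data."""


class LayoutError(DimerScreenError, ValueError):
    """Plate layout is inconsistent (non-rectangular, bad control placement)."""


class PatternError(DimerScreenError, ValueError):
    """A SMARTS/SMILES pattern failed to parse."""


class PackingError(DimerScreenError, RuntimeError):
    """Requested objects cannot be packed into the image canvas."""


class DegeneratePlateError(DimerScreenError, ValueError):
    """Plate residuals have zero robust scale; B-scores undefined."""


class InsufficientControlsError(DimerScreenError, ValueError):
    """Fewer control wells than the operation requires."""


class DegenerateControlsError(DimerScreenError, ValueError):
    """Positive and negative control means coincide; normalization undefined."""


class EmptySelectionError(DimerScreenError, ValueError):
    """Selection requested from an empty score set."""


class DegenerateLabelsError(DimerScreenError, ValueError):
    """Classifier training requires both activity classes."""


class ConfigError(DimerScreenError, ValueError):
    """Mismatched or invalid configuration (e.g. fingerprint parameters)."""


class NoSignalError(DimerScreenError, ValueError):
    """An image channel carries no signal (all-zero pixels)."""
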