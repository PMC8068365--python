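"""Exception hierarchy for picmontage.

Fatal conditions raise; per-file problems become skip diagnostics instead
(see :mod:`picmontage.dataset_discovery`).
"""


class PicmontageError(Exception):
    """Base class for all picmontage errors."""


class ConfigurationError(PicmontageError):
    """Invalid user configuration (dataset spec, contrast policy, render options)."""


class DatasetError(PicmontageError):
    """Fatal dataset-level problem (missing parent, no subfolders, no usable images)."""


class ImageReadError(PicmontageError):
    """A single image file could not be read or has an unsupported layout.

    Callers inside the discovery layer convert this into a skip diagnostic;
    it is only fatal when raised for a path the user named explicitly.
    """


class ContrastError(PicmontageError):
    """Contrast enhancement cannot proceed (e.g. mixed bit depths in one group)."""


class RenderError(PicmontageError):
    """Montage rendering failed (inconsistent tile sizes, bad color, ...)."""
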