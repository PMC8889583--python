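"""Exception hierarchy.

``BrnibError`` is the common base so callers (and the CLI) can distinguish
domain/data problems (exit code 3) from genuine usage errors (exit code 2).
"""


class BrnibError(Exception):
    """Base class for all package-specific errors."""


class Mol2FormatError(BrnibError):
    """A MOL2 file violates the dialect this package reads."""


class EmptyModelError(BrnibError):
    """A cavity model or pose has no atoms."""


class LabelOverlapError(BrnibError):
    """The active and decoy ID sets intersect."""


class MissingCompoundsError(BrnibError):
    """Labelled, non-skipped compounds are absent from the pose library."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "labelled compounds missing from pose library: " + ", ".join(self.missing)
        )


class UndefinedMetricError(BrnibError):
    """An enrichment metric was requested on a single-class ranking."""
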