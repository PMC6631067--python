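"""Exception hierarchy.

Exit-code mapping used by the CLI: bad input / malformed files -> 2,
degenerate data (constant columns, single-class labels, too-short
signals) -> 3.
"""


class HeartEdgeError(Exception):
    """Base class for all package errors."""


class BadInputError(HeartEdgeError):
    """Malformed or inconsistent user input (files, arguments)."""


class DegenerateDataError(HeartEdgeError):
    """Input that is structurally valid but statistically degenerate."""


# -- io ---------------------------------------------------------------------

class MultiChannelAudioError(BadInputError):
    """Audio file has more than one channel; mono PCG is required."""


class EmptyAudioError(BadInputError):
    """Audio file contains no samples."""


class LabelValueError(BadInputError):
    """Label value outside the dialect's alphabet."""


class DuplicateIdError(BadInputError):
    """Duplicate record id in a label file or dataset."""


class DatasetMismatchError(BadInputError):
    """Label ids and audio files do not match one-to-one."""


# -- features ---------------------------------------------------------------

class DegenerateSignalError(DegenerateDataError):
    """Signal on which a feature is undefined (e.g. constant squared signal)."""


class ShortSignalError(BadInputError):
    """Signal shorter than one analysis window."""


class FeatureExtractionError(HeartEdgeError):
    """Feature extraction failed for one or more records; carries the ids."""

    def __init__(self, failures):
        self.failures = dict(failures)
        ids = ", ".join(sorted(self.failures))
        super().__init__(f"feature extraction failed for: {ids}")
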