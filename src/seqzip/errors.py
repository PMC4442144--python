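"""Exception hierarchy for the seqzip toolkit."""


class SeqzipError(Exception):
    """Base class for all toolkit errors."""


class InvalidSequenceError(SeqzipError):
    """Sequence contains characters outside the DNA alphabet, or is too short."""


class AlignmentError(SeqzipError):
    """Probe and target cannot be aligned (e.g. unequal lengths)."""


class InfeasibleDesignError(SeqzipError):
    """No arm-length choice satisfies the design constraints.

    ``constraint`` names the first violated constraint (``"arm_tm"`` or
    ``"max_len"``).
    """

    def __init__(self, message: str, constraint: str):
        super().__init__(message)
        self.constraint = constraint


class DesignError(SeqzipError):
    """Gene model cannot be covered by a ligamer pool as requested."""


class CapacityError(SeqzipError):
    """More barcodes requested than the sequence space can hold."""


class SearchExhaustedError(SeqzipError):
    """Barcode search gave up after its attempt budget."""


class ModelError(SeqzipError):
    """Malformed gene model."""


class IndexingError(SeqzipError):
    """An isoform cannot be covered by an unbroken ligamer chain."""


class DecodeError(SeqzipError):
    """Decoder misuse (e.g. empty index)."""


class SimulationError(SeqzipError):
    """Invalid simulation request."""
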