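"""Exception types raised by the clustering pipeline."""


class SamspecError(Exception):
    """Base class for all package-specific errors."""


class DegenerateDataError(SamspecError):
    """All events are identical: no spatial extent in any dimension."""


class SamplingNonConvergenceError(SamspecError):
    """The adaptive neighbourhood-radius loop did not reach the target
    community-count range within the iteration budget.

    Carries the trace of attempted radii in ``h_trace``.
    """

    def __init__(self, message: str, h_trace: list[float]):
        super().__init__(message)
        self.h_trace = list(h_trace)


class DisconnectedVertexError(SamspecError):
    """A community has zero total similarity to the graph (zero degree)."""
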