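"""Exception types shared across the package."""


class SpecError(ValueError):
    """A cohort or pipeline specification violates its invariants."""


class AliasingError(SpecError):
    """A signal-model component frequency is at or above the Nyquist limit."""


class CohortFormatError(ValueError):
    """An on-disk cohort is malformed; the message names the offending part."""


class AllChannelsPrunedError(RuntimeError):
    """Channel pruning rejected every channel; the pipeline cannot proceed."""


class ConvergenceError(RuntimeError):
    """An iterative optimiser failed to converge; carries diagnostics."""
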