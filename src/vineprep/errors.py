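"""Package-specific exception types."""


class NoForegroundError(ValueError):
    """Raised when an operation requires foreground (non-black) pixels and a
    required region contains none."""


class IcaConvergenceError(RuntimeError):
    """Raised when FastICA fails to converge (e.g. rank-deficient or
    Gaussian-only patch matrices, on which ICA is unidentifiable)."""


class NetworkStructureError(ValueError):
    """Raised when declared layer dimensions disagree with the dimensions
    implied by convolution/pooling arithmetic; names the offending layer."""
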