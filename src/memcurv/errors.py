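"""Exception hierarchy.

All analysis failures raise subclasses of :class:`MemcurvError` so the CLI
can map them to a single non-zero exit code while tests can assert on the
specific failure mode.
"""


class MemcurvError(Exception):
    """Base class for all analysis errors."""


class LeafletError(MemcurvError):
    """Leaflet partition did not yield exactly two connected components."""

    def __init__(self, n_components: int, message: str | None = None):
        self.n_components = n_components
        super().__init__(
            message
            or f"leaflet graph has {n_components} connected component(s); expected 2"
        )


class LocalFrameError(MemcurvError):
    """Too few marker beads near a query point to define a local frame."""


class MidlineError(MemcurvError):
    """Midline trace failed to close or hit the step budget."""


class SpectraError(MemcurvError):
    """Midline too short, ambiguous unwrapping, or degenerate parameterization."""


class FitError(MemcurvError):
    """Nonlinear fit failed to converge from any starting point."""
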