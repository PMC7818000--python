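"""Exceptions raised by the analysis layer.

These signal a *structural* property of the optical system (e.g. no finite
aperture anywhere), not a numerical failure; callers such as the CLI map
them to a distinct exit code.
"""


class AnalysisError(Exception):
    """The path lacks the structure an analysis operation needs."""


class NoApertureStop(AnalysisError):
    """No finite aperture limits the on-axis ray bundle."""


class NoFieldStop(AnalysisError):
    """No aperture limits the chief ray: the field of view is unbounded."""


class StopConjugateToObject(AnalysisError):
    """The aperture stop is conjugate to the object plane, so the axial and
    chief rays are not defined by a finite linear solve."""


class DegenerateBasis(AnalysisError):
    """The principal/axial ray pair has zero Lagrange invariant and cannot
    serve as a decomposition basis."""
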