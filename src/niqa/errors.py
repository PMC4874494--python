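"""Exceptions and warning categories used across the pipeline.

Hard failures (exceptions) terminate the analysis, mirroring the behaviour
of the original algorithm on non-orthogonal slices or degenerate sphere
arrangements.  Soft anomalies (warning categories) are issued through the
:mod:`warnings` machinery and additionally collected into result objects so
they end up in the final report.
"""

from __future__ import annotations


class NiqaError(Exception):
    """Base class for all niqa-specific failures."""


class MalformedSeriesError(NiqaError):
    """A DICOM series is missing required geometry tags."""


class IrregularSeriesError(NiqaError):
    """Inter-slice spacing of a DICOM series varies beyond tolerance."""


class NonOrthogonalSlicesError(NiqaError):
    """Image Orientation (Patient) entries are not all in {-1, 0, +1}."""

    def __init__(self, orientation):
        self.orientation = orientation
        super().__init__(
            "image slices are not orthogonal to the patient axes; "
            f"offending direction cosines: {orientation!r}"
        )


class DegenerateTemplateError(NiqaError):
    """Template rasterization produced an empty mask."""


class TemplateTooLargeError(NiqaError):
    """Matched-filter template does not fit inside the volume anywhere."""


class NoConcaveNeighborhoodError(NiqaError):
    """No strictly concave-down profile neighborhood exists at the argmax."""


class DegenerateFitError(NiqaError):
    """Quadratic least-squares system is singular."""


class DegenerateArrangementError(NiqaError):
    """Three sphere centers are (near-)collinear; no isometry can be fit."""


class WallModelError(NiqaError):
    """No voxels could be labeled as plastic sphere wall."""


class MappingOutOfBoundsError(NiqaError):
    """A mapped sphere lies entirely outside the PET volume."""


class EmptyROIError(NiqaError):
    """A sphere ROI covers no voxels."""


class NiqaWarning(UserWarning):
    """Base class for all niqa warning categories."""


class MultipleMaximaWarning(NiqaWarning):
    """Several positions share the maximum matched value; first one used."""


class NonConcaveFitWarning(NiqaWarning):
    """Quadratic fit Hessian is not negative definite; argmax used."""


class NoConcaveNeighborhoodWarning(NiqaWarning):
    """Concave subset unavailable; fell back to a 3x3x3 box."""


class ClippedBoxWarning(NiqaWarning):
    """A bounding box was clipped at the volume edge."""


class BoundaryMaxWarning(NiqaWarning):
    """Matched-value maximum lies on the boundary of the search space."""


class VertexFarFromMaxWarning(NiqaWarning):
    """Quadratic vertex is more than two indices from the grid argmax."""


class BoundaryWarning(NiqaWarning):
    """A mapped sphere center lies outside the PET volume bounds."""


class ROIClippedWarning(NiqaWarning):
    """A sphere ROI is clipped by the volume boundary."""
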