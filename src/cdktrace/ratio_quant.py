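"""Cytoplasmic:nuclear DHB-ratio quantification.

The CDK-activity readout is the ratio of the mean sensor intensity in a
perinuclear cytoplasmic patch to the mean intensity in a nuclear toroid
(an annular ROI that excludes the nucleolus, where the sensor does not
localize).  Images are background-subtracted first with a rolling-ball
style morphological filter to remove camera amplifier offset and residual
out-of-focus light.

Trace-level conventions implemented here:

* ``snapshot_ratio`` — the G1 snapshot convention: read the ratio at the
  sample nearest a query time, by default 25 min after anaphase.
* ``classify_cdklow_by_threshold`` — the fixed-threshold quiescence call
  used for zebrafish tailbud traces: a cell is CDK^low when its ratio
  stays strictly below 0.19 for three or more consecutive post-anaphase
  frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import CoverageError, DegenerateMeasurementError, RoiError
from .traces import CdkTrace

CDK_LOW = "CDK_low"
CDK_INC = "CDK_inc"

#: default rolling-ball radius, in pixels of the processed image
DEFAULT_ROLLING_BALL_RADIUS = 50

#: default fixed threshold / run length for the CDK^low quiescence call
CDKLOW_THRESHOLD = 0.19
CDKLOW_MIN_FRAMES = 3

#: default G1 snapshot time, minutes after anaphase
G1_SNAPSHOT_MIN = 25.0


@dataclass(frozen=True)
class RoiMeasurement:
    """Nuclear / cytoplasmic mean intensities and their ratio for one cell
    at one timepoint.  ``ratio`` is exactly ``cyto_mean / nuc_mean``."""

    cell_id: str
    time_min: float
    nuc_mean: float
    cyto_mean: float

    @property
    def ratio(self) -> float:
        return self.cyto_mean / self.nuc_mean


def rolling_ball_subtract(image: np.ndarray,
                          radius: int = DEFAULT_ROLLING_BALL_RADIUS) -> np.ndarray:
    """Subtract a smooth background estimated by grayscale opening.

    The background is the morphological opening of the image with a flat
    disk footprint of the given radius (applied as a decomposed footprint
    sequence for speed): any bright structure narrower than the disk is
    excluded from the background estimate and therefore keeps its full
    contrast, while a constant offset (camera baseline) and slowly varying
    shading are removed.  To keep the estimate off the noise floor, the
    background is computed on a 3x3-mean presmoothed copy (as rolling-ball
    implementations conventionally do) and subtracted from the original.
    A flat image maps to all zeros, and adding a constant to the input
    leaves the output unchanged.  Output is clipped at zero.

    Parameters
    ----------
    image
        2-D non-negative intensity array.
    radius
        Footprint radius in pixels of the processed image; must be > 0.
        Default 50.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {image.ndim}-D")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    smoothed = ndimage.uniform_filter(image, size=3, mode="nearest")
    footprint = morphology.disk(int(radius), decomposition="sequence")
    background = morphology.opening(smoothed, footprint=footprint)
    return np.clip(image - background, 0.0, None)


def measure_cell(image: np.ndarray, nuclear_toroid_mask: np.ndarray,
                 cyto_patch_mask: np.ndarray, cell_id: str,
                 time_min: float) -> RoiMeasurement:
    """Mean-intensity measurement over the two ROIs of one cell.

    ``nuc_mean`` is the mean gray value over the nuclear toroid,
    ``cyto_mean`` over the cytoplasmic patch; the ratio is cyto/nuc.
    Masks must be nonempty, disjoint, and the same shape as the image.
    A zero nuclear mean raises :class:`DegenerateMeasurementError` (the
    ratio would be undefined — typically over-aggressive background
    subtraction).
    """
    image = np.asarray(image, dtype=float)
    nuc = np.asarray(nuclear_toroid_mask) != 0
    cyto = np.asarray(cyto_patch_mask) != 0
    if nuc.shape != image.shape or cyto.shape != image.shape:
        raise RoiError("mask shape does not match image shape")
    if not nuc.any():
        raise RoiError("nuclear toroid mask is empty")
    if not cyto.any():
        raise RoiError("cytoplasmic patch mask is empty")
    if (nuc & cyto).any():
        raise RoiError("nuclear and cytoplasmic masks overlap")
    nuc_mean = float(image[nuc].mean())
    cyto_mean = float(image[cyto].mean())
    if nuc_mean == 0:
        raise DegenerateMeasurementError(
            f"cell {cell_id!r} t={time_min}: nuclear mean is 0; ratio undefined")
    return RoiMeasurement(cell_id=cell_id, time_min=float(time_min),
                          nuc_mean=nuc_mean, cyto_mean=cyto_mean)


def snapshot_ratio(trace: CdkTrace, t_query: float = G1_SNAPSHOT_MIN,
                   tolerance_min: float | None = None) -> float:
    """Ratio at the sample nearest ``t_query`` (default 25 min post-anaphase).

    Lookup is nearest-neighbor with no interpolation.  If the nearest
    sample is farther from ``t_query`` than one sampling interval (or the
    explicit ``tolerance_min``), the trace does not cover the query time
    and :class:`CoverageError` is raised.
    """
    if tolerance_min is None:
        tolerance_min = trace.sampling_interval if len(trace) > 1 else 0.0
    dist = np.abs(trace.times - t_query)
    i = int(np.argmin(dist))
    if dist[i] > tolerance_min:
        raise CoverageError(
            f"trace {trace.cell_id!r}: nearest sample to t={t_query} is at "
            f"t={trace.times[i]} (> {tolerance_min} min away)")
    return float(trace.ratios[i])


def classify_cdklow_by_threshold(trace: CdkTrace,
                                 threshold: float = CDKLOW_THRESHOLD,
                                 min_frames: int = CDKLOW_MIN_FRAMES) -> str:
    """Fixed-threshold quiescence call on one trace.

    The cell is ``CDK_low`` iff some run of at least ``min_frames``
    consecutive post-anaphase samples (t >= 0) all lie strictly below the
    threshold; otherwise ``CDK_inc``.  Defaults are the zebrafish tailbud
    rule: below 0.19 for three or more frames.
    """
    _, ratios = trace.post_anaphase()
    if ratios.size < min_frames:
        raise CoverageError(
            f"trace {trace.cell_id!r}: {ratios.size} post-anaphase samples, "
            f"need >= {min_frames}")
    below = ratios < threshold
    run = 0
    for b in below:
        run = run + 1 if b else 0
        if run >= min_frames:
            return CDK_LOW
    return CDK_INC
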