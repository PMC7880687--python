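"""Synthetic CDK-sensor data with known ground truth.

Two generators:

* :func:`simulate_traces` — anaphase-aligned DHB-ratio traces sampled every
  5 min, with a mother-cell G2 peak (maximal nuclear exclusion of the
  sensor just before mitosis), a sharp drop at anaphase, and divergence of
  the daughters into a rising CDK^inc (proliferative, G1) branch versus a
  flat CDK^low (quiescent, G0) branch.  Default class parameters follow the
  means +/- SD measured in vivo: G0 around 0.13 +/- 0.04, G1 birth around
  0.35, G2 peak around 1.0 for the GFP sensor.

* :func:`simulate_cell_image` — a single-plane grayscale cell image
  (background field + nucleus disk with a nucleolus hole + perinuclear
  cytoplasm annulus + Gaussian read noise) together with the nuclear-toroid
  and cytoplasmic-patch ROI masks and the known true cyto/nuc ratio, for
  end-to-end tests of the ratio quantification pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .traces import PROLIFERATIVE, QUIESCENT, CdkTrace, TraceSet

# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------


@dataclass
class TraceSimConfig:
    """Parameters of the two-fate trace generator.

    Ratios are dimensionless cytoplasmic:nuclear DHB ratios; times are
    minutes relative to anaphase.  Defaults mirror published in vivo
    values: quiescent (G0) cells at 0.13 +/- 0.04, cycling daughters born
    near 0.35 and rising through G1/S, mothers peaking near 1.0 in G2.
    """

    n_traces_per_class: int = 100
    dt_min: float = 5.0
    t_start_min: float = -20.0
    t_end_min: float = 120.0
    g2_peak_mean: float = 1.0
    g1_birth_mean: float = 0.35
    g0_mean: float = 0.13
    inc_slope: float = 0.008  # ratio per minute; ~0.35 -> ~1.0 over 80 min
    inc_birth_sd: float = 0.13  # cross-cell SD of the CDK^inc birth ratio
    noise_sd: float = 0.04
    noise_ar1: float = 0.0  # lag-1 autocorrelation of ratio noise (0 = white)
    short_trace_fraction: float = 0.25  # truncated to 20-60 min post-anaphase
    lineage_offsets: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_traces_per_class < 1:
            raise ConfigurationError("n_traces_per_class must be >= 1")
        if self.dt_min <= 0:
            raise ConfigurationError("dt_min must be > 0")
        if not (self.t_start_min < 0 < self.t_end_min):
            raise ConfigurationError("require t_start_min < 0 < t_end_min")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.inc_birth_sd < 0:
            raise ConfigurationError("inc_birth_sd must be >= 0")
        if not (self.g0_mean <= self.g1_birth_mean <= self.g2_peak_mean):
            raise ConfigurationError("require g0_mean <= g1_birth_mean <= g2_peak_mean")
        if not (self.g0_mean < self.g2_peak_mean):
            raise ConfigurationError("require g0_mean < g2_peak_mean")
        if not (0.0 <= self.short_trace_fraction <= 1.0):
            raise ConfigurationError("short_trace_fraction must be in [0, 1]")
        if not (0.0 <= self.noise_ar1 < 1.0):
            raise ConfigurationError("noise_ar1 must be in [0, 1)")


def _noise(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    """Stationary Gaussian noise with SD ``sd``; AR(1) when ar1 > 0."""
    if sd == 0:
        return np.zeros(n)
    if ar1 == 0:
        return rng.normal(0.0, sd, size=n)
    innov_sd = sd * math.sqrt(1.0 - ar1 * ar1)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        eps[i] = ar1 * eps[i - 1] + rng.normal(0.0, innov_sd)
    return eps


def _mean_curve(cfg: TraceSimConfig, times: np.ndarray, fate: str) -> np.ndarray:
    """Noise-free ratio trajectory for one fate class."""
    vals = np.empty_like(times)
    pre = times < 0
    # mother G2: ramp up to maximal nuclear exclusion right before anaphase
    span = -cfg.t_start_min
    vals[pre] = cfg.g2_peak_mean * (1.0 - 0.2 * (-times[pre]) / span)
    post = ~pre
    if fate == PROLIFERATIVE:
        vals[post] = cfg.g1_birth_mean + cfg.inc_slope * times[post]
    else:
        vals[post] = cfg.g0_mean
    return vals


def simulate_traces(cfg: TraceSimConfig) -> TraceSet:
    """Generate ``n_traces_per_class`` traces per fate class.

    Every trace has a sample at t = 0.  Proliferative (CDK^inc) daughters
    are born at ``g1_birth_mean`` plus a per-cell offset with SD
    ``inc_birth_sd`` — mirroring the much larger cross-cell spread of G1
    ratios than of G0 ratios seen in vivo — and rise with ``inc_slope``;
    quiescent (CDK^low) daughters fluctuate around ``g0_mean``.  Because
    the offset is shared along a trace while the branches diverge, fate is
    partly ambiguous shortly after anaphase and increasingly predictable
    later, as in the recordings this emulates.  A configurable fraction of
    traces is truncated to end between 20 and 60 min post-anaphase, so
    both the long-trace (post-60-min) and short-trace
    (last-three-timepoints) classification rules are exercised downstream.
    Identical seeds give identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_pre = int(round(-cfg.t_start_min / cfg.dt_min))
    n_post = int(round(cfg.t_end_min / cfg.dt_min))
    full_times = cfg.dt_min * np.arange(-n_pre, n_post + 1)

    # candidate truncation points: grid times in [20, 60] min post-anaphase
    short_ends = full_times[(full_times >= 20.0) & (full_times <= 60.0)]
    lineages = list(cfg.lineage_offsets) or ["sim"]

    traces: list[CdkTrace] = []
    for fate, tag in ((PROLIFERATIVE, "prolif"), (QUIESCENT, "quies")):
        base = _mean_curve(cfg, full_times, fate)
        for i in range(cfg.n_traces_per_class):
            lineage = lineages[i % len(lineages)]
            offset = cfg.lineage_offsets.get(lineage, 0.0)
            vals = base + offset + _noise(rng, full_times.size, cfg.noise_sd,
                                          cfg.noise_ar1)
            if fate == PROLIFERATIVE and cfg.inc_birth_sd > 0:
                # per-cell birth-ratio offset, shared along the whole
                # post-anaphase branch
                vals[full_times >= 0] += rng.normal(0.0, cfg.inc_birth_sd)
            times = full_times
            if short_ends.size and rng.random() < cfg.short_trace_fraction:
                t_end = rng.choice(short_ends)
                keep = times <= t_end
                times, vals = times[keep], vals[keep]
            traces.append(CdkTrace(
                cell_id=f"{tag}_{i:04d}",
                times=times.copy(),
                ratios=np.clip(vals, 0.0, None),
                lineage=lineage,
                fate=fate,
            ))
    return TraceSet(traces)


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------


@dataclass
class ImageSimConfig:
    """Parameters of the synthetic single-cell image renderer.

    Intensities are arbitrary units.  ``read_noise_sd`` emulates EM-CCD
    amplifier noise; ``shading_amplitude`` adds a slowly varying background
    field on top of the constant ``background_mean``.
    """

    image_shape: tuple[int, int] = (128, 128)
    nucleus_radius: float = 20.0
    nucleolus_radius: float = 6.0
    cyto_outer_radius: float = 32.0
    nuc_mean: float = 100.0
    cyto_mean: float = 50.0
    background_mean: float = 10.0
    read_noise_sd: float = 2.0
    shading_amplitude: float = 5.0
    mask_margin_px: int = 2  # conservative ROI margin away from compartment edges
    seed: int = 0

    def validate(self) -> None:
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ConfigurationError("image_shape must be 2-D and at least 8x8")
        if not (0 < self.nucleolus_radius < self.nucleus_radius < self.cyto_outer_radius):
            raise ConfigurationError(
                "require 0 < nucleolus_radius < nucleus_radius < cyto_outer_radius")
        if 2 * self.cyto_outer_radius >= min(self.image_shape):
            raise ConfigurationError("cell does not fit in the image")
        for name in ("nuc_mean", "cyto_mean", "background_mean"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.read_noise_sd < 0 or self.shading_amplitude < 0:
            raise ConfigurationError("noise and shading amplitudes must be >= 0")
        if self.nuc_mean == 0:
            raise ConfigurationError("nuc_mean must be > 0 for a defined ratio")


def simulate_cell_image(cfg: ImageSimConfig
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Render one cell and its ROI masks.

    Returns ``(image, nuclear_toroid_mask, cyto_patch_mask, true_ratio)``.
    The image is background field + nucleus disk at ``nuc_mean`` (with the
    nucleolus left at background level, since the sensor does not localize
    there) + cytoplasm annulus at ``cyto_mean`` + Gaussian read noise.
    Masks are uint8 (nonzero = in mask), eroded by ``mask_margin_px`` from
    every compartment boundary, mutually disjoint, and exclude both the
    nucleolus and all pixels outside the cell.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)

    # slowly varying shading: diagonal gradient spanning [0, amplitude]
    image = cfg.background_mean + cfg.shading_amplitude * (xx + yy) / (h + w - 2)
    nucleus = (r <= cfg.nucleus_radius) & (r > cfg.nucleolus_radius)
    annulus = (r > cfg.nucleus_radius) & (r <= cfg.cyto_outer_radius)
    image = image + cfg.nuc_mean * nucleus + cfg.cyto_mean * annulus
    if cfg.read_noise_sd > 0:
        image = image + rng.normal(0.0, cfg.read_noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)

    m = cfg.mask_margin_px
    toroid = (r <= cfg.nucleus_radius - m) & (r > cfg.nucleolus_radius + m)
    patch = (r > cfg.nucleus_radius + m) & (r <= cfg.cyto_outer_radius - m)
    true_ratio = cfg.cyto_mean / cfg.nuc_mean
    return (image, (toroid * np.uint8(255)), (patch * np.uint8(255)), true_ratio)
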