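"""Proximity-ligation-assay (PLA) event calling and counting.

A PLA produces one diffraction-limited fluorescent spot per detected
receptor-ligand interaction.  Quantification follows the workflow used for
confocal z-stacks of vessel cross-sections:

1. collapse the z-stack to its maximum-intensity projection;
2. place six regions of interest (ROIs) per image: three polygon bands drawn
   along the vessel lumen reaching 5 um into the tunica intima (enveloping
   the endothelium) and three circles inside the tunica media, spaced 120
   degrees apart;
3. threshold the projection at a fixed gray value (default 100 on 8-bit
   images) and extract connected components (8-connectivity);
4. components of 2-50 px count as one interaction event each; larger blobs
   are treated as merged events and contribute ``round(area / 10)`` events,
   10 px being the median single-event size;
5. densities (events per mm2 of ROI) are corrected by subtracting the
   matching negative-control density measured with identical rules.

Component sizes are interpreted as pixel *areas* throughout: that is the only
reading under which a median event size of 10 px, a 2-50 px gate and an
``area / 10`` merge rule are mutually coherent.  A blob straddling an ROI
boundary is assigned to the ROI containing its centroid, with its full area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure

from .stats import timecourse_summary

__all__ = [
    "ImageStack",
    "ROI",
    "ParticleRecord",
    "max_project",
    "place_rois",
    "detect_particles",
    "count_events",
    "background_correct",
    "measure_pla_specimen",
    "pla_timecourse",
    "LUMEN",
    "INTIMA",
    "MEDIA",
]

# Segmentation label conventions for vessel cross-sections.
LUMEN, INTIMA, MEDIA = 1, 2, 3

DEFAULT_THRESHOLD = 100      # gray values, 8-bit scale
DEFAULT_MIN_AREA = 2         # px; single-pixel components are discarded
DEFAULT_SINGLE_MAX_AREA = 50 # px; larger blobs are treated as merged events
DEFAULT_MEDIAN_SPOT_AREA = 10  # px; median size of a single PLA event


# ---------------------------------------------------------------------------
# image container and projection
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A z-stack of grayscale images with physical pixel metadata.

    ``data`` has shape ``(n_slices, rows, cols)``; a 2-D array is promoted to
    a single-slice stack.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    z_step_um: float = 2.0
    channel: str = "pla"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError("image stack must be 2-D or 3-D")
        if arr.shape[0] < 1:
            raise ValueError("image stack needs at least one slice")
        self.data = arr
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be > 0")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape[1:]

    def max_projection(self) -> np.ndarray:
        return max_project(self)

    def save(self, path) -> None:
        tifffile.imwrite(path, self.data, photometric="minisblack")

    @classmethod
    def load(cls, path, pixel_size_um=1.0, z_step_um=2.0, channel="pla", meta=None):
        return cls(
            data=tifffile.imread(path),
            pixel_size_um=pixel_size_um,
            z_step_um=z_step_um,
            channel=channel,
            meta=meta or {},
        )


def max_project(stack) -> np.ndarray:
    """Pixelwise maximum across the slices of a z-stack.

    Accepts an :class:`ImageStack`, a 3-D ``(z, rows, cols)`` array, or a 2-D
    image (returned unchanged).  Slices of mismatched shape are rejected by
    array construction.
    """
    arr = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("expected a (z, rows, cols) stack with >= 1 slice")
    return arr.max(axis=0)


# ---------------------------------------------------------------------------
# regions of interest
# ---------------------------------------------------------------------------

@dataclass
class ROI:
    """A measurement region, held as a boolean pixel mask.

    ``shape_kind`` records whether the ROI originated as a polygon (the
    endothelial bands) or a circle (the media ROIs); geometry-file import
    builds the same masks from vertices or center+radius.
    """

    roi_id: str
    compartment: str
    mask: np.ndarray
    pixel_size_um: float = 1.0
    shape_kind: str = "polygon"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.roi_id!r} has an empty mask")
        if self.compartment not in ("endothelium", "media"):
            raise ValueError("compartment must be 'endothelium' or 'media'")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * (self.pixel_size_um / 1000.0) ** 2

    @classmethod
    def from_circle(cls, roi_id, compartment, center_rc, radius_px, image_shape,
                    pixel_size_um=1.0):
        rr, cc = np.ogrid[: image_shape[0], : image_shape[1]]
        mask = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px**2
        return cls(roi_id, compartment, mask, pixel_size_um, shape_kind="circle")

    @classmethod
    def from_polygon(cls, roi_id, compartment, vertices_rc, image_shape,
                     pixel_size_um=1.0):
        from skimage.draw import polygon2mask

        vertices = np.asarray(vertices_rc, dtype=float)
        mask = polygon2mask(image_shape, vertices)
        return cls(roi_id, compartment, mask, pixel_size_um, shape_kind="polygon")


def _angular_distance(angles, center):
    """Smallest absolute difference between angles, radians."""
    d = np.mod(angles - center + math.pi, 2 * math.pi) - math.pi
    return np.abs(d)


def place_rois(
    segmentation: np.ndarray,
    pixel_size_um: float,
    band_depth_um: float = 5.0,
    arc_deg: float = 100.0,
    n_per_compartment: int = 3,
    circle_area_mm2: float | None = None,
    area_bounds_mm2: tuple[float, float] | None = None,
    angle_offset_deg: float = 0.0,
) -> list[ROI]:
    """Place the standard 3 + 3 ROIs on a lumen/intima/media segmentation.

    Three polygon bands hug the lumen boundary, extending
    ``round(band_depth_um / pixel_size_um)`` px into the intima, centered at
    ``angle_offset_deg`` plus multiples of 360/n degrees and spanning
    ``arc_deg`` each.  Three circles sit at the same angles, centered on the
    local mid-media radius.  ``angle_offset_deg`` is the angular anchor an
    analyst would choose when drawing by hand; shifting it together with a
    rotation of the segmentation rotates all ROIs rigidly.

    Parameters
    ----------
    segmentation : int array
        Label image with 1 = lumen, 2 = intima, 3 = media, 0 = background.
    circle_area_mm2 : float, optional
        Target area of each media circle.  Defaults to the largest circle
        with diameter 0.85x the local media thickness.
    area_bounds_mm2 : (lo, hi), optional
        If given, every ROI area must fall inside; out-of-bounds ROIs raise.

    Raises
    ------
    ValueError
        If the media is too thin for the requested circle area (the message
        names the maximum feasible area), or an ROI violates the area bounds.
    """
    seg = np.asarray(segmentation)
    lumen = seg == LUMEN
    intima = seg == INTIMA
    media = seg == MEDIA
    for name, mask in (("lumen", lumen), ("intima", intima), ("media", media)):
        if not mask.any():
            raise ValueError(f"segmentation has no {name} pixels")

    cy, cx = ndimage.center_of_mass(lumen)
    depth_px = max(1, round(band_depth_um / pixel_size_um))
    dist_from_lumen = ndimage.distance_transform_edt(~lumen)

    rr, cc = np.indices(seg.shape)
    angles = np.arctan2(rr - cy, cc - cx)

    band = intima & (dist_from_lumen <= depth_px)
    half_arc = math.radians(arc_deg) / 2.0
    step = 2 * math.pi / n_per_compartment
    offset = math.radians(angle_offset_deg)

    rois: list[ROI] = []
    for i in range(n_per_compartment):
        center_angle = offset + i * step
        sector = _angular_distance(angles, center_angle) <= half_arc
        mask = band & sector
        if not mask.any():
            raise ValueError(f"endothelial band sector {i} is empty")
        rois.append(
            ROI(f"endo_{i}", "endothelium", mask, pixel_size_um, shape_kind="polygon")
        )

    radial = np.hypot(rr - cy, cc - cx)
    for i in range(n_per_compartment):
        center_angle = offset + i * step
        wedge = media & (_angular_distance(angles, center_angle) <= math.radians(15))
        if not wedge.any():
            raise ValueError(f"media wedge {i} is empty")
        r_in = np.quantile(radial[wedge], 0.02)
        r_out = np.quantile(radial[wedge], 0.98)
        thickness = r_out - r_in
        max_radius = 0.425 * thickness
        if circle_area_mm2 is None:
            radius_px = math.floor(max_radius)
        else:
            radius_px = math.sqrt(circle_area_mm2 * 1e6 / math.pi) / pixel_size_um
        if radius_px > max_radius or radius_px < 1:
            max_area = math.pi * (max_radius * pixel_size_um / 1000.0) ** 2
            raise ValueError(
                "media too thin for the requested circle area; "
                f"maximum feasible area is {max_area:.6f} mm2"
            )
        r_c = 0.5 * (r_in + r_out)
        center = (cy + r_c * math.sin(center_angle), cx + r_c * math.cos(center_angle))
        roi = ROI.from_circle(f"media_{i}", "media", center, radius_px, seg.shape,
                              pixel_size_um)
        outside = roi.mask & ~media
        if outside.sum() > 0.02 * roi.area_px:
            raise ValueError(f"media circle {i} does not fit inside the media")
        rois.append(roi)

    combined = np.zeros(seg.shape, dtype=np.uint8)
    for roi in rois:
        combined += roi.mask
    if (combined > 1).any():
        raise ValueError("placed ROIs overlap")

    if area_bounds_mm2 is not None:
        lo, hi = area_bounds_mm2
        for roi in rois:
            if not lo <= roi.area_mm2 <= hi:
                raise ValueError(
                    f"ROI {roi.roi_id!r} area {roi.area_mm2:.6f} mm2 outside "
                    f"bounds [{lo}, {hi}]"
                )
    return rois


# ---------------------------------------------------------------------------
# particle detection and event counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleRecord:
    """One above-threshold connected component assigned to an ROI."""

    label: int
    centroid: tuple
    area_px: int
    peak: float
    roi_id: str


def _label_components(image, threshold, min_area, connectivity):
    """Connected components of {pixel >= threshold}; area-gated.

    Returns a list of (label, centroid, area, peak) tuples.
    """
    img = np.asarray(image)
    if img.dtype == np.uint8 and not 0 <= threshold <= 255:
        raise ValueError("threshold outside the 8-bit range")
    labels = measure.label(img >= threshold, connectivity=connectivity)
    out = []
    for prop in measure.regionprops(labels, intensity_image=img):
        if prop.area < min_area:
            continue
        out.append((prop.label, prop.centroid, int(prop.area), float(prop.intensity_max)))
    return out


def detect_particles(
    image: np.ndarray,
    roi: ROI,
    threshold: int = DEFAULT_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
    connectivity: int = 2,
) -> list[ParticleRecord]:
    """Above-threshold particles belonging to one ROI.

    Components are labeled on the full image (8-connectivity by default;
    ``connectivity=1`` for 4-connectivity) and assigned to the ROI containing
    their centroid, so a spot straddling the ROI edge keeps its full area.
    Components smaller than ``min_area`` (default 2 px) are discarded.  An
    empty result is valid.
    """
    components = _label_components(image, threshold, min_area, connectivity)
    return _assign_to_roi(components, roi)


def _assign_to_roi(components, roi: ROI) -> list[ParticleRecord]:
    records = []
    nrows, ncols = roi.mask.shape
    for label, centroid, area, peak in components:
        r = min(max(int(round(centroid[0])), 0), nrows - 1)
        c = min(max(int(round(centroid[1])), 0), ncols - 1)
        if roi.mask[r, c]:
            records.append(ParticleRecord(label, centroid, area, peak, roi.roi_id))
    return records


def count_events(
    particles,
    single_max_area: int = DEFAULT_SINGLE_MAX_AREA,
    median_spot_area: int = DEFAULT_MEDIAN_SPOT_AREA,
    fractional: bool = False,
):
    """Number of PLA events represented by a set of particles.

    A particle of area <= ``single_max_area`` px is one event.  A larger
    particle is a merger of several events and contributes
    ``area / median_spot_area`` events, rounded to the nearest integer with
    ties rounding up (``fractional=True`` keeps the quotient unrounded for
    sensitivity analyses).
    """
    total = 0.0
    for p in particles:
        area = p.area_px if isinstance(p, ParticleRecord) else int(p)
        if area <= single_max_area:
            total += 1
        elif fractional:
            total += area / median_spot_area
        else:
            total += math.floor(area / median_spot_area + 0.5)
    return total if fractional else int(total)


def background_correct(raw_density: float, control_density: float) -> float:
    """Background-corrected event density: raw minus matched negative control.

    Negative results are retained (not clamped) so that group means stay
    unbiased; callers flag them.
    """
    return float(raw_density) - float(control_density)


# ---------------------------------------------------------------------------
# specimen-level quantification and time-course summaries
# ---------------------------------------------------------------------------

def _roi_table(image, rois, threshold, min_area, single_max_area,
               median_spot_area, connectivity):
    """Per-ROI particle and event counts for one projected image."""
    components = _label_components(image, threshold, min_area, connectivity)
    rows = []
    for roi in rois:
        particles = _assign_to_roi(components, roi)
        n_events = count_events(particles, single_max_area, median_spot_area)
        rows.append(
            {
                "roi_id": roi.roi_id,
                "compartment": roi.compartment,
                "area_mm2": roi.area_mm2,
                "particle_count": len(particles),
                "event_count": n_events,
                "density": n_events / roi.area_mm2,
            }
        )
    return pd.DataFrame(rows)


def measure_pla_specimen(
    pla_stack,
    control_stack,
    rois,
    threshold: int = DEFAULT_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
    single_max_area: int = DEFAULT_SINGLE_MAX_AREA,
    median_spot_area: int = DEFAULT_MEDIAN_SPOT_AREA,
    connectivity: int = 2,
    keys: dict | None = None,
) -> pd.DataFrame:
    """Quantify one specimen: PLA z-stack plus its matched negative control.

    Both stacks are max-projected and counted with identical threshold and
    size rules.  Per-ROI densities are averaged per compartment; the control
    density of the same compartment is subtracted.

    Returns one row per compartment with columns ``raw_density``,
    ``control_density``, ``corrected_density`` (events/mm2) and a
    ``negative_flag`` marking corrections that went below zero, plus any
    ``keys`` (rat, day, pair, ...) passed through.
    """
    if control_stack is None:
        raise ValueError(
            f"missing negative control for specimen {keys or '<unnamed>'}"
        )
    args = (threshold, min_area, single_max_area, median_spot_area, connectivity)
    raw = _roi_table(max_project(pla_stack), rois, *args)
    ctrl = _roi_table(max_project(control_stack), rois, *args)
    rows = []
    for compartment in ("endothelium", "media"):
        r = raw[raw["compartment"] == compartment]
        c = ctrl[ctrl["compartment"] == compartment]
        if r.empty:
            continue
        raw_d = float(r["density"].mean())
        ctrl_d = float(c["density"].mean())
        corrected = background_correct(raw_d, ctrl_d)
        row = dict(keys or {})
        row.update(
            compartment=compartment,
            n_rois=len(r),
            particle_count=int(r["particle_count"].sum()),
            event_count=float(r["event_count"].sum()),
            raw_density=raw_d,
            control_density=ctrl_d,
            corrected_density=corrected,
            negative_flag=corrected < 0,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pla_timecourse(
    event_table: pd.DataFrame,
    baseline_day: int = -1,
    value: str = "corrected_density",
) -> pd.DataFrame:
    """Per-pair, per-compartment, per-day group mean +/- SE of corrected
    density, with percent change versus the pre-fistula baseline group mean.

    ``event_table`` is long-format with at least ``pair, compartment, day``
    and the value column (one row per specimen and compartment).
    """
    return timecourse_summary(
        event_table, value=value, by=["pair", "compartment"], baseline_day=baseline_day
    )
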