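"""Seeded synthetic study generator: flow traces, vessel geometries and
phantom microscopy z-stacks with known ground truth.

The generator emulates the measurable surfaces of a rat carotid-jugular
arteriovenous fistula (AVF) study so that every downstream stage — Poiseuille
shear estimation, immunofluorescence (IF) quantification, proximity-ligation
(PLA) spot counting and the time-course statistics — can be exercised and
validated against known truth without any external data:

* pulsatile flow traces whose session mean rises from a 5.2 mL/min carotid
  baseline by a factor 2.4 at fistula creation (day 0) and then linearly to
  an 11-fold plateau at day 42;
* vessel radii solved from the inverse Poiseuille relation so that the
  forward shear computation reproduces a prescribed wall-shear-stress trend
  (3.5 -> 46 dyn/cm2 over days 0-42, flat to day 84) exactly when replicate
  noise is off;
* phantom vessel cross-sections (lumen / tunica intima / tunica media
  annuli) rendered as 8-bit z-stacks: marker channels with compartment mean
  gray following per-marker percent-change time-courses, and PLA channels
  with discrete spots (median area 10 px) whose per-compartment density
  follows per-pair interaction time-courses, plus matched negative controls
  carrying only nonspecific spots.

Biological replicate variation is a per-specimen multiplicative lognormal
factor (CV ``replicate_noise_cv``).  One root seed drives everything; every
(rat, day, channel) gets its own independent stream derived by stable
hashing, so adding a marker or pair never perturbs existing images.
"""

from __future__ import annotations

import heapq
import math
import shutil
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .hemodynamics import (
    DEFAULT_VISCOSITY,
    FlowTrace,
    VesselGeometry,
    ml_min_to_cm3_s,
    radius_for_wss,
)
from .pla_quant import ImageStack, INTIMA, LUMEN, MEDIA

__all__ = [
    "CalibrationProfile",
    "VesselPhantom",
    "GroundTruth",
    "default_calibration",
    "default_phantom",
    "pla_default_phantom",
    "small_phantom",
    "compartment_masks",
    "derive_rng",
    "gen_flow_traces",
    "gen_geometry_series",
    "gen_vessel_image",
    "gen_study",
    "sample_spot_areas",
]


# ---------------------------------------------------------------------------
# study calibration
# ---------------------------------------------------------------------------

#: Per-marker true percent change of endothelial expression vs the
#: pre-fistula baseline (day -1).  Anchors: caspase3 +10% day 1 and +35% peak
#: at day 42; Notch1 +81% at day 3, sustained; Notch4 +45% at day 21 after a
#: three-week delay; Delta1/Delta4 peaking at day 84 (+61%/+74%); Jagged1
#: responding two weeks before the Deltas and peaking at day 42 (+58%); Hes1
#: (overall pathway activity) peaking at day 42 (+64%); CD31 as a flat
#: endothelial reference.  Intermediate days interpolate those anchors
#: monotonically.
MARKER_TIMECOURSES = {
    "caspase3": {1: 10, 3: 14, 7: 18, 14: 24, 21: 29, 42: 35, 84: 32},
    "CD31": {1: 0, 3: 0, 7: 0, 14: 0, 21: 0, 42: 0, 84: 0},
    "Notch1": {1: 40, 3: 81, 7: 80, 14: 80, 21: 79, 42: 80, 84: 80},
    "Notch4": {1: 0, 3: 2, 7: 6, 14: 18, 21: 45, 42: 47, 84: 50},
    "Delta1": {1: 0, 3: 2, 7: 6, 14: 12, 21: 28, 42: 47, 84: 61},
    "Delta4": {1: 0, 3: 3, 7: 8, 14: 15, 21: 33, 42: 56, 84: 74},
    "Jagged1": {1: 0, 3: 5, 7: 22, 14: 36, 21: 46, 42: 58, 84: 50},
    "Hes1": {1: 5, 3: 10, 7: 20, 14: 31, 21: 42, 42: 64, 84: 54},
}

#: Per-pair true percent change of receptor-ligand interaction density vs
#: baseline.  Anchors: Notch1-Delta1 +23% at day 84; Notch1-Delta4 +31% at
#: day 42; Notch1-Jagged1 +22% at day 84; Notch4-Delta4 and Notch4-Jagged1
#: rising early (day 3) and ranging to +35% at day 84; Notch4-Delta1 a
#: steady time-correlated rise.
INTERACTION_TIMECOURSES = {
    "Notch1-Delta1": {1: 2, 3: 5, 7: 8, 14: 11, 21: 14, 42: 18, 84: 23},
    "Notch1-Delta4": {1: 2, 3: 6, 7: 10, 14: 15, 21: 20, 42: 31, 84: 28},
    "Notch1-Jagged1": {1: 2, 3: 5, 7: 8, 14: 12, 21: 15, 42: 19, 84: 22},
    "Notch4-Delta1": {1: 1, 3: 4, 7: 7, 14: 10, 21: 13, 42: 17, 84: 20},
    "Notch4-Delta4": {1: 8, 3: 24, 7: 26, 14: 28, 21: 30, 42: 33, 84: 35},
    "Notch4-Jagged1": {1: 7, 3: 21, 7: 24, 14: 27, 21: 30, 42: 33, 84: 35},
}


@dataclass
class CalibrationProfile:
    """Study-design constants plus the true effect sizes the phantoms encode.

    The defaults are the study conditions: days {-1, 1, 3, 7, 14, 21, 42, 84}
    with the sham (pre-fistula) group coded as day -1, 4 rats per timepoint
    in the imaging arms and 6 in the hemodynamic arm, a 5.2 mL/min carotid
    baseline flow rising 2.4x at fistula creation and 11x by day 42, and a
    wall-shear trend linear from 3.5 dyn/cm2 (day 0) to 46 dyn/cm2 (day 42),
    flat thereafter.
    """

    time_grid_days: tuple = (-1, 1, 3, 7, 14, 21, 42, 84)
    flow_baseline_ml_min: float = 5.2
    flow_day0_factor: float = 2.4
    flow_day42_fold: float = 11.0
    wss_day0: float = 3.5
    wss_day42: float = 46.0
    plateau_after_day42: bool = True
    marker_timecourses: dict = field(default_factory=lambda: dict(MARKER_TIMECOURSES))
    interaction_timecourses: dict = field(
        default_factory=lambda: dict(INTERACTION_TIMECOURSES)
    )
    marker_base_fiu: dict = field(
        default_factory=lambda: {"endothelium": 90.0, "media": 40.0}
    )
    pla_base_rate_mm2: dict = field(
        default_factory=lambda: {"endothelium": 55000.0, "media": 13000.0}
    )
    nonspecific_rate_mm2: float = 400.0
    marker_effect_compartment: str = "endothelium"
    interaction_effect_compartment: str = "both"
    merged_fraction: float = 0.10
    replicate_noise_cv: float = 0.05
    rats_per_timepoint: int = 4
    flow_rats_per_timepoint: int = 6
    seed: int = 0

    def __post_init__(self):
        grid = tuple(int(d) for d in self.time_grid_days)
        if list(grid) != sorted(set(grid)):
            raise ValueError("time grid must be strictly increasing")
        if sum(1 for d in grid if d < 0) != 1:
            raise ValueError("time grid must contain exactly one baseline day (< 0)")
        self.time_grid_days = grid
        if self.replicate_noise_cv < 0:
            raise ValueError("replicate noise CV must be >= 0")
        if self.rats_per_timepoint < 2 or self.flow_rats_per_timepoint < 2:
            raise ValueError("need at least 2 rats per timepoint")
        if not (self.wss_day0 > 0 and self.wss_day42 > 0):
            raise ValueError("wall-shear targets must be > 0")

    @property
    def baseline_day(self) -> int:
        return next(d for d in self.time_grid_days if d < 0)

    @property
    def flow_days(self) -> tuple:
        """Days with a flow recording: the study grid plus day 0 (the moment
        of fistula creation, when flow was recorded on the table)."""
        return tuple(sorted(set(self.time_grid_days) | {0}))

    def flow_mean_ml_min(self, day: int) -> float:
        """Noise-free session-mean flow for a study day, mL/min."""
        q0 = self.flow_baseline_ml_min * self.flow_day0_factor
        q42 = q0 * self.flow_day42_fold
        if day < 0:
            return self.flow_baseline_ml_min
        if day >= 42:
            return q42
        return q0 + (q42 - q0) * day / 42.0

    def wss_target(self, day: int) -> float:
        """Noise-free wall-shear-stress target for a study day, dyn/cm2.

        Linear in time from day 0 to day 42, then flat.  The pre-fistula
        baseline keeps the day-0 vessel radius, so its shear scales with the
        baseline/day-0 flow ratio.
        """
        if day < 0:
            return self.wss_day0 / self.flow_day0_factor
        if day >= 42:
            if self.plateau_after_day42:
                return self.wss_day42
        return self.wss_day0 + (self.wss_day42 - self.wss_day0) * day / 42.0

    def _effect(self, table, name, day, kind):
        if name not in table:
            raise KeyError(f"unknown {kind} {name!r}; known: {sorted(table)}")
        if day == self.baseline_day:
            return 0.0
        if day not in table[name]:
            raise KeyError(f"{kind} {name!r} has no effect entry for day {day}")
        return float(table[name][day])

    def marker_effect(self, marker: str, day: int) -> float:
        """True percent change of a marker's expression vs baseline."""
        return self._effect(self.marker_timecourses, marker, day, "marker")

    def interaction_effect(self, pair: str, day: int) -> float:
        """True percent change of a pair's interaction density vs baseline."""
        return self._effect(self.interaction_timecourses, pair, day, "pair")


def default_calibration(seed: int = 0, **overrides) -> CalibrationProfile:
    """The calibrated study profile with an explicit root seed."""
    return CalibrationProfile(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselPhantom:
    """Geometry of a synthetic vessel cross-section z-stack."""

    lumen_radius_px: float = 360.0
    intima_thickness_px: float = 12.0
    media_thickness_px: float = 110.0
    pixel_size_um: float = 1.0
    image_shape: tuple = (1024, 1024)
    n_z_slices: int = 6
    z_step_um: float = 2.0

    def __post_init__(self):
        if min(self.intima_thickness_px, self.media_thickness_px,
               self.lumen_radius_px) <= 0:
            raise ValueError("phantom radii and thicknesses must be > 0")
        outer = self.lumen_radius_px + self.intima_thickness_px + self.media_thickness_px
        if 2 * (outer + 2) > min(self.image_shape):
            raise ValueError("vessel annulus does not fit inside the image")
        if self.n_z_slices < 1 or self.z_step_um <= 0:
            raise ValueError("z geometry invalid")

    @property
    def z_volume_um(self) -> float:
        return self.n_z_slices * self.z_step_um

    @property
    def center(self) -> tuple:
        return (self.image_shape[0] / 2.0, self.image_shape[1] / 2.0)


def default_phantom() -> VesselPhantom:
    """Full-scale phantom: a 1.0 um/px, 1024x1024 field holding one dilated
    vessel (lumen radius 360 um) imaged as 6 z-slices of 2 um (12 um total)."""
    return VesselPhantom()


def pla_default_phantom() -> VesselPhantom:
    """Phantom for PLA arms, imaged at higher magnification (0.5 um/px) so
    the 5-um endothelial band is 10 px deep and carries enough spots for
    stable counting statistics.  Same 12-um z-volume; a larger dilated
    vessel (lumen radius 400 um)."""
    return VesselPhantom(
        lumen_radius_px=800, intima_thickness_px=20, media_thickness_px=110,
        pixel_size_um=0.5, image_shape=(2048, 2048), n_z_slices=6, z_step_um=2.0,
    )


def small_phantom() -> VesselPhantom:
    """A reduced phantom for fast tests; same 12-um z-volume."""
    return VesselPhantom(
        lumen_radius_px=80, intima_thickness_px=8, media_thickness_px=34,
        pixel_size_um=1.0, image_shape=(256, 256), n_z_slices=3, z_step_um=4.0,
    )


@lru_cache(maxsize=8)
def compartment_masks(phantom: VesselPhantom):
    """Lumen/intima/media boolean masks and the label segmentation image."""
    rr, cc = np.indices(phantom.image_shape)
    cy, cx = phantom.center
    radial = np.hypot(rr - cy, cc - cx)
    r_l = phantom.lumen_radius_px
    r_i = r_l + phantom.intima_thickness_px
    r_m = r_i + phantom.media_thickness_px
    lumen = radial <= r_l
    intima = (radial > r_l) & (radial <= r_i)
    media = (radial > r_i) & (radial <= r_m)
    seg = np.zeros(phantom.image_shape, dtype=np.uint8)
    seg[lumen] = LUMEN
    seg[intima] = INTIMA
    seg[media] = MEDIA
    return {"lumen": lumen, "intima": intima, "media": media, "segmentation": seg}


def compartment_area_mm2(phantom: VesselPhantom, compartment: str) -> float:
    masks = compartment_masks(phantom)
    key = "intima" if compartment == "endothelium" else compartment
    return float(masks[key].sum()) * (phantom.pixel_size_um / 1000.0) ** 2


# ---------------------------------------------------------------------------
# seeded RNG streams
# ---------------------------------------------------------------------------

def derive_rng(root_seed: int, *key) -> np.random.Generator:
    """An independent generator for a (rat, day, channel, ...) key.

    The key is hashed stably (CRC-32 of its string form), so streams never
    depend on generation order and adding an arm never perturbs another.
    """
    text = "/".join(str(k) for k in key)
    h = zlib.crc32(text.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) % 2**31, h]))


def _lognormal_factor(rng, cv: float) -> float:
    """Unit-mean multiplicative lognormal replicate factor."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


# ---------------------------------------------------------------------------
# flow traces and geometries
# ---------------------------------------------------------------------------

def gen_flow_traces(
    profile: CalibrationProfile,
    rat_id: str,
    day: int,
    duration_s: float = 3.0,
    sample_rate_hz: float = 100.0,
    pulse_freq_hz: float = 6.0,
    pulse_amplitude: float = 0.3,
) -> FlowTrace:
    """A pulsatile flow trace whose time-average is the day's mean flow times
    a lognormal replicate factor.

    Pulsatility is a positive sinusoidal modulation at the rat heart rate
    (default 6 Hz, amplitude 0.3 of the mean), sampled over whole cycles so
    the trapezoidal mean is exact.  The trace is never negative.
    """
    if day not in profile.flow_days:
        raise ValueError(
            f"day {day} not in the study flow grid {profile.flow_days}"
        )
    if not 0 <= pulse_amplitude < 1:
        raise ValueError("pulse amplitude must be in [0, 1)")
    n = int(round(duration_s * sample_rate_hz))
    t = np.linspace(0.0, duration_s, n + 1)
    rng = derive_rng(profile.seed, "flow", rat_id, day)
    factor = _lognormal_factor(rng, profile.replicate_noise_cv)
    mean_q = profile.flow_mean_ml_min(day) * factor
    flow = mean_q * (1.0 + pulse_amplitude * np.sin(2 * math.pi * pulse_freq_hz * t))
    label = "carotid_proximal" if day < 0 else "fistula_vein"
    return FlowTrace(t_s=t, flow_ml_min=flow, vessel_label=label,
                     rat_id=rat_id, day=day)


def gen_geometry_series(
    profile: CalibrationProfile,
    rat_id: str,
    days=None,
    viscosity: float = DEFAULT_VISCOSITY,
) -> dict:
    """Per-day vessel geometries calibrated against the shear trend.

    The radius for each day solves R = (4*eta*Q/(pi*tau_target))**(1/3) with
    the day's noise-free mean flow, so that the forward Poiseuille
    computation on (noise-free flow, radius) returns the target trend
    exactly; with replicate noise on, measured shear inherits the flow's
    replicate scatter.  Radii are checked against a physiological window
    (0.01-0.5 cm).
    """
    if days is None:
        days = profile.flow_days
    out = {}
    for day in days:
        q = float(ml_min_to_cm3_s(profile.flow_mean_ml_min(day)))
        tau = profile.wss_target(day)
        radius = radius_for_wss(tau, q, viscosity)
        if not 0.01 <= radius <= 0.5:
            raise ValueError(
                f"calibrated radius {radius:.4f} cm for day {day} is outside "
                "the physiological window (0.01-0.5 cm)"
            )
        out[day] = VesselGeometry(internal_radius_cm=radius, viscosity=viscosity)
    return out


# ---------------------------------------------------------------------------
# spot fields
# ---------------------------------------------------------------------------

_NEIGHBOR9 = np.array([(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)])


def sample_spot_areas(rng, n: int, median_area: int = 10, sigma: float = 0.45,
                      min_area: int = 2, max_area: int = 50) -> np.ndarray:
    """Discretized lognormal spot areas, median ``median_area`` px, truncated
    to [min_area, max_area] so an isolated spot is never misread as a merger."""
    if n == 0:
        return np.zeros(0, dtype=int)
    out = np.zeros(n, dtype=int)
    need = np.ones(n, dtype=bool)
    mu = math.log(median_area)
    while need.any():
        draw = np.rint(rng.lognormal(mu, sigma, size=int(need.sum()))).astype(int)
        ok = (draw >= min_area) & (draw <= max_area)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def _grow_blob(rng, area: int) -> np.ndarray:
    """A connected, roughly round pixel blob of exactly ``area`` px, as (row,
    col) offsets from its seed pixel.  Grown by noisy-distance-first region
    growing, which guarantees 4-connectivity."""
    chosen = []
    heap = [(0.0, (0, 0))]
    seen = {(0, 0)}
    while len(chosen) < area:
        _, (r, c) = heapq.heappop(heap)
        chosen.append((r, c))
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nxt = (r + dr, c + dc)
            if nxt not in seen:
                seen.add(nxt)
                prio = math.hypot(*nxt) + rng.uniform(0.0, 0.8)
                heapq.heappush(heap, (prio, nxt))
    return np.array(chosen)


class _SpotCanvas:
    """Mutable scratch state while stamping spots into one image field."""

    def __init__(self, shape, rng):
        self.shape = shape
        self.rng = rng
        self.value = np.zeros(shape, dtype=np.float32)
        self.slice_of = np.full(shape, -1, dtype=np.int16)
        self.blocked = np.zeros(shape, dtype=bool)

    def _stamp(self, coords, n_z):
        z = int(self.rng.integers(n_z))
        base = self.rng.uniform(150.0, 230.0)
        vals = np.clip(base + self.rng.normal(0.0, 10.0, len(coords)), 120.0, 255.0)
        self.value[coords[:, 0], coords[:, 1]] = vals
        self.slice_of[coords[:, 0], coords[:, 1]] = z

    def _block(self, coords):
        nbr = coords[:, None, :] + _NEIGHBOR9[None, :, :]
        nbr = nbr.reshape(-1, 2)
        nbr[:, 0] = np.clip(nbr[:, 0], 0, self.shape[0] - 1)
        nbr[:, 1] = np.clip(nbr[:, 1], 0, self.shape[1] - 1)
        self.blocked[nbr[:, 0], nbr[:, 1]] = True

    def _candidate(self, region_idx):
        flat = int(region_idx[self.rng.integers(len(region_idx))])
        return divmod(flat, self.shape[1])

    def _fits(self, coords):
        if (coords[:, 0].min() < 0 or coords[:, 1].min() < 0
                or coords[:, 0].max() >= self.shape[0]
                or coords[:, 1].max() >= self.shape[1]):
            return False
        return not self.blocked[coords[:, 0], coords[:, 1]].any()

    def place_isolated(self, region_idx, region_mask, area, n_z,
                       max_attempts=300, block=True):
        blob = _grow_blob(self.rng, area)
        for _ in range(max_attempts):
            r, c = self._candidate(region_idx)
            coords = blob + (r, c)
            if not self._fits(coords):
                continue
            # the spot belongs to the compartment holding its centroid, so
            # the centroid pixel itself must lie inside the region
            cr = int(round(coords[:, 0].mean()))
            cc = int(round(coords[:, 1].mean()))
            if not region_mask[cr, cc]:
                continue
            self._stamp(coords, n_z)
            if block:
                self._block(coords)
            return coords
        raise ValueError(
            "could not place a spot without overlap; the PLA event rate is too "
            "high for this phantom — use a smaller rate or a larger vessel"
        )

    def place_cluster(self, region_idx, region_mask, areas, n_z, min_union_area,
                      max_attempts=300):
        """Place len(areas) mutually overlapping spots forming one blob whose
        union exceeds ``min_union_area`` px.  Returns the number of spots
        actually seeded (extended if the union came out too small)."""
        first = self.place_isolated(region_idx, region_mask, int(areas[0]), n_z,
                                    max_attempts=max_attempts, block=False)
        cluster = {tuple(p) for p in first}
        n_spots = 1
        pending = [int(a) for a in areas[1:]]
        while pending or len(cluster) <= min_union_area:
            area = pending.pop(0) if pending else int(
                sample_spot_areas(self.rng, 1)[0]
            )
            blob = _grow_blob(self.rng, area)
            placed = False
            members = list(cluster)
            for _ in range(max_attempts):
                ar, ac = members[int(self.rng.integers(len(members)))]
                off = self.rng.integers(-3, 4, size=2)
                coords = blob + (ar + int(off[0]), ac + int(off[1]))
                if (coords[:, 0].min() < 0 or coords[:, 1].min() < 0
                        or coords[:, 0].max() >= self.shape[0]
                        or coords[:, 1].max() >= self.shape[1]):
                    continue
                new = {tuple(p) for p in coords}
                if not (new & cluster):
                    continue
                outside = np.array(sorted(new - cluster))
                if outside.size and self.blocked[outside[:, 0], outside[:, 1]].any():
                    continue
                self._stamp(coords, n_z)
                cluster |= new
                n_spots += 1
                placed = True
                break
            if not placed:
                raise ValueError(
                    "could not extend a merged-spot cluster; reduce the event "
                    "rate or merged fraction"
                )
        coords = np.array(sorted(cluster))
        self._block(coords)
        return n_spots


def _place_compartment_spots(canvas, region_mask, n_spots, merged_fraction,
                             n_z, rng, single_max_area=50):
    """Seed ``n_spots`` true events into a compartment; a ``merged_fraction``
    of them as clusters whose union exceeds the single-event size gate.

    Returns (n_seeded, areas, n_clusters).  n_seeded can exceed n_spots when
    a cluster needed extension to clear the merge gate.
    """
    region_idx = np.flatnonzero(region_mask)
    if len(region_idx) == 0:
        raise ValueError("empty compartment mask")
    # capacity guard: spots plus their 1-px halos must fit comfortably
    if n_spots * 30 > 0.85 * len(region_idx):
        raise ValueError(
            f"{n_spots} spots cannot fit in a {len(region_idx)}-px compartment; "
            "use a smaller event rate"
        )
    n_merged = int(round(merged_fraction * n_spots))
    seeded = 0
    areas = []
    n_clusters = 0
    while n_merged - seeded >= 5:
        k = int(rng.integers(6, 9))
        k = min(k, n_merged - seeded)
        if k < 5:
            break
        cluster_areas = sample_spot_areas(rng, k)
        n = canvas.place_cluster(region_idx, region_mask, cluster_areas, n_z,
                                 min_union_area=single_max_area)
        areas.extend(cluster_areas.tolist())
        seeded += n
        n_clusters += 1
    n_single = max(0, n_spots - seeded)
    single_areas = sample_spot_areas(rng, n_single)
    for area in single_areas:
        canvas.place_isolated(region_idx, region_mask, int(area), n_z)
    areas.extend(single_areas.tolist())
    return seeded + n_single, areas, n_clusters


# ---------------------------------------------------------------------------
# phantom images
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything seeded into one specimen's image set."""

    rat_id: str
    day: int
    name: str
    arm: str  # "if" or "pla"
    marker_level: dict = field(default_factory=dict)
    pla_rate_mm2: dict = field(default_factory=dict)
    n_spots: dict = field(default_factory=dict)
    n_nonspecific: dict = field(default_factory=dict)
    n_control_spots: dict = field(default_factory=dict)
    n_clusters: int = 0
    spot_areas: list = field(default_factory=list)

    @property
    def true_event_count(self) -> dict:
        """Seeded specific events per compartment (equals the spot count)."""
        return dict(self.n_spots)


def _noise_stack(shape, n_z, background, sd, rng):
    stack = np.full((n_z,) + tuple(shape), float(background), dtype=np.float32)
    if sd > 0:
        stack += rng.normal(0.0, sd, size=stack.shape).astype(np.float32)
    return stack


def _to_uint8(stack):
    return np.clip(np.rint(stack), 0, 255).astype(np.uint8)


def _render_marker_stack(phantom, levels, rng, background=20.0, read_noise_sd=5.0):
    """Marker channel: intima/media annuli at background + level mean gray."""
    masks = compartment_masks(phantom)
    value = np.full(phantom.image_shape, background, dtype=np.float32)
    value[masks["intima"]] += levels.get("endothelium", 0.0)
    value[masks["media"]] += levels.get("media", 0.0)
    stack = _noise_stack(phantom.image_shape, phantom.n_z_slices, 0.0,
                         read_noise_sd, rng)
    stack += value[None]
    return ImageStack(_to_uint8(stack), phantom.pixel_size_um, phantom.z_step_um,
                      channel="marker")


def _render_spot_stack(phantom, rates_mm2, rng, background=30.0, noise_sd=8.0,
                       merged_fraction=0.0, channel="pla"):
    """Spot channel: background noise plus Poisson spot fields per compartment.

    Returns (stack, n_spots_by_compartment, areas, n_clusters).
    """
    masks = compartment_masks(phantom)
    canvas = _SpotCanvas(phantom.image_shape, rng)
    n_by_comp, all_areas, n_clusters = {}, [], 0
    for comp, region_key in (("endothelium", "intima"), ("media", "media")):
        rate = float(rates_mm2.get(comp, 0.0))
        if rate < 0:
            raise ValueError("PLA event rate must be >= 0")
        n_target = int(rng.poisson(rate * compartment_area_mm2(phantom, comp)))
        if n_target == 0:
            n_by_comp[comp] = 0
            continue
        n, areas, k = _place_compartment_spots(
            canvas, masks[region_key], n_target, merged_fraction,
            phantom.n_z_slices, rng)
        n_by_comp[comp] = n
        all_areas.extend(areas)
        n_clusters += k
    stack = _noise_stack(phantom.image_shape, phantom.n_z_slices, background,
                         noise_sd, rng)
    has_spot = canvas.slice_of >= 0
    if has_spot.any():
        rr, cc = np.nonzero(has_spot)
        zz = canvas.slice_of[rr, cc]
        stack[zz, rr, cc] = np.maximum(stack[zz, rr, cc], canvas.value[rr, cc])
    return (ImageStack(_to_uint8(stack), phantom.pixel_size_um, phantom.z_step_um,
                       channel=channel), n_by_comp, all_areas, n_clusters)


def gen_vessel_image(
    phantom: VesselPhantom,
    marker_level,
    pla_event_rate,
    seed,
    nonspecific_rate_mm2: float = 400.0,
    merged_fraction: float = 0.10,
    marker_background: float = 20.0,
    read_noise_sd: float = 5.0,
    pla_background: float = 30.0,
    pla_noise_sd: float = 8.0,
    keys: dict | None = None,
):
    """Render one specimen set: marker channel, PLA channel, PLA negative
    control, and the ground-truth record.

    ``marker_level`` and ``pla_event_rate`` may be scalars (applied to the
    endothelium, media zero) or ``{"endothelium": ..., "media": ...}`` dicts;
    rates are specific events per mm2 of compartment.  The negative control
    carries only the nonspecific spot rate.  ``seed`` may be an integer or a
    ready ``numpy`` Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = (dict(marker_level) if isinstance(marker_level, dict)
              else {"endothelium": float(marker_level), "media": 0.0})
    rates = (dict(pla_event_rate) if isinstance(pla_event_rate, dict)
             else {"endothelium": float(pla_event_rate), "media": 0.0})
    if min(levels.values()) < 0 or min(rates.values()) < 0:
        raise ValueError("marker levels and event rates must be >= 0")

    marker = _render_marker_stack(phantom, levels, rng,
                                  background=marker_background,
                                  read_noise_sd=read_noise_sd)
    total_rates = {c: rates.get(c, 0.0) + nonspecific_rate_mm2
                   for c in ("endothelium", "media")}
    pla, n_total, areas, n_clusters = _render_spot_stack(
        phantom, total_rates, rng, background=pla_background,
        noise_sd=pla_noise_sd, merged_fraction=merged_fraction)
    nc_rates = {c: nonspecific_rate_mm2 for c in ("endothelium", "media")}
    negative, n_nc, _, _ = _render_spot_stack(
        phantom, nc_rates, rng, background=pla_background,
        noise_sd=pla_noise_sd, merged_fraction=0.0, channel="negative_control")

    info = keys or {}
    truth = GroundTruth(
        rat_id=str(info.get("rat_id", "")),
        day=int(info.get("day", 0)),
        name=str(info.get("name", "")),
        arm=str(info.get("arm", "")),
        marker_level=levels,
        pla_rate_mm2=rates,
        n_spots=n_total,
        n_nonspecific={},
        n_control_spots=n_nc,
        n_clusters=n_clusters,
        spot_areas=areas,
    )
    return marker, pla, negative, truth


# ---------------------------------------------------------------------------
# full-study generation to disk
# ---------------------------------------------------------------------------

def _specimen_levels(profile, marker, day, factor):
    base = profile.marker_base_fiu
    comp = profile.marker_effect_compartment
    eff = profile.marker_effect(marker, day) / 100.0
    return {
        "endothelium": base["endothelium"] * (1 + eff if comp in ("endothelium", "both") else 1) * factor,
        "media": base["media"] * (1 + eff if comp in ("media", "both") else 1) * factor,
    }


def _specimen_rates(profile, pair, day, factor):
    base = profile.pla_base_rate_mm2
    comp = profile.interaction_effect_compartment
    eff = profile.interaction_effect(pair, day) / 100.0
    return {
        "endothelium": base["endothelium"] * (1 + eff if comp in ("endothelium", "both") else 1) * factor,
        "media": base["media"] * (1 + eff if comp in ("media", "both") else 1) * factor,
    }


def iter_if_specimens(profile: CalibrationProfile, marker: str,
                      phantom: VesselPhantom):
    """Yield (rat_id, day, levels, marker_stack, control_stack) for every
    specimen of one immunofluorescence arm, in manifest order."""
    for day in profile.time_grid_days:
        for i in range(profile.rats_per_timepoint):
            rat = f"if_{marker}_d{day}_r{i}"
            rng = derive_rng(profile.seed, "if", marker, rat, day)
            factor = _lognormal_factor(rng, profile.replicate_noise_cv)
            levels = _specimen_levels(profile, marker, day, factor)
            stack = _render_marker_stack(phantom, levels, rng)
            ctrl = _render_marker_stack(
                phantom, {"endothelium": 0.0, "media": 0.0},
                derive_rng(profile.seed, "if_ctrl", marker, rat, day))
            yield rat, day, levels, stack, ctrl


def iter_pla_specimens(profile: CalibrationProfile, pair: str,
                       phantom: VesselPhantom):
    """Yield (rat_id, day, rates, pla_stack, control_stack, truth) for every
    specimen of one PLA arm, in manifest order."""
    for day in profile.time_grid_days:
        for i in range(profile.rats_per_timepoint):
            rat = f"pla_{pair}_d{day}_r{i}"
            rng = derive_rng(profile.seed, "pla", pair, rat, day)
            factor = _lognormal_factor(rng, profile.replicate_noise_cv)
            rates = _specimen_rates(profile, pair, day, factor)
            _, pla, nc, truth = gen_vessel_image(
                phantom, {"endothelium": 0.0, "media": 0.0}, rates, rng,
                nonspecific_rate_mm2=profile.nonspecific_rate_mm2,
                merged_fraction=profile.merged_fraction,
                keys={"rat_id": rat, "day": day, "name": pair, "arm": "pla"},
            )
            yield rat, day, rates, pla, nc, truth


def gen_study(
    profile: CalibrationProfile,
    out_dir,
    markers=None,
    pairs=None,
    if_phantom: VesselPhantom | None = None,
    pla_phantom: VesselPhantom | None = None,
) -> pd.DataFrame:
    """Write a complete synthetic study to ``out_dir`` and return its manifest.

    Emits, fully determined by (profile, phantom):

    * ``flows.csv`` — pulsatile traces for the hemodynamic arm (6 rats per
      day over the flow grid) in long format;
    * ``geometry.csv`` — calibrated per-day vessel radii;
    * ``segmentation_if.tif`` / ``segmentation_pla.tif`` — each arm's
      lumen/intima/media label image (the PLA arm is imaged at higher
      magnification);
    * ``images/*.tif`` — per-specimen marker + primary-antibody-control
      stacks for every marker, and PLA + negative-control stacks for every
      pair (4 rats per study day each);
    * ``manifest.csv`` — one row per image file with its rat, day, arm,
      name, channel and pixel geometry;
    * ``ground_truth.csv`` — seeded levels, rates and spot counts.

    Partial output is removed if generation fails.  The directory must not
    already contain files.
    """
    import tifffile

    if_phantom = if_phantom or default_phantom()
    pla_phantom = pla_phantom or pla_default_phantom()
    markers = list(profile.marker_timecourses) if markers is None else list(markers)
    pairs = list(profile.interaction_timecourses) if pairs is None else list(pairs)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise ValueError(f"output directory {out} is not empty")
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir()
    try:
        flow_rows, geom_rows = [], []
        geometries = gen_geometry_series(profile, rat_id="", days=profile.flow_days)
        for day in profile.flow_days:
            for i in range(profile.flow_rats_per_timepoint):
                rat = f"hemo_d{day}_r{i}"
                trace = gen_flow_traces(profile, rat, day)
                flow_rows.append(pd.DataFrame({
                    "rat_id": rat, "day": day, "vessel_label": trace.vessel_label,
                    "t_s": trace.t_s, "flow_ml_min": trace.flow_ml_min,
                }))
                geom_rows.append({
                    "rat_id": rat, "day": day,
                    "internal_radius_cm": geometries[day].internal_radius_cm,
                    "viscosity": geometries[day].viscosity,
                })
        pd.concat(flow_rows, ignore_index=True).to_csv(out / "flows.csv", index=False)
        pd.DataFrame(geom_rows).to_csv(out / "geometry.csv", index=False)
        tifffile.imwrite(out / "segmentation_if.tif",
                         compartment_masks(if_phantom)["segmentation"])
        tifffile.imwrite(out / "segmentation_pla.tif",
                         compartment_masks(pla_phantom)["segmentation"])

        manifest, truth_rows = [], []

        def record(fname, arm, name, rat, day, channel, phantom):
            manifest.append({
                "file": f"images/{fname}", "arm": arm, "name": name,
                "rat_id": rat, "day": day, "channel": channel,
                "pixel_size_um": phantom.pixel_size_um,
                "z_step_um": phantom.z_step_um, "n_z": phantom.n_z_slices,
                "segmentation": f"segmentation_{arm}.tif",
            })

        for marker in markers:
            for rat, day, levels, stack, ctrl in iter_if_specimens(
                    profile, marker, if_phantom):
                base = rat
                stack.save(out / "images" / f"{base}_marker.tif")
                ctrl.save(out / "images" / f"{base}_control.tif")
                record(f"{base}_marker.tif", "if", marker, rat, day,
                       "marker", if_phantom)
                record(f"{base}_control.tif", "if", marker, rat, day,
                       "primary_control", if_phantom)
                truth_rows.append({
                    "arm": "if", "name": marker, "rat_id": rat, "day": day,
                    "level_endothelium": levels["endothelium"],
                    "level_media": levels["media"],
                    "rate_endothelium": 0.0, "rate_media": 0.0,
                    "n_spots_endothelium": 0, "n_spots_media": 0,
                })

        for pair in pairs:
            for rat, day, rates, pla, nc, truth in iter_pla_specimens(
                    profile, pair, pla_phantom):
                base = rat
                pla.save(out / "images" / f"{base}_pla.tif")
                nc.save(out / "images" / f"{base}_negctrl.tif")
                record(f"{base}_pla.tif", "pla", pair, rat, day, "pla",
                       pla_phantom)
                record(f"{base}_negctrl.tif", "pla", pair, rat, day,
                       "negative_control", pla_phantom)
                truth_rows.append({
                    "arm": "pla", "name": pair, "rat_id": rat, "day": day,
                    "level_endothelium": 0.0, "level_media": 0.0,
                    "rate_endothelium": rates["endothelium"],
                    "rate_media": rates["media"],
                    "n_spots_endothelium": truth.n_spots.get("endothelium", 0),
                    "n_spots_media": truth.n_spots.get("media", 0),
                })

        manifest_df = pd.DataFrame(manifest)
        manifest_df.to_csv(out / "manifest.csv", index=False)
        pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
        return manifest_df
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for child in out.iterdir():
                if child.is_dir():
                    shutil.rmtree(child, ignore_errors=True)
                else:
                    child.unlink()
        raise
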