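"""Per-slice bony-contour segmentation, area measurement, Cavalieri volume.

Pipeline per coronal slice: threshold to a bone mask, trace the closed
inner boundary of the bone ring around a seed inside the cavity — bridging
wall interruptions (foramina, fissures) with straight chords between the
nearest flanking bone boundaries — then fill the enclosed region and
report its area as pixel count times pixel area.  The orbit volume is the
Cavalieri sum: slice interval times the sum of slice areas.

Area convention: a pixel belongs to the region iff its center lies inside
or on the closed contour, so a brute-force point-in-polygon count is an
exact oracle for every measured area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.draw import line as sk_line
from skimage.filters import threshold_otsu

from .config import ProtocolConfig
from .errors import (
    NoEnclosingBoneError,
    PartialMeasurementError,
    SegmentationError,
    UnclosableContourError,
    ValidationError,
)
from .imaging import Slice2D, VolumeImage, extract_coronal_slice

#: 4-connectivity structuring element; the chord barriers are 8-connected
#: pixel chains, which a 4-connected flood cannot cross.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class BridgedSegment:
    """A chord closing a wall interruption, in pixel coordinates."""

    start: tuple
    end: tuple
    length_mm: float


@dataclass
class SliceMeasurement:
    slice_index: int
    plane_position: float  # world y, mm
    closed_contour: np.ndarray  # (N, 2) pixel coords, first == last
    bridged_segments: list
    filled_mask: np.ndarray
    area_mm2: float


@dataclass
class OrbitMeasurement:
    side: str
    slices: list
    volume_mm3: float

    @property
    def areas_mm2(self):
        return [s.area_mm2 for s in self.slices]

    def to_dict(self):
        return {
            "side": self.side,
            "volume_mm3": self.volume_mm3,
            "slices": [
                {
                    "slice_index": s.slice_index,
                    "plane_position_mm": s.plane_position,
                    "area_mm2": s.area_mm2,
                    "n_bridged_segments": len(s.bridged_segments),
                }
                for s in self.slices
            ],
        }


def _auto_threshold(values: np.ndarray) -> float:
    """Automatic bone threshold from an intensity histogram.

    A single 2-class (Otsu) split is made first.  CBCT-like data carry
    three intensity populations — air/background, soft tissue, bone — and
    on such histograms the first split can land between background and
    soft tissue; when the upper class is itself clearly bimodal (mode
    separation well beyond the mode spreads), the bone threshold is the
    midpoint between those two dominant modes instead.  A constant
    histogram has nothing to split and raises.
    """
    values = values.ravel()
    if np.ptp(values) == 0:
        raise SegmentationError(
            "cannot auto-threshold constant intensities (degenerate histogram)"
        )
    t1 = float(threshold_otsu(values))
    upper = values[values >= t1]
    if upper.size >= 2 and np.ptp(upper) > 0:
        t2 = float(threshold_otsu(upper))
        lo, hi = upper[upper < t2], upper[upper >= t2]
        if lo.size and hi.size:
            sep = hi.mean() - lo.mean()
            if sep > 4.0 * (lo.std() + hi.std()) + 1e-12:
                return float((lo.mean() + hi.mean()) / 2.0)
    return t1


def bone_mask(s: Slice2D, threshold: float | str = "auto") -> np.ndarray:
    """Threshold a slice to bone: pixel true iff intensity >= threshold.

    ``"auto"`` derives the threshold from this slice's own histogram; for
    a whole measurement prefer the volume-wide threshold
    (:func:`volume_bone_threshold`), since deep slices near the apex may
    be dominated by a single tissue class.
    """
    px = np.asarray(s.pixels, dtype=float)
    if px.size == 0:
        raise ValidationError("empty slice")
    if threshold == "auto":
        threshold = _auto_threshold(px)
    return px >= float(threshold)


def volume_bone_threshold(vol: VolumeImage) -> float:
    """Volume-wide automatic bone threshold."""
    return _auto_threshold(np.asarray(vol.voxels[::2, ::2, ::2], dtype=float))


def _ray_hits(mask, center_px, pixel_spacing, n_rays):
    """First bone hit per radial ray from the seed, in mm and pixel coords."""
    sp = np.asarray(pixel_spacing, float)
    c_mm = np.asarray(center_px, float) * sp
    nx, nz = mask.shape
    thetas = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    step = float(sp.min()) / 2.0
    r_max = float(np.hypot(nx * sp[0], nz * sp[1]))
    radii = step * np.arange(1, int(r_max / step) + 1)
    px = (c_mm[0] + np.cos(thetas)[:, None] * radii[None, :]) / sp[0]
    pz = (c_mm[1] + np.sin(thetas)[:, None] * radii[None, :]) / sp[1]
    ix = np.rint(px).astype(int)
    iz = np.rint(pz).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iz >= 0) & (iz < nz)
    hit = np.zeros_like(inside)
    hit[inside] = mask[ix[inside], iz[inside]]
    has_hit = hit.any(axis=1)
    first = np.argmax(hit, axis=1)
    r_hit = np.where(has_hit, radii[np.minimum(first, radii.size - 1)], np.inf)
    hit_px = np.stack([ix[np.arange(n_rays), first], iz[np.arange(n_rays), first]], 1)
    return r_hit, hit_px, has_hit


def _open_runs(open_flags):
    """Maximal circular runs of True, as (start, stop) index pairs."""
    n = open_flags.size
    if open_flags.all() or not open_flags.any():
        return []
    # rotate so index 0 is closed, then find contiguous runs
    k = int(np.argmin(open_flags))
    rolled = np.roll(open_flags, -k)
    runs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            runs.append(((i + k) % n, (j - 1 + k) % n))
            i = j
        else:
            i += 1
    return runs


def close_boundary(
    mask: np.ndarray,
    roi_center,
    max_gap_mm: float,
    pixel_spacing,
    n_rays: int = 1440,
    jump_factor: float = 1.6,
):
    """Trace the closed inner boundary of the bone ring around a seed.

    Wall interruptions are detected as angular runs of rays whose first
    bone hit is absent or much farther than the typical inner-boundary
    radius; each run is bridged by a straight chord between the bone hits
    flanking it, provided the chord is no longer than ``max_gap_mm``.

    Returns ``(closed_contour, bridged_segments, filled_region)`` where the
    contour is an (N, 2) pixel-coordinate loop, each bridged segment
    records its chord endpoints and mm length, and the filled region is the
    enclosed binary mask (holes — e.g. an implant cross-section — filled,
    since the measured quantity is the whole bony cavity cross-section).
    """
    mask = np.asarray(mask, dtype=bool)
    sp = np.asarray(pixel_spacing, float)
    ci = tuple(int(round(v)) for v in roi_center)
    if not (0 <= ci[0] < mask.shape[0] and 0 <= ci[1] < mask.shape[1]):
        raise ValidationError(f"roi_center {roi_center} outside the slice")
    if mask[ci]:
        raise SegmentationError("roi_center lies on bone, not inside a cavity")

    r_hit, hit_px, has_hit = _ray_hits(mask, roi_center, sp, n_rays)
    if not has_hit.any():
        raise NoEnclosingBoneError("no bone found around the seed point")
    med = float(np.median(r_hit[has_hit]))
    open_flags = ~has_hit | (r_hit > jump_factor * med)
    if open_flags.all():
        raise NoEnclosingBoneError("no consistent bone ring around the seed point")

    def _anchor(idx, direction):
        # Rays grazing a cut face can first hit bone well outside the true
        # inner boundary; anchor the chord at the innermost hit among the
        # nearest closed rays on this side of the interruption.
        k_look = max(3, n_rays // 144)  # ~2.5 degrees
        cands = []
        for k in range(1, k_look + 1):
            j = (idx + direction * k) % n_rays
            if open_flags[j]:
                break
            cands.append(j)
        if not cands:
            cands = [(idx + direction) % n_rays]
        # nearest ray whose hit is essentially as deep as the window's
        # innermost hit: hugs the interruption without climbing a cut face
        tol = float(np.hypot(*sp))
        r_min = min(r_hit[j] for j in cands)
        best = next(j for j in cands if r_hit[j] <= r_min + tol)
        return hit_px[best]

    def _nearest_bone(p, q, window_px=4):
        # bone pixel near p that is closest (in mm) to q: the chord joins
        # the *nearest* bony boundaries flanking the interruption.  The
        # window stays smaller than half the narrowest bridgeable opening
        # so a refined endpoint cannot jump across to the far flank.
        lo0, hi0 = max(p[0] - window_px, 0), min(p[0] + window_px + 1, mask.shape[0])
        lo1, hi1 = max(p[1] - window_px, 0), min(p[1] + window_px + 1, mask.shape[1])
        cand = np.argwhere(mask[lo0:hi0, lo1:hi1])
        if cand.size == 0:
            return p
        cand = cand + (lo0, lo1)
        d2 = (((cand - q) * sp) ** 2).sum(axis=1)
        return cand[int(np.argmin(d2))]

    barrier = mask.copy()
    bridges = []
    for start, stop in _open_runs(open_flags):
        p0 = _anchor(start, -1)
        p1 = _anchor(stop, +1)
        for _ in range(2):
            p0 = _nearest_bone(p0, p1)
            p1 = _nearest_bone(p1, p0)
        chord_mm = float(np.hypot(*((p1 - p0) * sp)))
        if chord_mm > max_gap_mm:
            raise UnclosableContourError(chord_mm, max_gap_mm)
        rr, cc = sk_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
        barrier[rr, cc] = True
        bridges.append(BridgedSegment(tuple(p0), tuple(p1), chord_mm))

    labels, _ = ndi.label(~barrier, structure=_STRUCT4)
    seed_label = labels[ci]
    if seed_label == 0:
        raise SegmentationError("seed point fell on a boundary pixel")
    region = labels == seed_label
    if (
        region[0, :].any()
        or region[-1, :].any()
        or region[:, 0].any()
        or region[:, -1].any()
    ):
        raise NoEnclosingBoneError(
            "region around the seed leaks to the slice border (ring not closed)"
        )
    filled = ndi.binary_fill_holes(region)

    contours = skmeasure.find_contours(filled.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no contour around the enclosed region")
    contour = max(contours, key=len)
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    return contour, bridges, filled


def fill_and_measure(contour: np.ndarray, pixel_spacing, shape=None):
    """Fill a simple closed contour and measure its area.

    A pixel belongs to the region iff its center is inside or on the
    contour polygon; the area is exactly pixel count times pixel area.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
        raise ValidationError("contour must be an (N, 2) coordinate array, N >= 3")
    if not np.allclose(contour[0], contour[-1]):
        raise ValidationError("contour is not closed (first point != last point)")
    sp = np.asarray(pixel_spacing, float)
    if shape is None:
        shape = tuple(int(np.ceil(contour[:, k].max())) + 1 for k in range(2))
    lo = np.maximum(np.floor(contour.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(contour.max(axis=0)).astype(int) + 1, shape)
    ii, jj = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), indexing="ij"
    )
    pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    path = MplPath(contour)
    # +/- radius includes centers lying exactly on the polygon either way
    # the path winds
    inside = path.contains_points(pts, radius=1e-9) | path.contains_points(
        pts, radius=-1e-9
    )
    filled = np.zeros(shape, dtype=bool)
    filled[lo[0] : hi[0], lo[1] : hi[1]] = inside.reshape(ii.shape)
    area = float(filled.sum()) * float(sp[0] * sp[1])
    return filled, area


def estimate_volume(areas, interval_mm: float) -> float:
    """Cavalieri volume estimate: interval times the sum of slice areas."""
    areas = list(areas)
    if len(areas) < 1:
        raise ValidationError("need at least one area")
    if interval_mm <= 0:
        raise ValidationError("interval_mm must be > 0")
    if any(a < 0 for a in areas):
        raise ValidationError("areas must be non-negative")
    return float(interval_mm) * float(sum(areas))


def measure_slice(
    s: Slice2D, roi_center_px, threshold, max_gap_mm, slice_index: int
) -> SliceMeasurement:
    mask = bone_mask(s, threshold)
    contour, bridges, _ = close_boundary(
        mask, roi_center_px, max_gap_mm, s.pixel_spacing
    )
    filled, area = fill_and_measure(contour, s.pixel_spacing, shape=mask.shape)
    return SliceMeasurement(
        slice_index=slice_index,
        plane_position=s.plane_position,
        closed_contour=contour,
        bridged_segments=bridges,
        filled_mask=filled,
        area_mm2=area,
    )


def measure_orbit(
    vol: VolumeImage,
    side: str,
    seed_point,
    cfg: ProtocolConfig | None = None,
) -> OrbitMeasurement:
    """Measure one orbit on a canonically aligned volume.

    Extracts ``n_slices`` coronal slices at ``interval_mm`` spacing dorsally
    from the frame plane, runs the segmentation chain on each, and sums the
    areas into the Cavalieri volume.  The seed (world mm, inside the cavity
    at the frame plane) is re-centered on each previous slice's filled
    centroid, since the cavity drifts toward the apex.

    Raises :class:`PartialMeasurementError` carrying completed slices if a
    deeper slice cannot be closed.
    """
    cfg = cfg or ProtocolConfig()
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    seed = np.asarray(seed_point, dtype=float)
    if not vol.contains_point(seed):
        raise ValidationError(f"seed point {seed.tolist()} outside the volume")
    threshold = cfg.bone_threshold
    if threshold == "auto":
        threshold = volume_bone_threshold(vol)

    slices = []
    roi_px = None
    for k, y_mm in enumerate(cfg.slice_positions(), start=1):
        try:
            s = extract_coronal_slice(vol, y_mm)
            if roi_px is None:
                roi_px = (
                    (seed[0] - s.origin2d[0]) / s.pixel_spacing[0],
                    (seed[2] - s.origin2d[1]) / s.pixel_spacing[1],
                )
            sm = measure_slice(s, roi_px, threshold, cfg.max_gap_mm, k)
        except (SegmentationError, ValidationError) as exc:
            raise PartialMeasurementError(k, exc, slices) from exc
        slices.append(sm)
        com = ndi.center_of_mass(sm.filled_mask)
        roi_px = (float(com[0]), float(com[1]))

    volume = estimate_volume([s.area_mm2 for s in slices], cfg.interval_mm)
    return OrbitMeasurement(side=side, slices=slices, volume_mm3=volume)
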