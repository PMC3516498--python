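"""Synthetic CBCT-like head phantoms with bilateral orbital cavities.

The phantom idealizes each bony orbit as a cavity of analytically known
geometry — by default an elliptic cone (rim 40 x 35 mm, depth 45 mm,
matching adult orbital-rim dimensions) — surrounded by a bone shell of
fixed thickness, voxelized at 0.3 mm isotropic CBCT resolution.  Radial
sector openings cut through the shell stand in for the orbital fissures
and foramina that interrupt the real bony contour.  An optional implanted
sphere (18 or 20 mm diameter, the common post-enucleation implant sizes)
can sit inside a cavity at bone-level intensity.

Every cross-sectional area and every slab volume of the cavity is known
in closed form, so each downstream measurement stage can be tested
without any scan data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import GeometryError, ValidationError
from .imaging import VolumeImage

LABEL_BACKGROUND = 0
LABEL_CAVITY = 1
LABEL_BONE = 2


@dataclass(frozen=True)
class GapSpec:
    """A radial sector opening cut through the bone shell.

    ``depth_lo``/``depth_hi`` bound the opening in mm behind the rim plane;
    ``angle_deg`` is its angular position in the coronal plane, measured
    from the lateral (outward) direction toward superior; ``width_mm`` is
    the opening's arc width at the local cavity boundary.
    """

    depth_lo: float
    depth_hi: float
    angle_deg: float
    width_mm: float


@dataclass(frozen=True)
class ImplantSpec:
    center: tuple  # world mm
    diameter_mm: float = 20.0


@dataclass(frozen=True)
class OrbitSpec:
    """Geometry of one idealized orbital cavity."""

    rim_width: float = 40.0
    rim_height: float = 35.0
    depth: float = 45.0
    rim_center: tuple = (25.0, 0.0, 0.0)
    shape: str = "elliptic-cone"
    gaps: tuple = ()
    implant: ImplantSpec | None = None

    def __post_init__(self):
        if min(self.rim_width, self.rim_height, self.depth) <= 0:
            raise ValidationError("rim_width, rim_height and depth must be > 0")
        if self.shape not in ("elliptic-cone", "rectangular-pyramid"):
            raise ValidationError(f"unknown orbit shape {self.shape!r}")
        for g in self.gaps:
            if g.width_mm <= 0 or g.depth_hi <= g.depth_lo:
                raise ValidationError(f"invalid gap spec {g}")
            # openings must stay a minor fraction of the local perimeter
            frac = max(0.0, 1.0 - g.depth_hi / self.depth)
            perim = math.pi * (self.rim_width + self.rim_height) / 2 * frac
            if perim > 0 and g.width_mm >= perim:
                raise ValidationError(
                    f"gap width {g.width_mm} mm exceeds local wall perimeter"
                )

    @property
    def half_axes(self):
        return self.rim_width / 2.0, self.rim_height / 2.0


def _default_gaps():
    # stand-ins for the inferior and superior orbital fissures
    return (
        GapSpec(depth_lo=12.0, depth_hi=38.0, angle_deg=-50.0, width_mm=4.0),
        GapSpec(depth_lo=15.0, depth_hi=38.0, angle_deg=55.0, width_mm=3.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full bilateral phantom: two orbits plus voxelization parameters."""

    left: OrbitSpec = field(
        default_factory=lambda: OrbitSpec(
            rim_center=(-25.0, 0.0, 0.0), gaps=_default_gaps()
        )
    )
    right: OrbitSpec = field(
        default_factory=lambda: OrbitSpec(
            rim_center=(25.0, 0.0, 0.0), gaps=_default_gaps()
        )
    )
    voxel_spacing: float = 0.3
    bone_intensity: float = 1000.0
    cavity_intensity: float = 300.0
    background_intensity: float = 100.0
    noise_sd: float = 20.0
    wall_thickness: float = 2.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.voxel_spacing <= 0:
            raise ValidationError("voxel_spacing must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        floor = 5.0 * self.noise_sd
        if self.bone_intensity - max(
            self.cavity_intensity, self.background_intensity
        ) < floor:
            raise ValidationError(
                "bone_intensity must exceed cavity and background intensities "
                f"by at least 5*noise_sd = {floor}"
            )

    # -- JSON round trip (CLI spec files) ---------------------------------
    def to_json(self, path) -> None:
        def orbit(o: OrbitSpec):
            d = {
                "rim_width": o.rim_width,
                "rim_height": o.rim_height,
                "depth": o.depth,
                "rim_center": list(o.rim_center),
                "shape": o.shape,
                "gaps": [
                    [g.depth_lo, g.depth_hi, g.angle_deg, g.width_mm]
                    for g in o.gaps
                ],
            }
            if o.implant is not None:
                d["implant"] = {
                    "center": list(o.implant.center),
                    "diameter_mm": o.implant.diameter_mm,
                }
            return d

        Path(path).write_text(
            json.dumps(
                {
                    "schema": "orbitovol-phantom-spec-1",
                    "left": orbit(self.left),
                    "right": orbit(self.right),
                    "voxel_spacing": self.voxel_spacing,
                    "bone_intensity": self.bone_intensity,
                    "cavity_intensity": self.cavity_intensity,
                    "background_intensity": self.background_intensity,
                    "noise_sd": self.noise_sd,
                    "wall_thickness": self.wall_thickness,
                    "rng_seed": self.rng_seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())

        def orbit(o):
            implant = None
            if o.get("implant"):
                implant = ImplantSpec(
                    tuple(o["implant"]["center"]), o["implant"]["diameter_mm"]
                )
            return OrbitSpec(
                rim_width=o["rim_width"],
                rim_height=o["rim_height"],
                depth=o["depth"],
                rim_center=tuple(o["rim_center"]),
                shape=o.get("shape", "elliptic-cone"),
                gaps=tuple(GapSpec(*g) for g in o.get("gaps", [])),
                implant=implant,
            )

        return cls(
            left=orbit(d["left"]),
            right=orbit(d["right"]),
            voxel_spacing=d.get("voxel_spacing", 0.3),
            bone_intensity=d.get("bone_intensity", 1000.0),
            cavity_intensity=d.get("cavity_intensity", 300.0),
            background_intensity=d.get("background_intensity", 100.0),
            noise_sd=d.get("noise_sd", 20.0),
            wall_thickness=d.get("wall_thickness", 2.0),
            rng_seed=d.get("rng_seed", 0),
        )


class GroundTruth:
    """Closed-form areas, volumes and gap positions for a phantom.

    Areas and volumes refer to the cavity interior (the quantity the
    slice-measurement stage estimates); depths are mm behind the rim plane.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec

    def _orbit(self, side: str) -> OrbitSpec:
        if side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
        return getattr(self.spec, side)

    @staticmethod
    def _rim_area(o: OrbitSpec) -> float:
        a, b = o.half_axes
        if o.shape == "elliptic-cone":
            return math.pi * a * b
        return 4.0 * a * b

    def area(self, side: str, depth_mm: float) -> float:
        """Analytic cavity cross-section area (mm^2) at a depth behind the rim."""
        o = self._orbit(side)
        if not (0.0 <= depth_mm <= o.depth):
            raise ValidationError(
                f"depth {depth_mm} mm outside [0, {o.depth}] for {side} orbit"
            )
        frac = 1.0 - depth_mm / o.depth
        return self._rim_area(o) * frac * frac

    def volume(self, side: str, depth_lo: float = 0.0, depth_hi: float | None = None) -> float:
        """Analytic cavity volume (mm^3) between two depths, clipped to the cavity."""
        o = self._orbit(side)
        if depth_hi is None:
            depth_hi = o.depth
        lo = max(0.0, min(depth_lo, o.depth))
        hi = max(0.0, min(depth_hi, o.depth))
        if hi < lo:
            raise ValidationError("depth_hi must be >= depth_lo")
        return self._integral(o, lo, hi)

    def slab_reference_volume(self, side: str, depth_lo: float, depth_hi: float) -> float:
        """Integral of the cavity's quadratic area profile over a slab.

        Unlike :meth:`volume`, the profile is continued analytically
        anterior of the rim plane (depth < 0), which is the exact quantity
        a midpoint-rule Cavalieri sum with slice 1 at the rim estimates.
        """
        o = self._orbit(side)
        hi = min(depth_hi, o.depth)
        if hi < depth_lo:
            raise ValidationError("slab is empty")
        return self._integral(o, depth_lo, hi)

    def _integral(self, o: OrbitSpec, lo: float, hi: float) -> float:
        D = o.depth
        A0 = self._rim_area(o)
        # integral of A0 (1 - d/D)^2 = -A0 D/3 (1 - d/D)^3
        def F(d):
            return -A0 * D / 3.0 * (1.0 - d / D) ** 3

        return F(hi) - F(lo)

    def gap_positions(self, side: str):
        return self._orbit(side).gaps


def analytic_area(gt: GroundTruth, side: str, depth_mm: float) -> float:
    """Functional alias for :meth:`GroundTruth.area`."""
    return gt.area(side, depth_mm)


# --------------------------------------------------------------------------
# voxelization
# --------------------------------------------------------------------------

def _grid_coords(spec: PhantomSpec):
    """Voxel-center coordinate vectors covering both orbits plus margin.

    y and z centers fall on integer multiples of the voxel spacing (so the
    rim plane at y = 0 is an exact grid plane) and x centers on half-integer
    multiples (so a geometrically mirror-symmetric spec voxelizes to a
    mirror-symmetric grid).
    """
    h = spec.voxel_spacing
    w = spec.wall_thickness
    margin = 3.0
    # generous ventrodorsal headroom so the orbits stay inside the field
    # of view under head rotations up to ~10 degrees about the vertical
    # axis (badly positioned heads beyond that are excluded, not rescued)
    margin_ant, margin_post = 12.0, 8.0
    xs, ys, zs = [], [], []
    for o in (spec.left, spec.right):
        a, b = o.half_axes
        cx, cy, cz = o.rim_center
        xs += [cx - a - w - margin, cx + a + w + margin]
        ys += [cy - o.depth - w - margin_post, cy + margin_ant]
        zs += [cz - b - w - margin, cz + b + w + margin]

    def centered(lo, hi, offset):
        i0 = math.floor((lo - offset) / h)
        i1 = math.ceil((hi - offset) / h)
        return offset + h * np.arange(i0, i1 + 1)

    # x and y centers at half-integer multiples of h: x so that a mirror-
    # symmetric spec voxelizes symmetrically, y so that the rim plane
    # (y = 0) falls midway between voxel-center planes — the generic grid
    # placement, under which center-rule voxel counting is unbiased.
    return (
        centered(min(xs), max(xs), h / 2),
        centered(min(ys), max(ys), h / 2),
        centered(min(zs), max(zs), 0.0),
    )


def _orbit_masks(o: OrbitSpec, side_sign: float, x, y, z, wall: float):
    """Boolean (cavity, bone) masks for one orbit on coordinate vectors."""
    a0, b0 = o.half_axes
    cx, cy, cz = o.rim_center
    X = (x - cx)[:, None, None]
    Y = y[None, :, None]
    Z = (z - cz)[None, None, :]
    d = cy - Y  # depth behind the rim plane (dorsal = -y)
    frac = np.clip(1.0 - d / o.depth, 0.0, None)
    in_depth = (d >= 0.0) & (d <= o.depth)
    in_shell_depth = (d >= 0.0) & (d <= o.depth + wall)

    if o.shape == "elliptic-cone":
        a_d = a0 * frac
        b_d = b0 * frac
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(a_d > 0, (X / np.where(a_d > 0, a_d, 1.0)) ** 2, np.inf) + np.where(
                b_d > 0, (Z / np.where(b_d > 0, b_d, 1.0)) ** 2, np.inf
            )
        cavity = in_depth & (q <= 1.0) & (a_d > 0)
        q_out = (X / (a_d + wall)) ** 2 + (Z / (b_d + wall)) ** 2
        shell = in_shell_depth & (q_out <= 1.0)
    else:  # rectangular pyramid
        a_d = a0 * frac
        b_d = b0 * frac
        cavity = in_depth & (np.abs(X) <= a_d) & (np.abs(Z) <= b_d) & (a_d > 0)
        shell = in_shell_depth & (np.abs(X) <= a_d + wall) & (np.abs(Z) <= b_d + wall)

    bone = shell & ~cavity

    # anterior rim flange: the facial bone surrounding the orbital entry.
    # The entry itself stays open, but the rim ring extends one wall
    # thickness anterior of the frame plane, so the ring at depth 0 has
    # bone support on both sides under trilinear resampling.
    ant = (d >= -wall) & (d < 0.0)
    if o.shape == "elliptic-cone":
        in_rim = (X / a0) ** 2 + (Z / b0) ** 2 <= 1.0
        in_rim_out = (X / (a0 + wall)) ** 2 + (Z / (b0 + wall)) ** 2 <= 1.0
    else:
        in_rim = (np.abs(X) <= a0) & (np.abs(Z) <= b0)
        in_rim_out = (np.abs(X) <= a0 + wall) & (np.abs(Z) <= b0 + wall)
    bone |= ant & in_rim_out & ~in_rim

    if o.gaps:
        theta = np.arctan2(np.broadcast_to(Z, bone.shape), side_sign * X)
        for g in o.gaps:
            a_d_g = np.maximum(a0 * frac, 1e-6)
            b_d_g = np.maximum(b0 * frac, 1e-6)
            if o.shape == "elliptic-cone":
                ct, st = np.cos(np.radians(g.angle_deg)), np.sin(np.radians(g.angle_deg))
                r_loc = a_d_g * b_d_g / np.sqrt((b_d_g * ct) ** 2 + (a_d_g * st) ** 2)
            else:
                r_loc = np.sqrt(a_d_g * b_d_g)
            half_ang = (g.width_mm / 2.0) / r_loc
            dtheta = np.angle(np.exp(1j * (theta - np.radians(g.angle_deg))))
            in_gap = (d >= g.depth_lo) & (d <= g.depth_hi) & (np.abs(dtheta) <= half_ang)
            bone &= ~in_gap

    if o.implant is not None:
        ic = np.asarray(o.implant.center, float)
        r = o.implant.diameter_mm / 2.0
        _validate_implant(o, ic, r)
        rr = (
            (x - ic[0])[:, None, None] ** 2
            + (y - ic[1])[None, :, None] ** 2
            + (z - ic[2])[None, None, :] ** 2
        )
        implant = rr <= r * r
        bone = bone | implant

    return cavity, bone


def _validate_implant(o: OrbitSpec, center: np.ndarray, radius: float):
    a0, b0 = o.half_axes
    cx, cy, cz = o.rim_center
    depths = np.linspace(cy - center[1] - radius, cy - center[1] + radius, 21)
    for d in depths:
        if d < 0 or d > o.depth:
            raise GeometryError("implant extends outside the cavity depth range")
        frac = 1.0 - d / o.depth
        a_d, b_d = a0 * frac, b0 * frac
        if min(a_d, b_d) <= 1e-9:
            raise GeometryError("implant reaches the apex")
        # chord radius of the sphere at this depth plane
        chord = math.sqrt(max(radius**2 - (d - (cy - center[1])) ** 2, 0.0))
        q = math.hypot((center[0] - cx) / a_d, (center[2] - cz) / b_d)
        if q + chord / min(a_d, b_d) > 1.0:
            raise GeometryError("implant does not lie entirely inside the cavity")


def label_volume(spec: PhantomSpec):
    """Voxelize a phantom spec into labels (0 bg, 1 cavity, 2 bone).

    Returns ``(labels, spacing, origin)``; a voxel is labeled by its center
    (bone iff the center sits in the wall shell and outside every gap).
    """
    x, y, z = _grid_coords(spec)
    labels = np.zeros((x.size, y.size, z.size), dtype=np.uint8)
    cav_l, bone_l = _orbit_masks(spec.left, -1.0, x, y, z, spec.wall_thickness)
    cav_r, bone_r = _orbit_masks(spec.right, +1.0, x, y, z, spec.wall_thickness)
    shell_l = cav_l | bone_l
    shell_r = cav_r | bone_r
    if np.any(shell_l & shell_r):
        raise GeometryError("left and right orbital cavities overlap")
    labels[cav_l | cav_r] = LABEL_CAVITY
    labels[bone_l | bone_r] = LABEL_BONE
    origin = np.array([x[0], y[0], z[0]])
    spacing = np.full(3, spec.voxel_spacing)
    return labels, spacing, origin


def generate_phantom(spec: PhantomSpec):
    """Render a phantom spec into an intensity volume plus its ground truth.

    Intensities: background / cavity / bone levels from the spec, implant
    voxels at bone level, plus seeded additive Gaussian noise.
    """
    labels, spacing, origin = label_volume(spec)
    lut = np.array(
        [spec.background_intensity, spec.cavity_intensity, spec.bone_intensity]
    )
    voxels = lut[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=voxels.shape)
    vol = VolumeImage(voxels, spacing, origin)
    return vol, GroundTruth(spec)


def make_asymmetric_pair(
    spec: PhantomSpec, shrink_fraction: float, side: str = "left"
) -> PhantomSpec:
    """Shrink one orbit's rim and depth by ``(1 - shrink_fraction)``.

    Emulates the operated-vs-healthy contrast: the shrunken side's analytic
    volume scales by ``(1 - shrink_fraction)**3``.
    """
    if not (0.0 <= shrink_fraction < 1.0):
        raise ValidationError("shrink_fraction must be in [0, 1)")
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    s = 1.0 - shrink_fraction
    o = getattr(spec, side)
    shrunk = replace(
        o, rim_width=o.rim_width * s, rim_height=o.rim_height * s, depth=o.depth * s
    )
    return replace(spec, **{side: shrunk})


def phantom_landmarks(spec: PhantomSpec) -> dict:
    """Canonical-frame landmarks for a phantom (world mm).

    The entry-dorsal landmarks sit at the rim centers in the rim plane;
    rim superior/inferior landmarks at the vertical rim extremes.
    """
    out = {}
    for side in ("left", "right"):
        o = getattr(spec, side)
        cx, cy, cz = o.rim_center
        b0 = o.rim_height / 2.0
        out[f"{side}_entry_dorsal"] = np.array([cx, cy, cz], float)
        out[f"{side}_rim_superior"] = np.array([cx, cy, cz + b0], float)
        out[f"{side}_rim_inferior"] = np.array([cx, cy, cz - b0], float)
    return out
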