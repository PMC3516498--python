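"""Landmark-based canonical reorientation.

The measurement frame is defined by the most dorsal points of the two
orbital entries: after alignment their connecting line is parallel to the
left-right axis, their midpoint is the world origin, and the coronal plane
through them (y = 0) is the frame plane from which slices proceed dorsally.
Roll about the inter-orbital axis is left at zero unless superior/inferior
rim landmarks are supplied, in which case the mean rim axis is made
vertical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .imaging import RigidTransform, VolumeImage, resample_rigid

REQUIRED_LANDMARKS = ("right_entry_dorsal", "left_entry_dorsal")
OPTIONAL_LANDMARKS = (
    "right_rim_superior",
    "right_rim_inferior",
    "left_rim_superior",
    "left_rim_inferior",
)


@dataclass
class LandmarkSet:
    """Named anatomical points in world mm."""

    points: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        missing = [n for n in REQUIRED_LANDMARKS if n not in pts]
        if missing:
            raise ValidationError(
                f"missing required landmarks {missing}; required names are "
                f"{list(REQUIRED_LANDMARKS)} (optional: {list(OPTIONAL_LANDMARKS)})"
            )
        for name, p in pts.items():
            if p.shape != (3,):
                raise ValidationError(f"landmark {name!r} is not a 3-D point")
        r, l = pts["right_entry_dorsal"], pts["left_entry_dorsal"]
        if np.allclose(r, l):
            raise ValidationError("entry-dorsal landmarks are coincident")
        if abs(r[0] - l[0]) < 1e-9:
            raise ValidationError(
                "entry-dorsal landmarks must differ in the left-right coordinate"
            )
        self.points = pts

    def __getitem__(self, name):
        return self.points[name]

    def __contains__(self, name):
        return name in self.points

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({k: t.apply(p) for k, p in self.points.items()})


def _minimal_rotation(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector u onto unit vector w (Rodrigues)."""
    c = float(np.dot(u, w))
    axis = np.cross(u, w)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about the vertical axis
        return np.diag([-1.0, -1.0, 1.0])
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def canonical_transform(lm: LandmarkSet) -> RigidTransform:
    """Rigid transform into the canonical measurement frame.

    After the transform the two entry-dorsal landmarks share the same
    ventrodorsal (y) and vertical (z) coordinates, their midpoint is the
    origin, and the rotation is the minimal one achieving this (roll fixed
    by rim landmarks when present, otherwise zero).
    """
    r = lm["right_entry_dorsal"]
    l = lm["left_entry_dorsal"]
    v = r - l
    R1 = _minimal_rotation(v / np.linalg.norm(v), np.array([1.0, 0.0, 0.0]))

    R = R1
    rim_names = ("rim_superior", "rim_inferior")
    have_rims = all(
        f"{side}_{n}" in lm for side in ("left", "right") for n in rim_names
    )
    if have_rims:
        axes = []
        for side in ("left", "right"):
            axes.append(lm[f"{side}_rim_superior"] - lm[f"{side}_rim_inferior"])
        u = R1 @ np.mean(axes, axis=0)
        if np.hypot(u[1], u[2]) < 1e-9:
            warnings.warn(
                "rim landmarks leave roll unconstrained; roll set to zero",
                stacklevel=2,
            )
        else:
            phi = np.arctan2(u[1], u[2])
            c, s = np.cos(phi), np.sin(phi)
            Rx = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
            R = Rx @ R1

    midpoint = (r + l) / 2.0
    return RigidTransform(R, -R @ midpoint)


def align_volume(vol: VolumeImage, lm: LandmarkSet):
    """Resample a volume into the canonical frame.

    Returns ``(aligned_volume, transform)`` where the transform is the one
    produced by :func:`canonical_transform` for these landmarks.
    """
    for name, p in lm.points.items():
        if not vol.contains_point(p):
            raise ValidationError(
                f"landmark {name!r} at {p.tolist()} lies outside the volume extent"
            )
    t = canonical_transform(lm)
    return resample_rigid(vol, t), t
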