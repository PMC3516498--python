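"""End-to-end single-case pipeline and report rendering.

One run handles one head: align into the canonical frame, measure both
orbits, build the 3-rater x 3-repeat area table, run the per-slice paired
comparison and classify the case.  Cohort tallies are a separate pass
(:func:`orbitovol.stats.summarize_cohort`) over many case reports,
mirroring per-patient measurement followed by a cohort summary.

The 3-rater x 3-repeat area table is produced from the single
deterministic measurement per side by adding seeded Gaussian rater noise
(``rater_noise_sd``, mm^2), emulating human re-tracing variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import LandmarkSet, align_volume
from .config import ProtocolConfig
from .errors import ValidationError
from .imaging import load_landmarks_json, read_volume
from .measure import measure_orbit
from .phantom import PhantomSpec, generate_phantom, phantom_landmarks
from .stats import classify_case, simulate_repeated_measures, slice_significance

REPORT_SCHEMA = "orbitovol-report-1"


@dataclass
class RunConfig:
    """Configuration for one end-to-end case run.

    The input is either a volume + landmarks pair of files, or a phantom
    spec (JSON) rendered on the fly.  Seed points are world-mm points
    inside each cavity at the frame plane, in the ORIGINAL (pre-alignment)
    coordinates; for phantom input they default to the rim centers.
    """

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    volume_path: str | None = None
    landmarks_path: str | None = None
    phantom_spec_path: str | None = None
    seed_left: tuple | None = None
    seed_right: tuple | None = None
    operated_side: str = "left"
    rater_noise_sd: float = 10.0
    report_format: str = "json"
    output_dir: str | None = None
    rng_seed: int = 0
    case_id: str = "case"

    def __post_init__(self):
        if self.phantom_spec_path is None:
            if self.volume_path is None or self.landmarks_path is None:
                raise ValidationError(
                    "provide either phantom_spec_path or both volume_path "
                    "and landmarks_path"
                )
            for p in (self.volume_path, self.landmarks_path):
                if not Path(p).exists():
                    raise ValidationError(f"input file not found: {p}")
            if self.seed_left is None or self.seed_right is None:
                raise ValidationError("seed_left and seed_right are required")
        elif not Path(self.phantom_spec_path).exists():
            raise ValidationError(
                f"phantom spec not found: {self.phantom_spec_path}"
            )
        if self.operated_side not in ("left", "right"):
            raise ValidationError("operated_side must be 'left' or 'right'")
        if self.report_format not in ("json", "csv", "html"):
            raise ValidationError("report_format must be json, csv or html")
        if self.rater_noise_sd < 0:
            raise ValidationError("rater_noise_sd must be >= 0")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        proto = ProtocolConfig(**d.pop("protocol", {}))
        for key in ("seed_left", "seed_right"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(protocol=proto, **d)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute align -> measure (both sides) -> compare -> classify.

    Returns the case report as a plain dict (JSON-serializable).  All
    randomness (rater noise) derives from ``cfg.rng_seed``; reruns with the
    same config and inputs are bit-identical.
    """
    if cfg.phantom_spec_path is not None:
        spec = PhantomSpec.from_json(cfg.phantom_spec_path)
        vol, _ = generate_phantom(spec)
        lm = LandmarkSet(phantom_landmarks(spec))
        seeds = {
            "left": np.asarray(spec.left.rim_center, float),
            "right": np.asarray(spec.right.rim_center, float),
        }
    else:
        vol = read_volume(cfg.volume_path)
        lm = LandmarkSet(load_landmarks_json(cfg.landmarks_path))
        seeds = {
            "left": np.asarray(cfg.seed_left, float),
            "right": np.asarray(cfg.seed_right, float),
        }
    if cfg.seed_left is not None:
        seeds["left"] = np.asarray(cfg.seed_left, float)
    if cfg.seed_right is not None:
        seeds["right"] = np.asarray(cfg.seed_right, float)

    aligned, transform = align_volume(vol, lm)

    measurements = {}
    for side in ("left", "right"):
        seed_aligned = transform.apply(seeds[side])
        measurements[side] = measure_orbit(aligned, side, seed_aligned, cfg.protocol)

    rng = np.random.default_rng(cfg.rng_seed)
    rm = simulate_repeated_measures(
        {side: m.areas_mm2 for side, m in measurements.items()},
        noise_sd=cfg.rater_noise_sd,
        rng=rng,
        n_raters=cfg.protocol.n_raters,
        n_repeats=cfg.protocol.n_repeats,
        case_id=cfg.case_id,
    )
    pattern = slice_significance(rm, cfg.protocol, operated_side=cfg.operated_side)
    category = classify_case(pattern)

    return {
        "schema": REPORT_SCHEMA,
        "case_id": cfg.case_id,
        "operated_side": cfg.operated_side,
        "alpha": cfg.protocol.alpha,
        "interval_mm": cfg.protocol.interval_mm,
        "n_slices": cfg.protocol.n_slices,
        "rater_noise_sd": cfg.rater_noise_sd,
        "rng_seed": cfg.rng_seed,
        "transform": {
            "rotation": [float(v) for v in transform.rotation.ravel()],
            "translation": [float(v) for v in transform.translation],
        },
        "measurements": {s: m.to_dict() for s, m in measurements.items()},
        "p_values": list(pattern.p_values),
        "flags": list(pattern.flags),
        "category": category.category,
        "n_significant": category.n_significant,
        "atypical": category.atypical,
    }


def _report_rows(report: dict):
    for side in ("left", "right"):
        for s in report["measurements"][side]["slices"]:
            yield (
                side,
                s["slice_index"],
                s["plane_position_mm"],
                s["area_mm2"],
            )


def render_report(report: dict, fmt: str, path) -> None:
    """Serialize a case report deterministically.

    ``json`` is the full report; ``csv`` is the per-slice area table with
    columns side, slice_index, plane_position_mm, area_mm2; ``html`` is a
    minimal standalone page with the same table plus the verdict.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        lines = ["side,slice_index,plane_position_mm,area_mm2"]
        for side, k, pos, area in _report_rows(report):
            lines.append(f"{side},{k},{pos:.6g},{area:.6g}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "html":
        rows = "\n".join(
            f"<tr><td>{side}</td><td>{k}</td><td>{pos:.6g}</td>"
            f"<td>{area:.6g}</td></tr>"
            for side, k, pos, area in _report_rows(report)
        )
        path.write_text(
            "<!DOCTYPE html>\n<html><head><title>orbitovol report "
            f"{report['case_id']}</title></head><body>\n"
            f"<h1>Case {report['case_id']}: category {report['category']} "
            f"({report['n_significant']} significant slices)</h1>\n"
            "<table border='1'><tr><th>side</th><th>slice_index</th>"
            "<th>plane_position_mm</th><th>area_mm2</th></tr>\n"
            f"{rows}\n</table>\n"
            f"<p>Left volume: {report['measurements']['left']['volume_mm3']:.6g} "
            "mm&sup3;; right volume: "
            f"{report['measurements']['right']['volume_mm3']:.6g} mm&sup3;.</p>\n"
            "</body></html>\n"
        )
    else:
        raise ValidationError(f"unknown report format {fmt!r}")


def load_report(path) -> dict:
    report = json.loads(Path(path).read_text())
    if report.get("schema") != REPORT_SCHEMA:
        raise ValidationError(f"unsupported report schema {report.get('schema')!r}")
    return report
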