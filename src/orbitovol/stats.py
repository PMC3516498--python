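"""Bilateral paired comparison, case classification, cohort summaries.

The comparison unit is the repeated-measures table of one case: slice
areas for both orbits measured by ``n_raters`` raters, each ``n_repeats``
times.  Per slice, the operated orbit's 9 measurements are paired with the
healthy orbit's measurements from the same (rater, repeat) cell and tested
with a classical paired t-test (two-sided p, no multiple-testing
correction across the five slices).  A slice is flagged when p < alpha AND
the operated mean is smaller — the question is specifically volume loss.

Case taxonomy over the five flags:

* **A** — slices 1-4 all flagged (the first four or all five significant);
* **C** — no slice flagged;
* **B** — anything else (one or more flagged, but not the full anterior
  run).  Patterns with >= 4 flags that still miss one of slices 1-4 are B
  but tagged atypical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ProtocolConfig
from .errors import DegenerateVarianceError, StatisticsError, ValidationError

SIDES = ("left", "right")


def paired_t(a, b):
    """Classical paired t-test on differences ``d = a - b``.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))``,
    ``df = n - 1`` and a two-sided p from the t distribution.

    Zero variance of the differences (including all-zero differences)
    leaves the statistic undefined and raises
    :class:`DegenerateVarianceError` rather than fabricating a p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired_t needs two equal-length 1-D samples")
    n = a.size
    if n < 2:
        raise ValidationError("paired_t needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError(
            "pairwise differences have zero variance; t is undefined"
        )
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


@dataclass
class RepeatedMeasures:
    """Slice areas for (side x slice x rater x repeat) of one case.

    Backed by a DataFrame with columns ``case_id, side, slice_index,
    rater, repeat, area_mm2``.
    """

    data: pd.DataFrame

    REQUIRED_COLUMNS = ("case_id", "side", "slice_index", "rater", "repeat", "area_mm2")

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"repeated-measures table missing columns {missing}")
        if (df["area_mm2"] < 0).any():
            raise ValidationError("areas must be non-negative")
        bad = set(df["side"]) - set(SIDES)
        if bad:
            raise ValidationError(f"unknown side labels {sorted(bad)}")
        dup = df.duplicated(["case_id", "side", "slice_index", "rater", "repeat"])
        if dup.any():
            raise ValidationError("duplicate (side, slice, rater, repeat) cells")
        # every populated cell needs both sides
        cells = df.set_index(["case_id", "slice_index", "rater", "repeat"])
        counts = cells.groupby(level=[0, 1, 2, 3])["side"].nunique()
        if (counts < 2).any():
            raise ValidationError(
                "incomplete pairing: some (slice, rater, repeat) cells lack one side"
            )
        self.data = df.reset_index(drop=True)

    @property
    def case_ids(self):
        return sorted(self.data["case_id"].unique())

    @property
    def slice_indices(self):
        return sorted(self.data["slice_index"].unique())

    def cell(self, case_id, side, slice_index) -> pd.Series:
        """Areas for one (side, slice), indexed by (rater, repeat)."""
        df = self.data
        sel = df[
            (df["case_id"] == case_id)
            & (df["side"] == side)
            & (df["slice_index"] == slice_index)
        ]
        return sel.set_index(["rater", "repeat"])["area_mm2"].sort_index()

    @classmethod
    def from_csv(cls, path) -> "RepeatedMeasures":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class SlicePattern:
    """Per-slice significance flags (true = operated orbit smaller)."""

    case_id: str
    flags: tuple
    p_values: tuple | None = None

    def __post_init__(self):
        self.flags = tuple(bool(f) for f in self.flags)
        if self.p_values is not None:
            self.p_values = tuple(float(p) for p in self.p_values)
            if len(self.p_values) != len(self.flags):
                raise ValidationError("p_values and flags lengths differ")

    @property
    def n_significant(self) -> int:
        return sum(self.flags)


@dataclass
class CaseCategory:
    category: str  # 'A' | 'B' | 'C'
    n_significant: int
    atypical: bool = False


def slice_significance(
    rm: RepeatedMeasures,
    cfg: ProtocolConfig | None = None,
    operated_side: str = "left",
    case_id=None,
) -> SlicePattern:
    """Per-slice paired comparison of the operated vs healthy orbit.

    Pairs the operated orbit's (rater, repeat) measurements with the
    healthy orbit's same-cell measurements; a slice is flagged iff the
    two-sided paired-t p is below alpha AND the operated mean is the
    smaller one.  No multiplicity correction is applied across slices.
    """
    cfg = cfg or ProtocolConfig()
    if operated_side not in SIDES:
        raise ValidationError(f"operated_side must be one of {SIDES}")
    healthy_side = "right" if operated_side == "left" else "left"
    if case_id is None:
        ids = rm.case_ids
        if len(ids) != 1:
            raise ValidationError("specify case_id for a multi-case table")
        case_id = ids[0]

    flags, ps = [], []
    for k in rm.slice_indices:
        op = rm.cell(case_id, operated_side, k)
        he = rm.cell(case_id, healthy_side, k)
        if not op.index.equals(he.index):
            raise ValidationError(
                f"slice {k}: (rater, repeat) cells differ between sides"
            )
        t, _, p = paired_t(op.to_numpy(), he.to_numpy())
        flags.append(p < cfg.alpha and op.mean() < he.mean())
        ps.append(p)
    return SlicePattern(case_id=str(case_id), flags=tuple(flags), p_values=tuple(ps))


def classify_case(pattern: SlicePattern) -> CaseCategory:
    """Map a significance pattern to its A/B/C category."""
    flags = pattern.flags
    n = pattern.n_significant
    if len(flags) >= 4 and all(flags[:4]):
        return CaseCategory("A", n)
    if n == 0:
        return CaseCategory("C", 0)
    return CaseCategory("B", n, atypical=n >= 4)


def summarize_cohort(patterns):
    """Tally categories and per-slice significant-case counts."""
    patterns = list(patterns)
    if not patterns:
        raise ValidationError("no patterns to summarize")
    counts = {"A": 0, "B": 0, "C": 0}
    n_slices = len(patterns[0].flags)
    per_slice = [0] * n_slices
    for p in patterns:
        if len(p.flags) != n_slices:
            raise ValidationError("patterns have differing slice counts")
        counts[classify_case(p).category] += 1
        for k, f in enumerate(p.flags):
            per_slice[k] += int(f)
    return {
        "count_A": counts["A"],
        "count_B": counts["B"],
        "count_C": counts["C"],
        "n_cases": len(patterns),
        "per_slice_significant": per_slice,
    }


def rater_reproducibility(rm: RepeatedMeasures, case_id=None) -> pd.DataFrame:
    """Intra- and inter-rater coefficients of variation per (side, slice).

    intra-rater CV: mean over raters of (sd across repeats / mean across
    repeats); inter-rater CV: sd / mean of the rater means.
    """
    if case_id is None:
        ids = rm.case_ids
        if len(ids) != 1:
            raise ValidationError("specify case_id for a multi-case table")
        case_id = ids[0]
    df = rm.data[rm.data["case_id"] == case_id]
    if df["rater"].nunique() < 2 or df["repeat"].nunique() < 2:
        raise ValidationError("need >= 2 raters and >= 2 repeats")
    rows = []
    for (side, k), grp in df.groupby(["side", "slice_index"]):
        by_rater = grp.groupby("rater")["area_mm2"]
        means = by_rater.mean()
        if (means == 0).any() or means.mean() == 0:
            raise StatisticsError(f"zero mean area in slice {k} ({side})")
        intra = (by_rater.std(ddof=1) / means).mean()
        inter = means.std(ddof=1) / means.mean()
        rows.append(
            {
                "side": side,
                "slice_index": k,
                "intra_rater_cv": float(intra),
                "inter_rater_cv": float(inter),
            }
        )
    return pd.DataFrame(rows).sort_values(["side", "slice_index"]).reset_index(drop=True)


def simulate_repeated_measures(
    true_areas: dict,
    noise_sd: float,
    rng,
    n_raters: int = 3,
    n_repeats: int = 3,
    rater_bias_sd: float = 0.0,
    case_id: str = "sim",
) -> RepeatedMeasures:
    """Simulate a rater table around true per-slice areas.

    ``true_areas`` maps side -> list of slice areas.  Each measurement is
    truth + (optional) per-rater bias + iid Gaussian noise; a rater's bias
    is shared across sides, as a human's systematic tracing style would be.
    Areas are clipped at zero.
    """
    rows = []
    biases = rng.normal(0.0, rater_bias_sd, size=n_raters) if rater_bias_sd else None
    for side, areas in true_areas.items():
        for k, area in enumerate(areas, start=1):
            for r in range(1, n_raters + 1):
                bias = biases[r - 1] if biases is not None else 0.0
                vals = area + bias + rng.normal(0.0, noise_sd, size=n_repeats)
                for rep, v in enumerate(vals, start=1):
                    rows.append(
                        {
                            "case_id": case_id,
                            "side": side,
                            "slice_index": k,
                            "rater": r,
                            "repeat": rep,
                            "area_mm2": max(float(v), 0.0),
                        }
                    )
    return RepeatedMeasures(pd.DataFrame(rows))


def load_reference_cohort_flags():
    """Per-slice significance flags for the 20-case implant reference cohort.

    Ships with the package as a CSV of yes/no flags (one row per case,
    columns slice1..slice5) and is used to validate the classification and
    summary rules; returns a list of :class:`SlicePattern`.
    """
    with resources.files("orbitovol.data").joinpath(
        "reference_cohort_flags.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    patterns = []
    for _, row in df.iterrows():
        flags = tuple(
            str(row[f"slice{k}"]).strip().lower() == "yes" for k in range(1, 6)
        )
        patterns.append(SlicePattern(case_id=str(row["case"]), flags=flags))
    return patterns
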