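"""Gravitropic set-point angle (GSA) quantification and comparison.

The GSA of an organ is the angle between its base-to-tip axis and the
gravity vector: 0 deg = growing straight down, 90 deg = horizontal. This
module extracts that angle (and the flank cell-length asymmetry) from
simulated tissues, bins measured per-LR angles into the six standard
categories with plate-level mean +/- SEM, and compares angle distributions
with the two-sample Kolmogorov-Smirnov test.

Angle tables are plain pandas DataFrames with columns ``angle_deg``,
``plate_id``, ``seedling_id`` and ``label`` (genotype/treatment); the plate
is the replicate unit, so SEM is computed across plates, not across
individual lateral roots.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateGeometryError, InvalidStateError
from .geometry import Tissue

#: Category bin edges in degrees; intervals are half-open (lo, hi] with 0
#: assigned to the first bin, so the printed integer labels 0-30 | 31-50 | ...
#: get a deterministic boundary convention for continuous angles.
CATEGORY_EDGES = (0.0, 30.0, 50.0, 70.0, 90.0, 110.0, 180.0)
CATEGORY_LABELS = ("0-30", "31-50", "51-70", "71-90", "91-110", "111-180")

GSA_COLUMNS = ("angle_deg", "plate_id", "seedling_id", "label")


def validate_gsa(df: pd.DataFrame) -> pd.DataFrame:
    """Check an angle table: required columns present, angles in [0, 180]."""
    missing = [c for c in ("angle_deg", "plate_id") if c not in df.columns]
    if missing:
        raise ValueError(f"angle table lacks required columns: {missing}")
    bad = df.index[(df["angle_deg"] < 0) | (df["angle_deg"] > 180)
                   | df["angle_deg"].isna()]
    if len(bad):
        raise ValueError(
            f"angles outside [0, 180] at records {list(bad[:5])}"
            + ("..." if len(bad) > 5 else ""))
    return df


def bending_angle(tissue: Tissue, gravity=None) -> float:
    """Set-point angle (degrees) of the simulated organ vs the gravity vector.

    The organ axis runs from the centroid of the fixed base vertex column to
    the centroid of the tip-most vertex column. Invariant under rigid
    translation; reflection about the gravity axis preserves the angle.
    """
    if tissue.n_cols < 2:
        raise ValueError("need at least 2 cell columns to define an axis")
    g = np.asarray(tissue.gravity_direction if gravity is None else gravity,
                   dtype=float)
    g = g / np.linalg.norm(g)
    nvr = tissue.n_rows + 1
    tip = tissue.positions[:nvr].mean(axis=0)
    base = tissue.positions[tissue.n_cols * nvr:].mean(axis=0)
    axis = tip - base
    norm = float(np.linalg.norm(axis))
    if norm < 1e-12:
        raise DegenerateGeometryError("zero-length base-to-tip axis")
    cosang = float(np.clip(np.dot(axis, g) / norm, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def flank_fold_change(tissue: Tissue) -> float:
    """Upper/lower flank asymmetry of current axial cell lengths.

    Mean axial length of top-row elongation-zone cells divided by the mean
    of their bottom-row counterparts; the wild-type simulation ends above
    2-fold.
    """
    lengths = tissue.cell_axial_lengths()
    top = (tissue.cell_row == tissue.n_rows - 1) & tissue.elongating
    bottom = (tissue.cell_row == 0) & tissue.elongating
    if not top.any() or not bottom.any():
        raise InvalidStateError("no elongation-zone cells on one of the flanks")
    return float(lengths[top].mean() / lengths[bottom].mean())


@dataclasses.dataclass
class CategoryDistribution:
    """Per-plate and plate-averaged percentages over the six GSA categories."""

    labels: tuple[str, ...]
    per_plate: pd.DataFrame  # index plate_id, columns labels, values %
    mean: pd.Series
    sem: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.per_plate.T
        out.columns = [f"plate_{p}" for p in out.columns]
        out.insert(0, "mean_pct", self.mean)
        out.insert(1, "sem_pct", self.sem)
        out.index.name = "category"
        return out


def bin_gsa(df: pd.DataFrame) -> CategoryDistribution:
    """Bin per-LR angles into the six categories, per plate, with mean +/- SEM.

    Each angle lands in exactly one half-open interval (0,30], (30,50],
    (50,70], (70,90], (90,110], (110,180] (0 counts into the first bin).
    Percentages are computed within each plate; the across-plate mean and
    SEM (sd / sqrt(n_plates), plates as replicate unit) summarize them.
    """
    if len(df) == 0:
        raise ValueError("empty angle table")
    validate_gsa(df)
    edges = np.asarray(CATEGORY_EDGES)
    rows = {}
    for plate, sub in df.groupby("plate_id", sort=True):
        idx = np.digitize(sub["angle_deg"].to_numpy(), edges[1:-1], right=True)
        counts = np.bincount(idx, minlength=len(CATEGORY_LABELS))
        rows[plate] = counts / counts.sum() * 100.0
    per_plate = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=list(CATEGORY_LABELS))
    per_plate.index.name = "plate_id"
    n = per_plate.shape[0]
    mean = per_plate.mean(axis=0)
    sem = per_plate.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 \
        else pd.Series(0.0, index=per_plate.columns)
    return CategoryDistribution(CATEGORY_LABELS, per_plate, mean, sem)


@dataclasses.dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    D: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(a, b) -> KSResult:
    """Two-sample KS test: exact D, asymptotic two-sided p-value.

    D is the supremum of |ECDF_a - ECDF_b| evaluated exactly over the pooled
    sample points; the p-value comes from the asymptotic Kolmogorov
    distribution at effective sample size n1*n2/(n1+n2) — the standard
    large-sample form at the tens-to-hundreds of LRs per comparison.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / n1
    cdf_b = np.searchsorted(b, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(sps.kstwobign.sf(np.sqrt(en) * d), 0.0, 1.0))
    return KSResult(D=d, p_value=p, n1=n1, n2=n2)


def compare_groups(df: pd.DataFrame, label_a: str, label_b: str,
                   label_col: str = "label"
                   ) -> tuple[KSResult, CategoryDistribution, CategoryDistribution]:
    """KS comparison + per-group category distributions for two labels."""
    validate_gsa(df)
    if label_col not in df.columns:
        raise ValueError(f"angle table lacks column {label_col!r}")
    parts = {}
    for lab in (label_a, label_b):
        sub = df[df[label_col] == lab]
        if len(sub) == 0:
            raise ValueError(f"label {lab!r} not present in the angle table")
        parts[lab] = sub
    ks = ks_two_sample(parts[label_a]["angle_deg"], parts[label_b]["angle_deg"])
    return ks, bin_gsa(parts[label_a]), bin_gsa(parts[label_b])


def mean_angle_ttest(df: pd.DataFrame, label_a: str, label_b: str,
                     label_col: str = "label") -> tuple[float, float]:
    """Two-sample Student's t contrast of mean GSA (convenience wrapper)."""
    validate_gsa(df)
    a = df.loc[df[label_col] == label_a, "angle_deg"]
    b = df.loc[df[label_col] == label_b, "angle_deg"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both labels must be present")
    t, p = sps.ttest_ind(a, b)
    return float(t), float(p)
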