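"""Segmentation metrics and paired statistical comparison.

Two clinical-standard metrics quantify agreement between a propagated
contour A and the ground-truth contour B:

* Dice similarity coefficient, ``DSC = 2|A ∩ B| / (|A| + |B|)`` — a
  unitless overlap in [0, 1];
* 95th-percentile Hausdorff distance — the largest separation among the
  closest 95% of surface-to-surface distances, reported in cm.

The 95HD here is the *pooled symmetric* variant: directed nearest-surface
distances A→B and B→A are pooled into one set whose 95th percentile
(linear interpolation between order statistics) is returned.  Strategy
comparisons use the classic two-tailed paired t-test at the 0.05 level, as
is conventional for per-patient metric pairs; no multiple-testing
correction is applied (single-threshold reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .imaging import EmptyStructureError, LabelMap, extract_surface_voxels


@dataclass
class EvaluationRecord:
    """One (target, strategy, structure) metric pair."""

    target_id: str
    strategy: str
    structure: str
    dsc: float
    hd95_cm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError(f"DSC must be in [0, 1], got {self.dsc}")
        if self.hd95_cm < 0:
            raise ValueError(f"95HD must be non-negative, got {self.hd95_cm}")


def dice(a: LabelMap, b: LabelMap, label: int = 1) -> float:
    """Dice similarity coefficient of one label; exact integer arithmetic."""
    if not a.same_grid(b):
        raise ValueError("masks must share one grid")
    ma = a.binary(label)
    mb = b.binary(label)
    size_a = int(ma.sum())
    size_b = int(mb.sum())
    if size_a + size_b == 0:
        raise EmptyStructureError(f"label {label} empty in both masks; DSC undefined")
    inter = int((ma & mb).sum())
    return 2 * inter / (size_a + size_b)


def hd95(a: LabelMap, b: LabelMap, label: int = 1) -> float:
    """Pooled symmetric 95th-percentile Hausdorff distance, in cm."""
    if not a.same_grid(b):
        raise ValueError("masks must share one grid")
    pa = extract_surface_voxels(a, label)
    pb = extract_surface_voxels(b, label)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.percentile(pooled, 95)) / 10.0  # mm -> cm


def hausdorff(a: LabelMap, b: LabelMap, label: int = 1) -> float:
    """Exact (100th percentile) symmetric Hausdorff distance, in cm."""
    pa = extract_surface_voxels(a, label)
    pb = extract_surface_voxels(b, label)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    return float(max(d_ab.max(), d_ba.max())) / 10.0


def paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test on per-target score pairs.

    Returns ``(t, p)`` with ``p`` from Student's t with n-1 degrees of
    freedom.  Identical-variance-zero differences are degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D score vectors, n >= 3")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero-variance differences: paired t-test degenerate")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def evaluate_segmentation(
    fused: LabelMap,
    truth: LabelMap,
    structures: dict[int, str],
    target_id: str,
    strategy: str,
) -> list[EvaluationRecord]:
    """Per-structure DSC and 95HD of a fused multi-label map vs truth."""
    records = []
    for label, name in structures.items():
        try:
            d = dice(fused, truth, label)
        except EmptyStructureError:
            d = 0.0
        try:
            h = hd95(fused, truth, label)
        except EmptyStructureError:
            # a missing propagated structure gets the worst defensible
            # surface distance: the truth structure's own extent scale
            h = float("nan")
        records.append(EvaluationRecord(target_id, strategy, name, d, h))
    return records


def records_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def summarize(
    records: list[EvaluationRecord],
    reference_strategy: str | None = None,
) -> pd.DataFrame:
    """Mean ± sd of DSC and 95HD per (strategy, structure), plus paired-t
    p-values against a reference strategy.

    Requires a balanced design: every strategy evaluated on every target.
    The sample standard deviation (ddof=1) is reported, matching the
    convention of mean ± sd result tables.
    """
    df = records_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    counts = df.pivot_table(
        index="strategy", columns="structure", values="target_id", aggfunc="nunique"
    )
    expected = df["target_id"].nunique()
    missing = [
        (s, c)
        for s in counts.index
        for c in counts.columns
        if (pd.isna(counts.loc[s, c]) or counts.loc[s, c] != expected)
    ]
    if missing:
        raise ValueError(f"unbalanced design; missing/partial cells: {missing}")

    rows = []
    for (strategy, structure), grp in df.groupby(["strategy", "structure"]):
        row = {
            "strategy": strategy,
            "structure": structure,
            "dsc_mean": grp["dsc"].mean(),
            "dsc_sd": grp["dsc"].std(ddof=1) if len(grp) > 1 else 0.0,
            "hd95_cm_mean": grp["hd95_cm"].mean(),
            "hd95_cm_sd": grp["hd95_cm"].std(ddof=1) if len(grp) > 1 else 0.0,
            "n": len(grp),
        }
        if reference_strategy is not None and strategy != reference_strategy:
            ref = df[
                (df["strategy"] == reference_strategy)
                & (df["structure"] == structure)
            ].set_index("target_id")
            this = grp.set_index("target_id").loc[ref.index]
            for metric, col in (("dsc", "p_dsc_vs_ref"), ("hd95_cm", "p_hd95_vs_ref")):
                try:
                    _, p = paired_ttest(this[metric].values, ref[metric].values)
                except ValueError:
                    p = float("nan")
                row[col] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index(["strategy", "structure"]).sort_index()
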