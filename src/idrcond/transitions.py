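"""Chromatin-accessibility transition encoding across conditions.

Condition-level ATAC peak files are merged (gap <= 100 bp), unified into
a reference peak set, and each reference peak is scored open/closed per
condition by >= 1 bp overlap.  The per-peak states, read in a fixed
condition order, form a pattern code such as "CCOC" (closed, closed,
open, closed); pattern counts and conditional transition queries (e.g.
of the peaks that open specifically in one condition, what fraction
stays open in another) summarize the accessibility landscape.

Intervals are BED-style: 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config

__all__ = [
    "PeakSet",
    "OccupancyMatrix",
    "merge_peaks",
    "build_reference",
    "label_occupancy",
    "encode_patterns",
    "pattern_counts",
    "query_transition",
    "sample_peaks",
    "read_bed",
    "write_bed",
]

_BED_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class PeakSet:
    """Sorted, non-overlapping intervals for one condition."""

    condition: str
    intervals: pd.DataFrame  # columns chrom, start, end; sorted, disjoint

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class OccupancyMatrix:
    """Binary open/closed states of reference peaks across conditions."""

    reference: pd.DataFrame          # chrom, start, end
    states: pd.DataFrame             # boolean, one column per condition
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.states.columns) != list(self.conditions):
            raise ValueError("state columns must match the condition order")
        if len(self.states) != len(self.reference):
            raise ValueError("one state row per reference peak required")


def _as_frame(intervals) -> pd.DataFrame:
    df = pd.DataFrame(intervals, columns=_BED_COLUMNS) if not isinstance(
        intervals, pd.DataFrame) else intervals[_BED_COLUMNS].copy()
    if len(df) == 0:
        return df.astype({"start": int, "end": int}, errors="ignore")
    df = df.astype({"start": int, "end": int})
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValueError(f"malformed interval at line {int(bad[0]) + 1}")
    return df


def merge_peaks(intervals, max_gap: int = config.MERGE_MAX_GAP,
                condition: str = "") -> PeakSet:
    """Sort intervals and fuse neighbours separated by <= ``max_gap`` bp.

    bedtools-merge semantics: touching or overlapping intervals always
    fuse, and a gap of exactly ``max_gap`` still fuses.
    """
    df = _as_frame(intervals)
    if len(df) == 0:
        return PeakSet(condition, df)
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    cur = None
    for chrom, start, end in df.itertuples(index=False):
        if cur is not None and chrom == cur[0] and start - cur[2] <= max_gap:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [chrom, start, end]
    rows.append(tuple(cur))
    return PeakSet(condition, pd.DataFrame(rows, columns=_BED_COLUMNS))


def build_reference(peak_sets: dict[str, PeakSet],
                    max_gap: int = config.MERGE_MAX_GAP) -> PeakSet:
    """Unified reference peak set: all conditions' peaks pooled and
    merged with the same gap rule."""
    if not peak_sets:
        raise ValueError("need at least one condition")
    pooled = pd.concat([ps.intervals for ps in peak_sets.values()],
                       ignore_index=True)
    if len(pooled) == 0:
        warnings.warn("no peaks in any condition; reference is empty")
        return PeakSet("reference", pooled)
    ref = merge_peaks(pooled, max_gap=max_gap, condition="reference")
    return ref


def _overlaps(ref: pd.DataFrame, cond: pd.DataFrame, min_overlap: int) -> np.ndarray:
    """Boolean per reference row: overlap of >= min_overlap bp with any
    condition interval (same chromosome)."""
    out = np.zeros(len(ref), dtype=bool)
    for chrom, sub in cond.groupby("chrom", sort=False):
        sel = ref["chrom"] == chrom
        if not sel.any():
            warnings.warn(f"chromosome {chrom!r} absent from reference; ignored")
            continue
        r = ref.loc[sel]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        for i, (_, s, e) in zip(r.index, r.itertuples(index=False)):
            j = np.searchsorted(starts, e)  # intervals starting before ref end
            if j == 0:
                continue
            ov = np.minimum(ends[:j], e) - np.maximum(starts[:j], s)
            if ov.max() >= min_overlap:
                out[ref.index.get_loc(i)] = True
    return out


def label_occupancy(
    reference: PeakSet,
    peak_sets: dict[str, PeakSet],
    min_overlap: int = config.MIN_OVERLAP,
) -> OccupancyMatrix:
    """Open/closed state of each reference peak in each condition.

    A reference peak is open in a condition iff it overlaps any of that
    condition's (merged) peaks by at least ``min_overlap`` bp.
    """
    ref = reference.intervals.reset_index(drop=True)
    states = {}
    for cond, ps in peak_sets.items():
        states[cond] = _overlaps(ref, ps.intervals, min_overlap)
    return OccupancyMatrix(ref, pd.DataFrame(states), tuple(peak_sets))


def encode_patterns(
    matrix: OccupancyMatrix,
    condition_order: tuple[str, ...] = config.CONDITION_ORDER,
) -> pd.Series:
    """Per-peak pattern codes: 'O' for open, 'C' for closed, one
    character per condition in the given order."""
    missing = set(condition_order) - set(matrix.conditions)
    if missing or len(condition_order) != len(matrix.conditions):
        raise ValueError(
            f"condition order must permute {matrix.conditions}, got {condition_order}"
        )
    cols = [matrix.states[c].map({True: "O", False: "C"}) for c in condition_order]
    codes = cols[0].str.cat(cols[1:]) if len(cols) > 1 else cols[0]
    codes.name = "pattern"
    return codes


def pattern_counts(codes: pd.Series) -> pd.Series:
    """Counts per pattern code; sums to the number of reference peaks."""
    return codes.value_counts().sort_index()


def query_transition(
    matrix: OccupancyMatrix,
    require: dict[str, str],
    fraction_open_in: str | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Reference peaks matching a state predicate, with an optional
    conditional fraction.

    ``require`` maps condition name to 'O' or 'C' (e.g.
    ``{"FL": "C", "TR": "O"}`` selects peaks that open specifically in
    TR).  If ``fraction_open_in`` names a condition, the fraction of the
    selected peaks open in that condition is also returned (None, with a
    warning, when the selection is empty).
    """
    unknown = set(require) - set(matrix.conditions)
    if unknown:
        raise ValueError(f"unknown conditions {sorted(unknown)}")
    sel = pd.Series(True, index=matrix.states.index)
    for cond, state in require.items():
        if state not in ("O", "C"):
            raise ValueError(f"state must be 'O' or 'C', got {state!r}")
        sel &= matrix.states[cond] == (state == "O")
    subset = matrix.reference[sel.to_numpy()]
    frac = None
    if fraction_open_in is not None:
        if fraction_open_in not in matrix.conditions:
            raise ValueError(f"unknown condition {fraction_open_in!r}")
        if len(subset) == 0:
            warnings.warn("empty base set; conditional fraction undefined")
        else:
            frac = float(matrix.states.loc[sel, fraction_open_in].mean())
    return subset, frac


def sample_peaks(
    matrix: OccupancyMatrix,
    n: int = config.ALLUVIAL_SAMPLE,
    seed: int | None = None,
    condition_order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Uniform sample of reference peaks, exported long-format for
    alluvial plotting (peak_id, condition, state)."""
    total = len(matrix.reference)
    if n > total:
        warnings.warn(f"requested {n} of {total} peaks; using all")
        n = total
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    order = condition_order or matrix.conditions
    rows = []
    for i in idx:
        for cond in order:
            rows.append({
                "peak_id": int(i), "condition": cond,
                "state": "open" if matrix.states.iloc[i][cond] else "closed",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BED I/O (3+ column, tab-separated; extra columns preserved)
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    _as_frame(df[_BED_COLUMNS])  # validates
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
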