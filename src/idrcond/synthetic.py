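"""Synthetic inputs with the statistical structure the pipeline assumes.

Each generator emits both the artifact (sequence, image, trace table,
cell table, peak files) and its ground truth, so every downstream stage
can be validated by round-trip: on noiseless settings the consuming
analysis recovers the programmed quantity exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import config
from .imaging import FrapTraces, FretRois, NucleusImage

__all__ = [
    "SequenceSpec",
    "ImageSpec",
    "TraceSpec",
    "PopulationSpec",
    "PeakSetSpec",
    "generate_sequence",
    "generate_image",
    "generate_traces",
    "generate_population",
    "generate_peak_sets",
]


# ---------------------------------------------------------------------------
# Sequences: charge-block architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceSpec:
    """Blockwise random protein sequence.

    ``block_layout`` is an ordered list of (label, length, weights) where
    weights is a mapping of amino acid -> probability; each block's
    weights must be nonnegative and sum to 1.  Emulates a basic
    condensation-prone platform followed by an acidic charge block.
    """

    block_layout: tuple[tuple[str, int, Mapping[str, float]], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_layout:
            raise ValueError("block layout is empty")
        for label, length, weights in self.block_layout:
            if length <= 0:
                raise ValueError(f"block {label!r}: zero-length block")
            bad = set(weights) - config.AA_SET
            if bad:
                raise ValueError(f"block {label!r}: unknown residues {sorted(bad)}")
            w = np.array([weights.get(a, 0.0) for a in config.AMINO_ACIDS])
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError(
                    f"block {label!r}: weights must be nonnegative and sum to 1"
                )

    @property
    def length(self) -> int:
        return sum(length for _, length, _ in self.block_layout)


def generate_sequence(spec: SequenceSpec) -> tuple[str, pd.DataFrame]:
    """Draw the sequence and return it with a per-block annotation table
    (label, start, end, net charge sign of the block)."""
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(config.AMINO_ACIDS))
    parts: list[str] = []
    rows = []
    pos = 0
    for label, length, weights in spec.block_layout:
        w = np.array([weights.get(a, 0.0) for a in config.AMINO_ACIDS])
        w = w / w.sum()
        block = "".join(rng.choice(aas, size=length, p=w))
        net = sum(block.count(a) for a in "KR") - sum(block.count(a) for a in "DE")
        rows.append({
            "label": label, "start": pos, "end": pos + length,
            "net_charge_sign": int(np.sign(net)),
        })
        parts.append(block)
        pos += length
    return "".join(parts), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Images: Gaussian puncta over a noisy nuclear background
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Nuclear image with Gaussian puncta.

    ``puncta`` is a list of ((row, col), sigma_px, amplitude).  The
    nucleus mask is a centered disk of ``nucleus_radius`` pixels; all
    punctum centers must fall inside it.
    """

    shape: tuple[int, int] = (128, 128)
    nucleus_radius: float = 50.0
    background_level: float = 20.0
    puncta: tuple[tuple[tuple[float, float], float, float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be >= 0")
        cy, cx = (self.shape[0] - 1) / 2, (self.shape[1] - 1) / 2
        for (r, c), sigma, amp in self.puncta:
            if amp < 0:
                raise ValueError("punctum amplitude must be >= 0")
            if sigma <= 0:
                raise ValueError("punctum sigma must be > 0")
            if (r - cy) ** 2 + (c - cx) ** 2 > self.nucleus_radius ** 2:
                raise ValueError(f"punctum at ({r}, {c}) lies outside the nucleus")


def separated_centers(
    rng: np.random.Generator,
    n: int,
    min_dist: float,
    center: tuple[float, float] = (63.5, 63.5),
    spread: float = 25.0,
    max_tries: int = 10_000,
) -> list[tuple[float, float]]:
    """Punctum centers with pairwise distance >= ``min_dist``, drawn
    uniformly from a square around the nucleus center.  Keeping puncta
    apart keeps their Gaussian profiles from summing, which would push
    pixels out of a fixed segmentation intensity window."""
    out: list[tuple[float, float]] = []
    for _ in range(max_tries):
        if len(out) == n:
            return out
        cand = tuple(center[i] + rng.uniform(-spread, spread) for i in range(2))
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_dist ** 2
               for p in out):
            out.append(cand)
    raise RuntimeError("could not place separated punctum centers")


def generate_image(spec: ImageSpec) -> tuple[NucleusImage, np.ndarray]:
    """Render the image and return it with the ground-truth foci mask
    (pixels within 2 sigma of any punctum center)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.nucleus_radius ** 2
    img = np.zeros((h, w), dtype=float)
    img[mask] = spec.background_level
    truth = np.zeros((h, w), dtype=bool)
    for (r, c), sigma, amp in spec.puncta:
        d2 = (yy - r) ** 2 + (xx - c) ** 2
        img += amp * np.exp(-d2 / (2.0 * sigma ** 2))
        truth |= d2 <= (2.0 * sigma) ** 2
    if spec.noise_sd > 0:
        img[mask] += rng.normal(0.0, spec.noise_sd, size=int(mask.sum()))
    np.clip(img, 0.0, None, out=img)
    img[~mask] = 0.0
    return NucleusImage(img, mask), truth


# ---------------------------------------------------------------------------
# FRAP / pbFRET traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Programmed FRAP or pbFRET ROI intensities.

    For ``kind="pbfret"`` the forward model is the exact inverse of the
    drift-corrected efficiency: D_post = D_pre * b / (1 - E) with
    DN_post = DN_pre * b, all plus ``background_level`` (and noise).
    For ``kind="frap"`` the bleach-ROI trace recovers as
    I(t) = I_bleach + M * (I_pre - I_bleach) * (1 - exp(-t / tau)).
    """

    kind: str
    efficiency: float = 0.0        # pbfret: programmed E (< 1)
    mobile_fraction: float = 0.8   # frap: programmed M in [0, 1]
    tau: float = 10.0              # frap: recovery time constant, frames
    drift_factor: float = 1.0      # pbfret: b = DN_post / DN_pre
    background_level: float = 0.0
    n_timepoints: int = 85
    bleach_index: int = 5
    bleach_depth: float = 0.2      # frap: fraction of signal left at bleach
    base_intensity: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("frap", "pbfret"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.kind == "pbfret" and self.efficiency >= 1.0:
            raise ValueError("FRET efficiency must be < 1")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile fraction must be in [0, 1]")
        if self.drift_factor <= 0:
            raise ValueError("drift factor must be > 0")
        if self.tau <= 0 or self.noise_sd < 0:
            raise ValueError("tau must be > 0 and noise_sd >= 0")


def generate_traces(spec: TraceSpec) -> pd.DataFrame:
    """ROI intensity table for one cell.

    pbFRET: one row with columns d_pre, d_post, dn_pre, dn_post, bg_pre,
    bg_post.  FRAP: one row per timepoint with columns time, bleach,
    background, total and a ``bleach_index`` entry in ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_level
    if spec.kind == "pbfret":
        d_pre = spec.base_intensity
        dn_pre = spec.base_intensity
        d_post = d_pre * spec.drift_factor / (1.0 - spec.efficiency)
        dn_post = dn_pre * spec.drift_factor
        raw = np.array([d_pre, d_post, dn_pre, dn_post]) + bg
        if spec.noise_sd > 0:
            raw += rng.normal(0.0, spec.noise_sd, size=4)
        df = pd.DataFrame([{
            "d_pre": raw[0], "d_post": raw[1],
            "dn_pre": raw[2], "dn_post": raw[3],
            "bg_pre": bg, "bg_post": bg,
        }])
        return df

    n, k = spec.n_timepoints, spec.bleach_index
    if k < 5 or k >= n:
        raise ValueError("bleach index must be >= 5 and inside the trace")
    t = np.arange(n, dtype=float)
    i_pre = spec.base_intensity
    i_bleach = spec.bleach_depth * i_pre
    trace = np.full(n, i_pre)
    rec = t[k:] - t[k]
    trace[k:] = i_bleach + spec.mobile_fraction * (i_pre - i_bleach) * (
        1.0 - np.exp(-rec / spec.tau)
    )
    total = np.full(n, 10.0 * i_pre)
    background = np.full(n, bg)
    if spec.noise_sd > 0:
        trace = trace + rng.normal(0.0, spec.noise_sd, size=n)
        total = total + rng.normal(0.0, spec.noise_sd, size=n)
    df = pd.DataFrame({
        "time": t,
        "bleach": trace + bg,
        "background": background,
        "total": total + bg,
    })
    df.attrs["bleach_index"] = k
    return df


def traces_to_frap(df: pd.DataFrame, bleach_index: int | None = None) -> FrapTraces:
    """Adapter from a generated/loaded FRAP table to :class:`FrapTraces`."""
    k = bleach_index if bleach_index is not None else df.attrs.get("bleach_index")
    if k is None:
        raise ValueError("bleach index not provided")
    return FrapTraces(
        df["bleach"].to_numpy(), df["background"].to_numpy(),
        df["total"].to_numpy(), int(k), times=df["time"].to_numpy(),
    )


def traces_to_fret(df: pd.DataFrame) -> FretRois:
    """Adapter from a generated/loaded pbFRET table to :class:`FretRois`."""
    row = df.iloc[0]
    return FretRois(
        d_pre=row["d_pre"], d_post=row["d_post"],
        dn_pre=row["dn_pre"], dn_post=row["dn_post"],
        bg_pre=row.get("bg_pre", 0.0), bg_post=row.get("bg_post", 0.0),
    )


# ---------------------------------------------------------------------------
# Cell populations for expression-matched testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Two-group (or more) cell population with programmed condensation.

    ``model`` maps (group, intensity) to a condensation probability;
    either a callable or one of the built-in forms:

    - ``{"type": "constant", "p": x}``
    - ``{"type": "logistic", "intercept": a, "slope": b,
       "group_effects": {group: delta}}`` giving
      p = sigmoid(a + b * intensity + delta_group)
    """

    n_cells: Mapping[str, int]
    intensity: Mapping[str, tuple[float, float]]
    model: Mapping | Callable[[str, float], float] = field(
        default_factory=lambda: {"type": "constant", "p": 0.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_cells:
            raise ValueError("no groups specified")
        for g, n in self.n_cells.items():
            if n <= 0:
                raise ValueError(f"group {g!r} is empty")
            if g not in self.intensity:
                raise ValueError(f"group {g!r} has no intensity distribution")


def _condensation_prob(model, group: str, intensity: float) -> float:
    if callable(model):
        p = model(group, intensity)
    elif model["type"] == "constant":
        p = model["p"]
    elif model["type"] == "logistic":
        eta = (model.get("intercept", 0.0)
               + model.get("slope", 0.0) * intensity
               + model.get("group_effects", {}).get(group, 0.0))
        p = 1.0 / (1.0 + np.exp(-eta))
    else:
        raise ValueError(f"unknown condensation model {model!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("condensation probability outside [0, 1]")
    return p


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Cell table with columns cell_id, group, intensity, condensate."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    i = 0
    for group, n in spec.n_cells.items():
        mu, sd = spec.intensity[group]
        intensities = np.clip(rng.normal(mu, sd, size=n), 0.0, None)
        for x in intensities:
            p = _condensation_prob(spec.model, group, float(x))
            rows.append({
                "cell_id": f"cell{i:05d}", "group": group,
                "intensity": float(x),
                "condensate": bool(rng.random() < p),
            })
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Four-condition peak sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSetSpec:
    """Peak loci with programmed open/closed patterns across conditions.

    Loci are placed left to right with inter-locus gaps strictly greater
    than the merge gap (100 bp), so condition-level merging never fuses
    distinct ground-truth loci and the transition analysis recovers the
    programmed pattern counts exactly.
    """

    n_peaks: int = 200
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    pattern_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"OOOO": 1.0}
    )
    width_range: tuple[int, int] = (150, 400)
    conditions: tuple[str, ...] = config.CONDITION_ORDER
    min_gap: int = config.MERGE_MAX_GAP + 1
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = dict(self.pattern_freqs)
        if not np.isclose(sum(freqs.values()), 1.0):
            raise ValueError("pattern frequencies must sum to 1")
        k = len(self.conditions)
        for code, f in freqs.items():
            if len(code) != k or set(code) - {"C", "O"}:
                raise ValueError(f"invalid pattern code {code!r}")
            if f < 0:
                raise ValueError("pattern frequencies must be >= 0")
        lo, hi = self.width_range
        if not 0 < lo <= hi:
            raise ValueError("invalid width range")
        per_chrom = -(-self.n_peaks // self.n_chromosomes)
        budget = per_chrom * (hi + self.min_gap + 100)
        if budget > self.chrom_length:
            raise ValueError(
                "peak widths and spacing exceed the chromosome length budget"
            )


def generate_peak_sets(
    spec: PeakSetSpec,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-condition BED-style peak tables plus ground truth.

    Returns (``{condition: DataFrame(chrom, start, end)}``, truth table
    with one row per locus that is open in at least one condition:
    chrom, start, end, pattern).  Loci whose pattern is closed everywhere
    appear in no peak file and therefore in no truth row.
    """
    rng = np.random.default_rng(spec.seed)
    codes = sorted(spec.pattern_freqs)
    probs = np.array([spec.pattern_freqs[c] for c in codes])
    probs = probs / probs.sum()
    lo, hi = spec.width_range
    per_cond: dict[str, list] = {c: [] for c in spec.conditions}
    truth_rows = []
    chrom_of = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    placed = 0
    cursor = {c: 0 for c in chrom_of}
    ci = 0
    while placed < spec.n_peaks:
        chrom = chrom_of[ci % spec.n_chromosomes]
        ci += 1
        width = int(rng.integers(lo, hi + 1))
        gap = int(spec.min_gap + rng.integers(0, 100))
        start = cursor[chrom] + gap
        end = start + width
        if end > spec.chrom_length:
            raise ValueError("ran out of chromosome while placing peaks")
        cursor[chrom] = end
        code = codes[int(rng.choice(len(codes), p=probs))]
        placed += 1
        if "O" not in code:
            continue
        truth_rows.append({"chrom": chrom, "start": start, "end": end,
                           "pattern": code})
        for cond, state in zip(spec.conditions, code):
            if state == "O":
                per_cond[cond].append({"chrom": chrom, "start": start, "end": end})
    peak_sets = {
        c: pd.DataFrame(rows, columns=["chrom", "start", "end"])
        for c, rows in per_cond.items()
    }
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "pattern"])
    return peak_sets, truth
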