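"""IDR sequence grammar: long linker IDR calling, segmentation, the
90-feature vector, per-segment variability, and charge rewiring.

The feature vector combines binary patterning z-scores (blocky vs
well-mixed arrangement of residue-class pairs, measured against a
within-sequence shuffle null), amino-acid composition, charge metrics
(FCR, NCPR, pI), global scales (hydrophobicity, PPII propensity), and
run/patch content per residue type.  Coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config

__all__ = [
    "ProteinRecord",
    "DisorderTrack",
    "IDRRegion",
    "SegmentSet",
    "FeatureVector",
    "VariabilityProfile",
    "FEATURE_NAMES",
    "PATTERNING_PAIRS",
    "call_idrs",
    "select_llidrs",
    "segment_region",
    "composition_features",
    "charge_global_features",
    "block_features",
    "patterning_zscores",
    "feature_vector",
    "feature_variability",
    "rewire_charges",
    "isoelectric_point",
    "zscore_columns",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter amino-acid alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - config.AA_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: unknown residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder scores in [0, 1] for one protein."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("disorder track must be a nonempty 1-D array")
        if np.any(~np.isfinite(scores)) or scores.min() < 0 or scores.max() > 1:
            raise ValueError("disorder scores must be finite and in [0, 1]")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class IDRRegion:
    """A disordered region [start, end) of a protein."""

    protein_id: str
    start: int
    end: int
    is_llidr: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentSet:
    """Ordered half-open segments exactly tiling a parent region."""

    region: IDRRegion
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pos = self.region.start
        for s, e in self.segments:
            if s != pos or e <= s:
                raise ValueError("segments must tile the region in order")
            pos = e
        if pos != self.region.end:
            raise ValueError("segments must tile the region exactly")

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# Feature-name registry (fixed 90-column order)
# ---------------------------------------------------------------------------

_CLASS_NAMES = tuple(config.PATTERNING_CLASSES)
PATTERNING_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(_CLASS_NAMES, 2)
)
assert len(PATTERNING_PAIRS) == 36

BLOCK_RESIDUES = tuple(a for a in config.AMINO_ACIDS if a != "W")

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"z {a}-{b}" for a, b in PATTERNING_PAIRS)
    + tuple(f"Frac {a}" for a in config.AMINO_ACIDS)
    + tuple(config.GROUPED_SETS)
    + ("log10(K/R)", "log10(E/D)")
    + ("FCR", "NCPR", "Hydrophobicity", "Disorder-promoting", "pI",
       "Chain-expanding", "PPII")
    + tuple(f"Block {a}" for a in BLOCK_RESIDUES)
    + ("RG-stretch",)
)
assert len(FEATURE_NAMES) == 90


@dataclass
class FeatureVector:
    """The 90 named grammar features for one sequence.

    ``flagged`` lists patterning pairs with too few class members for a
    meaningful z-score (reported as 0).
    """

    values: pd.Series
    flagged: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if tuple(self.values.index) != FEATURE_NAMES:
            raise ValueError("feature vector must carry the 90 fixed names")


@dataclass
class VariabilityProfile:
    """Per-feature SD across a region's segments.

    ``defined`` is False when the region has fewer than two segments.
    ``excluded`` lists features flagged in every segment (SD set to NaN).
    """

    sd: pd.Series
    defined: bool
    excluded: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# IDR calling and segmentation
# ---------------------------------------------------------------------------

def call_idrs(
    track: DisorderTrack,
    threshold: float = config.DISORDER_THRESHOLD,
    min_len: int = config.IDR_MIN_LEN,
) -> list[IDRRegion]:
    """Maximal runs of scores >= ``threshold`` longer than ``min_len``.

    The length rule is strict: a run of exactly ``min_len`` residues is
    not reported.
    """
    above = track.scores >= threshold
    regions: list[IDRRegion] = []
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s > min_len:
            regions.append(IDRRegion(track.protein_id, int(s), int(e)))
    return regions


def select_llidrs(
    regions: list[IDRRegion],
    protein_length: int,
    min_len: int = config.LLIDR_MIN_LEN,
) -> list[IDRRegion]:
    """Flag long linker IDRs: internal regions longer than ``min_len``.

    A region qualifies iff it excludes the first residue (start > 0),
    excludes the last residue (end < protein length), and its length is
    strictly greater than ``min_len``.
    """
    out = []
    for r in regions:
        if r.end > protein_length:
            raise ValueError(
                f"region [{r.start}, {r.end}) exceeds protein length {protein_length}"
            )
        flag = r.start > 0 and r.end < protein_length and r.length > min_len
        out.append(IDRRegion(r.protein_id, r.start, r.end, is_llidr=flag))
    return out


def segment_region(
    region: IDRRegion,
    block: int = config.SEGMENT_BLOCK,
    min_tail: int = config.SEGMENT_MIN_TAIL,
) -> SegmentSet:
    """Split a region into consecutive ``block``-residue segments.

    A final remainder shorter than ``min_tail`` is merged into the
    preceding block, so every segment has at least ``min_tail`` residues.
    """
    n = region.length
    if n < min_tail:
        raise ValueError(f"region of {n} residues is shorter than {min_tail}")
    bounds = list(range(region.start, region.end, block))
    bounds.append(region.end)
    if len(bounds) > 2 and bounds[-1] - bounds[-2] < min_tail:
        del bounds[-2]  # merge the short tail into the preceding block
    segments = tuple(zip(bounds[:-1], bounds[1:]))
    return SegmentSet(region, segments)


# ---------------------------------------------------------------------------
# Composition and charge features
# ---------------------------------------------------------------------------

def _counts(seq: str) -> dict[str, int]:
    return {a: seq.count(a) for a in config.AMINO_ACIDS}


def composition_features(seq: str) -> pd.Series:
    """20 amino-acid fractions, 5 grouped fractions, and the two
    pseudocounted log-ratios log10((K+1)/(R+1)) and log10((E+1)/(D+1))."""
    _validate_seq(seq)
    n = len(seq)
    c = _counts(seq)
    vals: dict[str, float] = {f"Frac {a}": c[a] / n for a in config.AMINO_ACIDS}
    for name, members in config.GROUPED_SETS.items():
        vals[name] = sum(c[a] for a in members) / n
    vals["log10(K/R)"] = math.log10((c["K"] + 1) / (c["R"] + 1))
    vals["log10(E/D)"] = math.log10((c["E"] + 1) / (c["D"] + 1))
    return pd.Series(vals)


def isoelectric_point(
    seq: str,
    pka: dict[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge of the sequence (with free termini)
    vanishes, solved by bisection on [0, 14] to |net charge| < ``tol``."""
    pka = pka or config.PKA_EMBOSS
    c = _counts(seq)
    basic = [("Nterm", 1), ("K", c["K"]), ("R", c["R"]), ("H", c["H"])]
    acidic = [("Cterm", 1), ("D", c["D"]), ("E", c["E"]),
              ("C", c["C"]), ("Y", c["Y"])]

    def net(ph: float) -> float:
        pos = sum(n / (1.0 + 10.0 ** (ph - pka[g])) for g, n in basic if n)
        neg = sum(n / (1.0 + 10.0 ** (pka[g] - ph)) for g, n in acidic if n)
        return pos - neg

    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net(mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def charge_global_features(seq: str) -> pd.Series:
    """FCR, NCPR, mean rescaled hydrophobicity, disorder-promoting
    fraction, pI, chain-expanding fraction, and mean PPII propensity.

    FCR = (nK+nR+nD+nE)/L and NCPR = (nK+nR-nD-nE)/L by definition, so
    the identities FCR = frac(K+R)+frac(D+E) and
    NCPR = frac(K+R)-frac(D+E) hold exactly.
    """
    _validate_seq(seq)
    n = len(seq)
    c = _counts(seq)
    fpos = (c["K"] + c["R"]) / n
    fneg = (c["D"] + c["E"]) / n
    kd = config.KYTE_DOOLITTLE
    # rescale Kyte-Doolittle from [-4.5, 4.5] to [0, 1]
    hydro = sum((kd[a] + 4.5) / 9.0 for a in seq) / n
    return pd.Series({
        # computed from the class fractions so the identities with the
        # composition features hold bit-exactly
        "FCR": fpos + fneg,
        "NCPR": fpos - fneg,
        "Hydrophobicity": hydro,
        "Disorder-promoting": sum(c[a] for a in config.DISORDER_PROMOTING) / n,
        "pI": isoelectric_point(seq),
        "Chain-expanding": sum(c[a] for a in config.CHAIN_EXPANDING) / n,
        "PPII": sum(config.PPII_PROPENSITY[a] for a in seq) / n,
    })


# ---------------------------------------------------------------------------
# Run/patch ("block") features
# ---------------------------------------------------------------------------

def _patch_fraction(positions: list[int], length: int, min_occ: int,
                    max_gap: int, unit: int = 1) -> float:
    """Fraction of the sequence inside qualifying patches.

    ``positions`` are start indices of occurrences of a unit of size
    ``unit`` (1 for single residues, 2 for RG dimers).  Occurrences chain
    when separated by <= ``max_gap`` intervening residues; a chain
    qualifies with >= ``min_occ`` occurrences and contributes the span
    from its first occurrence to the end of its last.
    """
    if not positions:
        return 0.0
    covered = 0
    chain_start = positions[0]
    chain_len = 1
    prev = positions[0]
    for p in positions[1:] + [None]:  # sentinel flushes the last chain
        if p is not None and p - (prev + unit) <= max_gap:
            chain_len += 1
            prev = p
            continue
        if chain_len >= min_occ:
            covered += prev + unit - chain_start
        if p is not None:
            chain_start = p
            chain_len = 1
            prev = p
    return covered / length


def block_features(seq: str) -> pd.Series:
    """Per-residue patch fractions (A..Y excluding W) plus the RG-stretch
    fraction.

    A residue patch is a maximal chain of occurrences of one residue type
    separated by at most 2 other residues, qualifying at >= 4 occurrences;
    the feature is the fraction of sequence length covered by qualifying
    patch spans.  The RG analogue chains non-overlapping "RG" dimers
    (scanned left to right) separated by at most 2 residues, qualifying
    at >= 2 dimers.
    """
    _validate_seq(seq)
    n = len(seq)
    vals: dict[str, float] = {}
    for a in BLOCK_RESIDUES:
        pos = [i for i, ch in enumerate(seq) if ch == a]
        vals[f"Block {a}"] = _patch_fraction(
            pos, n, config.BLOCK_MIN_OCC, config.BLOCK_MAX_GAP, unit=1
        )
    rg = []
    i = 0
    while i < n - 1:
        if seq[i] == "R" and seq[i + 1] == "G":
            rg.append(i)
            i += 2
        else:
            i += 1
    vals["RG-stretch"] = _patch_fraction(
        rg, n, config.RG_MIN_OCC, config.RG_MAX_GAP, unit=2
    )
    return pd.Series(vals)


# ---------------------------------------------------------------------------
# Patterning z-scores
# ---------------------------------------------------------------------------

def _ternary_labels(seq: str, cx: frozenset[str], cy: frozenset[str]) -> np.ndarray:
    """1 for class X, 2 for class Y, 0 otherwise.  Where classes overlap
    (e.g. alanine in both hyd and ala) the first class takes precedence."""
    lab = np.zeros(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        if ch in cx:
            lab[i] = 1
        elif ch in cy:
            lab[i] = 2
    return lab


def _blockiness(lab2d: np.ndarray, windows=config.PATTERNING_WINDOWS) -> np.ndarray:
    """Mean over window sizes of the variance of windowed class asymmetry
    (n_X - n_Y)/g across all sliding windows.  ``lab2d`` is (m, L)."""
    m, L = lab2d.shape
    sgn = np.where(lab2d == 1, 1.0, np.where(lab2d == 2, -1.0, 0.0))
    out = np.zeros(m)
    nw = 0
    for g in windows:
        if L < g:
            continue
        cs = np.cumsum(sgn, axis=1)
        win = (cs[:, g - 1:] - np.concatenate(
            [np.zeros((m, 1)), cs[:, :-g]], axis=1)) / g
        out += win.var(axis=1)
        nw += 1
    if nw == 0:
        raise ValueError("sequence shorter than every window size")
    return out / nw


def patterning_zscores(
    seq: str,
    n_shuffles: int = config.PATTERNING_SHUFFLES,
    seed: int | None = None,
    pairs: tuple[tuple[str, str], ...] = PATTERNING_PAIRS,
) -> tuple[pd.Series, frozenset[str]]:
    """Blockiness z-scores for residue-class pairs against the
    within-sequence shuffle null.

    Positive z means the two classes segregate into blocks more than
    random shufflings of the same composition; negative means they are
    better mixed.  Pairs where either class has fewer than two mapped
    residues are reported as 0 and flagged.  Deterministic per seed.

    Returns (series indexed by ``"z X-Y"``, flagged feature names).
    """
    _validate_seq(seq)
    if len(seq) < 10:
        raise ValueError("patterning requires sequences of >= 10 residues")
    if n_shuffles < 50:
        raise ValueError("n_shuffles must be >= 50")
    rng = np.random.default_rng(seed)
    vals: dict[str, float] = {}
    flagged: set[str] = set()
    for cx_name, cy_name in pairs:
        name = f"z {cx_name}-{cy_name}"
        cx = config.PATTERNING_CLASSES[cx_name]
        cy = config.PATTERNING_CLASSES[cy_name]
        lab = _ternary_labels(seq, cx, cy if cy_name != cx_name else frozenset())
        n_x = int(np.sum(lab == 1))
        n_y = int(np.sum(lab == 2)) if cy_name != cx_name else n_x
        if n_x < 2 or n_y < 2:
            vals[name] = 0.0
            flagged.add(name)
            continue
        obs = _blockiness(lab[None, :])[0]
        perms = rng.permuted(
            np.broadcast_to(lab, (n_shuffles, lab.size)).copy(), axis=1
        )
        null = _blockiness(perms)
        sd = null.std()
        if sd == 0.0:
            vals[name] = 0.0
            flagged.add(name)
        else:
            vals[name] = float((obs - null.mean()) / sd)
    return pd.Series(vals), frozenset(flagged)


# ---------------------------------------------------------------------------
# Assembly, variability, rewiring
# ---------------------------------------------------------------------------

def feature_vector(
    seq: str,
    n_shuffles: int = config.PATTERNING_SHUFFLES,
    seed: int | None = None,
) -> FeatureVector:
    """The full 90-feature grammar vector, in the fixed column order."""
    z, flagged = patterning_zscores(seq, n_shuffles=n_shuffles, seed=seed)
    parts = pd.concat([
        z,
        composition_features(seq),
        charge_global_features(seq),
        block_features(seq),
    ])
    return FeatureVector(parts.reindex(list(FEATURE_NAMES)), flagged)


def feature_variability(vectors: list[FeatureVector]) -> VariabilityProfile:
    """Population SD of each feature across a region's segments.

    With fewer than two segments the profile is flagged undefined.
    Features flagged in every segment carry no signal and are excluded
    (SD reported as NaN).
    """
    if len(vectors) < 2:
        sd = pd.Series(np.nan, index=list(FEATURE_NAMES))
        return VariabilityProfile(sd, defined=False,
                                  excluded=frozenset(FEATURE_NAMES))
    mat = pd.DataFrame([v.values for v in vectors])
    sd = mat.std(axis=0, ddof=0)
    excluded = frozenset.intersection(*[v.flagged for v in vectors])
    sd[list(excluded)] = np.nan
    return VariabilityProfile(sd, defined=True, excluded=excluded)


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scoring of a segments x features matrix, for heatmap
    export.  Constant columns map to 0."""
    sd = matrix.std(axis=0, ddof=0).replace(0.0, np.nan)
    out = (matrix - matrix.mean(axis=0)) / sd
    return out.fillna(0.0)


_REWIRE_MAPS = {
    "AtoB": {"D": "R", "E": "K"},
    "AtoNon": {"D": config.NEUTRAL_SUBSTITUTE, "E": config.NEUTRAL_SUBSTITUTE},
    "BtoA": {"K": "E", "R": "D"},
    "BtoNon": {"K": config.NEUTRAL_SUBSTITUTE, "R": config.NEUTRAL_SUBSTITUTE},
}


def rewire_charges(seq: str, mode: str) -> str:
    """Charge-rewired sequence variants.

    ``AtoB``/``AtoNon`` replace acidic residues (D->R, E->K, or both to
    the neutral substitute); ``BtoA``/``BtoNon`` do the reverse for basic
    residues.  ``BS`` (balanced substitution) converts the minimal number
    of acidic residues, left to right, to basic ones (D->R, E->K) so that
    |NCPR| of the result is minimized.  Length is always preserved.
    """
    _validate_seq(seq)
    if mode in _REWIRE_MAPS:
        table = _REWIRE_MAPS[mode]
        return "".join(table.get(a, a) for a in seq)
    if mode == "BS":
        n_basic = sum(seq.count(a) for a in "KR")
        acidic_pos = [i for i, a in enumerate(seq) if a in "DE"]
        net = n_basic - len(acidic_pos)
        # each acidic->basic substitution raises the net charge by 2
        best_s = min(range(len(acidic_pos) + 1),
                     key=lambda s: (abs(net + 2 * s), s))
        out = list(seq)
        for i in acidic_pos[:best_s]:
            out[i] = "R" if out[i] == "D" else "K"
        return "".join(out)
    raise ValueError(f"unknown rewiring mode {mode!r}")


def _validate_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - config.AA_SET
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)}")
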