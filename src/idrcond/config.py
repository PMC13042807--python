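"""Fixed scales, residue class sets, and defaults used across the package.

Every constant that the analysis depends on but that is not derivable from
the data lives here, so that a run's assumptions are auditable and
overridable in one place.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

# ---------------------------------------------------------------------------
# Residue class sets
# ---------------------------------------------------------------------------

#: Classes used for binary patterning z-scores, in fixed order.  Overlaps
#: (A appears in both ``hyd`` and ``ala``) are intentional: class pairs are
#: evaluated independently.
PATTERNING_CLASSES: dict[str, frozenset[str]] = {
    "pol": frozenset("STNQCH"),
    "hyd": frozenset("AILMV"),
    "pos": frozenset("RK"),
    "neg": frozenset("DE"),
    "aro": frozenset("FWY"),
    "ala": frozenset("A"),
    "pro": frozenset("P"),
    "gly": frozenset("G"),
}

#: Grouped-composition sets (five features).
GROUPED_SETS: dict[str, frozenset[str]] = {
    "Frac K+R": frozenset("KR"),
    "Frac D+E": frozenset("DE"),
    "Frac Polar": frozenset("STNQCHY"),
    "Frac Aliphatic": frozenset("AILMV"),
    "Frac Aromatic": frozenset("FWY"),
}

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

#: Residues whose over-representation is characteristic of disordered
#: sequence (used for the disorder-promoting fraction).
DISORDER_PROMOTING = frozenset("ARGQSPEK")

#: Residues that expand the chain dimensions of a disordered sequence
#: (charged residues plus proline).
CHAIN_EXPANDING = frozenset("EDRKP")

# ---------------------------------------------------------------------------
# Per-residue scales
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy, raw scale (rescaled to [0, 1] when used).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Experimental polyproline-II helix propensities (host-guest ladder,
#: proline highest, glycine and aromatics low).
PPII_PROPENSITY: dict[str, float] = {
    "P": 0.74, "Q": 0.66, "A": 0.61, "L": 0.58, "M": 0.58,
    "K": 0.56, "S": 0.55, "I": 0.52, "E": 0.52, "R": 0.51,
    "T": 0.50, "N": 0.49, "C": 0.48, "D": 0.48, "V": 0.48,
    "F": 0.46, "H": 0.45, "Y": 0.45, "G": 0.40, "W": 0.40,
}

#: EMBOSS pKa table for isoelectric-point calculation.
PKA_EMBOSS: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

# ---------------------------------------------------------------------------
# Defaults for the analysis stages
# ---------------------------------------------------------------------------

DISORDER_THRESHOLD = 0.5       # per-residue disorder score cutoff
IDR_MIN_LEN = 30               # IDRs must exceed this many residues (strict >)
LLIDR_MIN_LEN = 1000           # long linker IDRs must exceed this (strict >)
SEGMENT_BLOCK = 200            # llIDR segmentation block size, residues
SEGMENT_MIN_TAIL = 30          # tails shorter than this merge backwards

PATTERNING_WINDOWS = (5, 6)    # window sizes for the blockiness statistic
PATTERNING_SHUFFLES = 1000     # default shuffle count for z-scores

BLOCK_MIN_OCC = 4              # residue patch rule: >= 4 occurrences
BLOCK_MAX_GAP = 2              # residue patch rule: <= 2 interruptions
RG_MIN_OCC = 2                 # RG-stretch rule: >= 2 dimers
RG_MAX_GAP = 2                 # RG-stretch rule: <= 2 residues between dimers

#: Neutral substitute used by charge rewiring (acidic/basic -> neutral).
NEUTRAL_SUBSTITUTE = "S"

SMOOTH_WINDOW = 5              # line-scan running-average window
CI_BASELINE_PERCENTILE = 20.0  # baseline percentile for the condensation index
MAD_CONSISTENCY = 1.4826       # normal-consistency factor applied once in CI

FOCI_WINDOW = (10.0, 50.0)     # intensity window for focus segmentation
FOCI_MIN_AREA = 4              # minimum focus area, pixels
FOCI_CONNECTIVITY = 2          # skimage connectivity (2 = 8-connected)

PSM_CALIPER = 0.2              # caliper, in SDs of the logit propensity
CLASSIFY_C_MIN = 0.8           # circularity threshold for LLPS vs aggregate
CLASSIFY_M_MIN = 0.5           # mobile-fraction threshold for LLPS

MERGE_MAX_GAP = 100            # bp; peaks with gap <= this are fused
MIN_OVERLAP = 1                # bp; reference peak counts as open at >= this
CONDITION_ORDER = ("EV", "FL", "TR", "LTR")
ALLUVIAL_SAMPLE = 5000         # peaks sampled for the alluvial export
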