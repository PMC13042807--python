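# idrcond

Quantitative tools for studying **charge-block autoregulation in long
disordered protein regions** and its consequences for nuclear
condensation and chromatin accessibility.

Some chromatin regulators carry intrinsically disordered regions (IDRs)
longer than 1000 residues sandwiched between folded domains ("long
linker IDRs", llIDRs). Within such a region, a basic, condensation-prone
segment can be silenced in *cis* by a downstream acidic "charge block";
disease-associated truncations that remove the acidic block unleash
liquid–liquid phase separation (LLPS), with downstream effects on
chromatin state. Testing this model requires a chain of bespoke
measurements, which this package implements as one tested pipeline:

- **Sequence grammar** (`idrcond.grammar`) — call IDRs from per-residue
  disorder scores (threshold 0.5, length strictly > 30), flag internal
  regions longer than 1000 residues as llIDRs, split them into
  200-residue segments (tails < 30 merged backwards), and compute a
  90-feature vector per segment: 36 NARDINI-style binary patterning
  z-scores over residue-class pairs (pol, hyd, pos, neg, aro, ala, pro,
  gly; positive z = blocky, negative = well-mixed, measured against the
  sequence's own compositional shuffle null), 20 amino-acid fractions,
  5 grouped fractions, log₁₀(K/R) and log₁₀(E/D) with +1 pseudocounts,
  FCR, NCPR, mean hydrophobicity, disorder-promoting fraction, pI,
  chain-expanding fraction, PPII propensity, 19 residue run/patch
  fractions (≥ 4 occurrences, ≤ 2 interruptions), and the RG-stretch
  fraction. Charge-rewired variants (acidic→basic, acidic→neutral,
  basic→acidic, basic→neutral, balanced substitution) implement the
  electrostatic-switch perturbations.
- **Imaging metrics** (`idrcond.imaging`) — line-scan condensation index
  CI = (I_peak − I_baseline)/(1.4826·MAD) with the 20th-percentile
  baseline, peak-to-valley ratio PVR = (I_peak − I_valley)/(I_peak +
  I_valley), intensity-window focus segmentation with condensed
  area/intensity fractions and puncta counts, Pearson colocalization,
  FRAP double normalization with a single-exponential recovery fit
  (mobile fraction, half-time), and drift-corrected acceptor-photobleach
  FRET efficiency E = 1 − D_pre·b/D_post with b = DN_post/DN_pre.
- **Expression-matched statistics** (`idrcond.matching`) — condensation
  probability rises with expression, so construct comparisons are
  confounded by expression level. Cells are propensity-score matched on
  fluorescence intensity (logit-scale caliper 0.2 SD, greedy 1:1) and
  compared with Fisher's exact test.
- **Accessibility transitions** (`idrcond.transitions`) — ATAC peak
  files per condition are merged (gap ≤ 100 bp), unified into a
  reference peak set, scored open/closed per condition by ≥ 1 bp
  overlap, and encoded as four-letter patterns ("CCOC" = closed,
  closed, open, closed) with pattern counts and conditional transition
  queries (e.g. what fraction of peaks opened in one condition stays
  open in another).
- **Synthetic data** (`idrcond.synthetic`) — seeded generators for every
  input (charge-block sequences, Gaussian-punctum nuclear images,
  FRAP/pbFRET traces with programmed parameters, confounded cell
  populations, four-condition peak sets with programmed patterns), each
  paired with its ground truth so every stage is validated by
  round-trip.

## Worked example

```python
import idrcond as ic

# a basic platform (100 aa) followed by an acidic charge block (100 aa)
spec = ic.SequenceSpec(
    block_layout=(
        ("basic", 100, {"K": 0.25, "R": 0.15, "G": 0.2, "S": 0.2, "A": 0.2}),
        ("acidic", 100, {"E": 0.25, "D": 0.15, "G": 0.2, "S": 0.2, "A": 0.2}),
    ),
    seed=1,
)
seq, blocks = ic.generate_sequence(spec)
fv = ic.feature_vector(seq, n_shuffles=1000, seed=1)
print(fv.values["NCPR"], fv.values["FCR"], fv.values["z pos-neg"])
# -0.045  0.445  10.712
```

The whole 200-residue construct is nearly charge-neutral (NCPR −0.045)
despite being 44.5% charged (FCR 0.445), and the patterning z-score for
the (pos, neg) class pair is strongly positive (z ≈ 10.7): opposite
charges are segregated into blocks, not mixed — the architecture of an
electrostatic switch. Featurizing the two halves separately shows it
directly: NCPR +0.40 for the basic platform, −0.49 for the acidic block.

```python
rois = ic.FretRois(d_pre=90.0, d_post=105.0, dn_pre=80.0, dn_post=76.0)
print(ic.pbfret_efficiency(rois))
# 0.1857...
```

The bleached-ROI donor brightened by 16.7% after acceptor bleaching,
while the unbleached control ROI dimmed by 5% (b = 0.95); correcting
for that acquisition drift gives a FRET efficiency of 18.6%.

```python
pop = ic.PopulationSpec(
    {"TR": 100, "LTR": 100},
    {"TR": (140.0, 20.0), "LTR": (100.0, 20.0)},
    model={"type": "logistic", "intercept": -6.0, "slope": 0.04,
           "group_effects": {"TR": 1.5}},
    seed=1,
)
records = ic.generate_population(pop)
matched = ic.propensity_match(records, seed=1)
result = ic.fisher_condensate_test(matched)
print(matched.n_pairs, result.odds_ratio, result.p_value)
# 22  5.278  0.0452
```

The two constructs differ in expression (means 140 vs 100), so only 22
expression-matched pairs exist; over those pairs condensation is still
enriched in the TR-like group (odds ratio 5.3, Fisher p = 0.045) — a
construct effect beyond expression level.

A command-line interface mirrors the library
(`idrcond --help`; subcommands `simulate`, `idr-scan`, `features`,
`variability`, `rewire`, `linescan`, `fractions`, `frap`, `fret`,
`coloc`, `match-test`, `atac-transitions`), writing CSV/BED/TIFF outputs
plus a JSON manifest with the tool version, resolved parameters and
input checksums.

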