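# Methods

This note records the models, conventions, parameter choices and known
limitations behind each stage of the pipeline. It describes procedures;
every empirical number it mentions is computed by the test suite or by
`scripts/acceptance.py` at run time.

## Coordinates and sequence conventions

All residue and genomic intervals are 0-based half-open. Under this
convention the llIDR "internality" criteria become: start > 0 (the
region excludes the first residue), end < protein length (it excludes
the last), and end − start > 1000. Protein sequences are restricted to
the 20 canonical amino acids; unknown letters are rejected at parse
time rather than silently skipped, because every downstream feature is
a function of exact counts.

## IDR calling

Disorder tracks are *inputs*: per-residue scores in [0, 1] produced by
whatever predictor the user trusts. IDRs are maximal runs of scores
≥ 0.5 with length strictly greater than 30 residues, with no gap
tolerance — smoothing of the disorder signal is the predictor's job,
and re-smoothing here would double-count it. llIDR segmentation cuts
consecutive 200-residue blocks; a final remainder shorter than 30
residues is merged into the preceding block, so every segment carries
enough residues for stable composition estimates (the shortest possible
segment is 30; the longest is 229).

## The 90-feature grammar vector

Fixed column order: 36 patterning z-scores, 20 amino-acid fractions,
5 grouped fractions, 2 log-ratios, 7 charge/global scalars, 19 residue
patch fractions, 1 RG-stretch fraction.

**Patterning z-scores.** Eight residue classes — pol {S,T,N,Q,C,H},
hyd {A,I,L,M,V}, pos {R,K}, neg {D,E}, aro {F,W,Y}, ala {A}, pro {P},
gly {G} — give 36 unordered pairs including self-pairs. For a pair
(X, Y) the sequence is mapped to ternary labels (X / Y / other; where
classes overlap, as alanine does in hyd and ala, the first class of the
pair takes precedence — pairs are evaluated independently, so the
overlap never mixes within one statistic). The blockiness statistic is
the variance across sliding windows of the windowed class asymmetry
(n_X − n_Y)/g, averaged over window sizes g = 5 and 6 — a kappa-style
patterning parameter. Only the z-score against n within-sequence
shuffles (default 1000, mandatory seed) is reported, so the overall
scale of the statistic cancels under the null; what matters is that it
orders blocky above well-mixed arrangements. Pairs where either class
has fewer than two residues carry no patterning information and are
reported as 0 with a flag. Calibration (acceptance suite): across 200
sequences drawn from a fixed composition's own shuffle null, the
(pos, neg) z has mean within ±0.15 and SD within [0.8, 1.2], while a
50/50 E–K diblock scores z ≥ 3 (in practice ≈ 19).

**Composition.** Fractions are counts/length. Grouped sets: K+R, D+E,
Polar {S,T,N,Q,C,H,Y}, Aliphatic {A,I,L,M,V}, Aromatic {F,W,Y}. The
basic/acidic bias ratios use +1 pseudocounts,
log₁₀((n_K+1)/(n_R+1)) and log₁₀((n_E+1)/(n_D+1)), so they are defined
for sequences lacking either residue (and equal 0 in the fully
symmetric or fully absent cases).

**Charge and global scalars.** FCR and NCPR are computed as the sum and
difference of the K+R and D+E fractions, so the identities
FCR = f(K+R) + f(D+E) and NCPR = f(K+R) − f(D+E) hold bit-exactly.
Hydrophobicity is the per-residue mean of Kyte–Doolittle rescaled to
[0, 1]. The disorder-promoting set is {A,R,G,Q,S,P,E,K}; the
chain-expanding set (charged residues plus proline) is {E,D,R,K,P}.
PPII propensity is the mean of a fixed per-residue experimental
propensity ladder (proline highest at 0.74, glycine and tryptophan
lowest at 0.40). pI is solved by bisection of the net-charge curve on
pH ∈ [0, 14] with the EMBOSS pKa table, free termini included, to
|net charge| < 1e-4; because the titration curve can be shallow near
neutrality this guarantees the charge criterion, not a fixed number of
pH digits. All scales and sets live in `idrcond.config` and are
overridable.

**Residue patches.** For each residue type (A…Y excluding tryptophan,
which is too rare in disordered sequence for a stable patch signal), a
patch is a chain of occurrences in which consecutive occurrences are
separated by at most 2 other residues; chains with ≥ 4 occurrences
qualify, and the feature is the fraction of sequence length covered by
qualifying chain spans. The RG-stretch analogue chains non-overlapping
"RG" dimers (scanned left to right) separated by at most 2 residues,
qualifying at ≥ 2 dimers. Both equal exhaustive span enumeration on
every length-12 binary sequence and on random 20-letter sequences
(tested).

**Variability.** Per-feature population SD (ddof = 0) across a
region's segments; undefined (flagged) for fewer than two segments;
features flagged in every segment are excluded as NaN.

**Charge rewiring.** AtoB maps D→R and E→K; BtoA mirrors it (K→E,
R→D); AtoNon/BtoNon substitute serine — small, polar and
disorder-compatible, chosen because published constructs do not print
their substitution table. Balanced substitution (BS) converts the
minimal number of acidic residues, left to right, to their basic
counterparts such that |NCPR| of the product is minimal (each
substitution shifts the net charge by +2; the minimal count among
minimizers is used). An exhaustive minimization over substitution
counts is the test oracle.

## Imaging metrics

**Line scans.** The 5-point running average is centered; at the trace
ends the window is clipped to the available samples and the mean taken
over what remains, so length is preserved and no padding value is
invented. CI uses the linearly interpolated (type-7) 20th percentile as
baseline and 1.4826·MAD as the robust scale — the consistency factor is
applied exactly once, in CI itself. A flat trace scores CI = 0; a
positive peak over zero MAD indicates a degenerate trace (bad line
placement) and raises rather than returning infinity. Line placement is
an input, not an algorithm. PVR is computed on the smoothed trace and
lies in [0, 1] for nonnegative traces, equal to 0 iff the trace is
constant.

**Foci.** Segmentation thresholds pixels inside an intensity window
(default 10–50, on the image's native scale — the window is
instrument-dependent and config-exposed), takes 8-connected components
within the nucleus mask, and drops components below 4 px. The
condensed area fraction is Σ focus areas / mask area; the condensed
intensity fraction is Σ focus integrated fluorescence / total nuclear
fluorescence. On noiseless synthetic images both recover the
generator's ground truth within 0.02; the residual comes from the 2σ
truth-disk convention (≈ 5% of a Gaussian punctum's mass lies outside
2σ) and window clipping at punctum edges.

**FRAP.** Background-subtracted bleach-ROI and total-area traces are
double-normalized, I_dn(t) = (T_pre/T(t))·(I(t)/I_pre), rescaled so the
pre-bleach mean is exactly 1, and a full-scale curve maps the first
post-bleach point to 0. The recovery model is single-exponential,
I(t) = M·(1 − exp(−t/τ)), fit by least squares on the post-bleach
full-scale curve; the mobile fraction is M and the half-time τ·ln 2. At
least five pre-bleach frames are required. A perfectly flat post-bleach
curve short-circuits the fit (M = plateau, τ undefined).

**pbFRET.** Per-image backgrounds are subtracted from all ROIs of that
image; the unbleached control ROI gives the drift factor
b = DN_post/DN_pre, and E = 1 − D_pre·b/D_post. E may legitimately be
negative (corrected donor dimming). The synthetic generator emits the
exact forward model D_post = D_pre·b/(1 − E), and inversion recovers
programmed E to 1e-9 over a grid of efficiencies and drift factors.

## Expression-matched condensation testing

Cell states are classified from morphology and FRAP: no foci → diffuse;
foci with circularity ≥ 0.8 and mobile fraction ≥ 0.5 → LLPS; other
foci → aggregate; foci lacking a FRAP measurement → unclassified. The
thresholds are declared defaults, not measured constants, and are
config-exposed.

The propensity model is a logistic regression of group membership on
intensity; matching is greedy 1:1 nearest-neighbour without replacement
on the linear predictor (logit) scale, processing order randomized by
seed, caliper 0.2 × SD of the logit propensity (the conventional
reading of "caliper 0.2"). With identical intensity distributions the
caliper still leaves distribution-tail cells unmatched (of 50 + 50
cells roughly 40 pairs form; even optimal bipartite matching within the
caliper does no better, a Kolmogorov-fluctuation effect). Perfect
separation of the logistic fit (disjoint intensity supports) is caught
and degrades gracefully to an empty matched set.

Fisher's exact test (two-sided, hypergeometric) runs on the 2×2 table
of group × condensate over matched cells; the implementation delegates
the p-value to scipy and is tested against an independent exact
rational-arithmetic enumeration to 1e-12. The odds ratio is the sample
cross-product ratio with the Haldane 0.5 correction when a cell is
zero; a table with an empty margin is reported as p = 1, flagged.
Calibration on 500 simulated populations of 100 + 100 cells: under the
null (state independent of group and intensity, p = 0.5) the matched
test rejects at the nominal 5% level (0.05 ± 0.02); when condensation
depends only on intensity and the groups differ in intensity, the
unmatched test rejects ≥ 80% of the time while the matched test stays
≤ 10% — matching removes the confound.

## Accessibility transitions

Merging follows bedtools semantics: after sorting, intervals on the
same chromosome separated by a gap ≤ 100 bp (including overlap and
touching) fuse; the operation is idempotent and equals a brute-force
pairwise-fusion oracle (and bedtools itself, cross-checked in a test).
The unified reference reuses the same 100-bp gap — the natural
consistent choice where the merging step is described without
restating the gap. A reference peak is open in a condition iff it
overlaps any of that condition's merged peaks by ≥ 1 bp (half-open
arithmetic: [100, 200) vs [199, 250) overlap by 1 bp; [100, 200) vs
[200, 250) do not). Pattern codes read the states in an explicit,
logged condition order (default EV, FL, TR, LTR); counts always sum to
the number of reference peaks. The alluvial export samples peaks
uniformly without replacement (default 5000, seeded) into a
long-format table.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* each analysis
assumes — blockwise residue composition, Gaussian puncta over a flat
nuclear background with additive Gaussian noise clipped at zero,
exponential FRAP recovery, the exact pbFRET forward model,
logistic-in-intensity condensation with group effects, and programmed
open/closed patterns with loci spaced > 100 bp so condition-level
merging never fuses distinct ground-truth units. They do not emulate
real optics (no PSF, no z-sectioning, no shot noise), chromatin
peak-shape or replicate structure, or biological covariance between
features. Passing round-trips therefore demonstrate that the analysis
code implements its stated contracts exactly, not that the contracts
are robust to every instrument artifact.

Default study conditions used by the tests and the acceptance script:
puncta of σ = 2.5–3 px and amplitude ≈ 40 over background 5–20 on
128×128 images (radius-50 nucleus), punctum centers ≥ 25 px apart so
fixed-window segmentation sees distinct spots; FRAP traces of 85 frames
bleached after frame 5 with 20% residual signal; populations of 100
cells per group with intensity SD 20; 200–400 peak loci of width
150–400 bp across two chromosomes. Simulation sizes (200 null
sequences × 1000 shuffles; 300–500 matched-test replicates; 300–1000
random interval sets) were chosen to estimate the calibration rates to
roughly ±0.02 while keeping the suite quick to run.

## Known limitations

- The patterning statistic is one member of the kappa family; absolute
  z-values are comparable only within a fixed window configuration and
  class definition.
- The logistic propensity model matches on intensity only; unmeasured
  confounders (cell-cycle stage, imaging batch) are untouched.
- Greedy matching is order-dependent by design (seeded); optimal
  matching would recover a few more pairs but not change the
  calibration properties.
- The single-exponential FRAP model under-fits two-component
  recoveries; mobile fractions from such data are effective, not
  mechanistic, parameters.
- Focus segmentation assumes the intensity window is meaningful on the
  image's native scale; images from different instruments need
  rescaled windows.
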