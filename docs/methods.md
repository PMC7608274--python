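# Methods

`protvp` is a protein-specific missense-variant classifier of the kind built
for single genes with a known or modelled structure: every variant is reduced
to a small set of interpretable structural and sequence criteria, and a
simple, heavily regularised linear model combines them.  This note records
the model, the numerical choices, and what the synthetic studies do and do
not demonstrate.

## The eight criteria

For a variant (ref, position, alt) on a single-chain structure with a
topology annotation (modelled residue ranges, domains I–IV, segments S1–S6,
a C-terminal domain, and one intracellular anchor residue):

| feature | definition | type |
|---|---|---|
| f1 | position lies inside a modelled range (inclusive intervals) | binary |
| f2 | loss of positive charge (ref ∈ {K,R}, alt ∉) and position in any S4 segment | binary |
| f3 | gain of positive charge (ref ∉ {K,R}, alt ∈) anywhere | binary |
| f4 | hydrophobic loss (ref hydrophobic, alt not) and position in domain I | binary |
| f5 | conservation decile of the position, 1 = most conserved | ordinal 1–10 |
| f6 | position in domain I and on the intracellular side | binary, missing if unmodelled |
| f7 | volume-change bin of V(ref) − V(alt) with edges −42, 0, +42 Å³ | 4 levels |
| f8 | clash score (internal proxy or ingested contact score) | real ≤ 0, missing if unmodelled |

Charge classes use the physiological-pH convention (K, R positive; D, E
negative; His neutral).  The hydrophobic set is the ten classically apolar
residues F, M, I, L, V, C, W, A, T, G — on the embedded transfer-free-energy
scale this corresponds to a threshold of ΔG ≥ 1.0 kcal/mol; a plain ΔG > 0
rule would also admit serine (ΔG = +0.6), which the package deliberately
excludes.  Volume bins are left-open/right-closed at every edge, so −42 falls
in the most-negative bin and 0 in the (−42, 0] bin.

Missing structural features for unmodelled positions are first-class: they
become their own discretization level rather than dropping the row, because
f1 itself is a feature and unmodelled variants must still be scorable.

## Sidedness

The membrane side of a residue is decided by the angle at the protein's
centre of mass between the vector to the query Cα and the vector to the
anchor residue's Cα; below 90° counts as intracellular.  The centre of mass
is the unweighted mean of all atom coordinates (mass weighting moves it by a
fraction of an ångström on typical compositions and never flips a call far
from the boundary).  The C-terminal domain and unmodelled positions are
excluded.  Note the rule is exact only for residues well away from the
membrane plane: for a bundle of half-height *h* and radius *r*, calls within
roughly *r²/2h* of the plane depend on azimuth.  On the synthetic bundle
with 30-residue helices, >90 % of residues below the plane are called
intracellular; shorter bundles blur further.

## Clash proxy

Mutant side chains are built by NeRF from idealized internal-coordinate
templates (standard bond lengths/angles, approximate ring closure) with χ
angles taken from a compact backbone-independent rotamer set (≤ 9 conformers
per residue type, modal values of the common rotamers).  For each rotamer the
penalty is

    Σ over pairs (mutant side-chain atom i, atom j of any other residue)
        max(0, r_i + r_j − d_ij)²

with Bondi-style van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å); the reported score is −(minimal penalty over rotamers), times a
configurable scale (default 1).  The score is an *ordinal* measure of steric
strain: it shares the sign convention of contact-dot goodness-of-fit scores
(more negative = worse) but not their units, so comparisons against numeric
thresholds from dot-based software must use ingested scores (a `probe`
column in the variant table, selected by a flag), never the proxy.  No
hydrogens are added; candidate neighbours are found with a KD-tree, and any
genuinely overlapping pair is always within the default 5 Å search radius,
so the cutoff only bounds work, not results.

## Conservation

A column's score is Σ_a freq(a) · BLOSUM62(ref, a) over the gap-excluded
residue frequencies — the expected substitution score of the column against
the reference residue.  Scores are ranked descending (high self-substitution
score = conserved) and cut into ten equal-frequency bins (sizes differ by at
most one; ties broken by ascending position for determinism).  Decile ≤ 5 is
"conserved".  Columns with under 50 % non-gap coverage are flagged
low-confidence but still scored.  This frequency-profile reading is one of
several reasonable position-specific scoring constructions; it is monotone
under the obvious invariances (identical columns score the diagonal entry,
mixtures are linear).

## The classifier

1. **Class balancing** — instance weights rescale each class to half the
   total mass, preserving the total (72 + 322 instances give per-class mass
   197 exactly).
2. **Supervised MDL discretization** (Fayyad–Irani) — recursive binary
   splitting of each numeric feature (f5, f8) on weighted class entropy,
   accepting a split only when the information gain exceeds
   (log₂(N−1) + log₂(3^k − 2) − k·E(S) + k₁·E(S₁) + k₂·E(S₂)) / N, with
   instance weights folded into all class counts and N the total weight.
   Cut points are midpoints of adjacent observed values rounded to six
   decimals.  Categorical/binary features pass through as levels.
3. **Weighted ridge logistic regression** — maximises the weighted
   log-likelihood minus λ‖β‖² (intercept unpenalised, λ = 10⁻⁸ by default)
   by L-BFGS with an analytic gradient to tolerance 10⁻⁸.  The penalised
   likelihood is strictly concave, so the optimum is unique and finite even
   under complete separation.  Discretized bins are indicator-encoded: a
   2-level feature becomes one column, k > 2 levels become k one-hot columns
   (the tiny ridge resolves the intercept collinearity); levels unobserved at
   fit time are not encoded.  Features reduced to a single level are dropped;
   a table with no informative feature degrades to an intercept-only model.

The decision threshold on P(disease) defaults to 0.56, boundary inclusive.
In cross-validation all three stages are re-fit inside each training fold —
fitting the filters globally before splitting would leak label information
into the discretization cuts, so pooled out-of-fold metrics here can sit
slightly below what a filter-then-split protocol reports on the same data.

## Evaluation

ROC AUC is the trapezoidal area over threshold-induced points and equals the
Mann–Whitney pairwise form (ties counted half) to machine precision — this
equivalence is asserted, not assumed.  PR AUC uses the step-wise
average-precision estimator with no interpolation; interpolated estimators
give slightly different areas on small cohorts.  MCC is the standard
four-count correlation, defined as 0 when a marginal is empty.
Cross-validation pools out-of-fold scores into one curve (per-fold AUCs are
also reported in the extras).  The Mann–Whitney test is exact when
n₁·n₂ ≤ 400 (null-distribution DP without ties; full combination enumeration
for small tied samples), otherwise tie-corrected normal.  McNemar uses the
continuity-corrected chi-square on discordant pairs.  Bonferroni defaults to
m = 10 comparisons (α 0.05 → 0.005), configurable.  External predictor
columns (SIFT, PolyPhen2, CADD raw/scaled, CONDEL) are evaluated from
ingested scores only, with per-tool thresholds and score direction (SIFT's
"lower = damaging" is negated for ranking).

## Synthetic fixtures

The generator emulates the statistical structure of a membrane-channel
variant study, not its physics:

* **Structure** — eight ideal α-helices (φ = −57°, ψ = −47°; backbone
  N, CA, C, O plus Cβ) of 24 residues on a circle of radius 11 Å,
  antiparallel, long axis along z; 4-residue unmodelled linkers, an
  8-residue unmodelled N-terminus and a 30-residue C-terminal domain;
  segments assigned S1…S6 within each domain in order (the default bundle
  covers domain I completely plus S1–S2 of domain II); anchor residue =
  lowest Cα.
* **Alignment** — 24 rows mutated from the reference at rate 0.02 inside
  conserved blocks (the modelled helices by default) and 0.5 elsewhere.
* **Cohorts** — every possible substitution is featurized once; a planted
  log-odds score over the criteria (defaults weight modelled-region
  membership, conservation, charge gain and clash most heavily, mirroring
  the contrasts such studies report) splits the universe into disease and
  benign sampling pools through a logistic link, and the link's scale is
  bisected until the *exact* mixture AUC — computed by summation over the
  finite universe — equals the target (0.90 by default; 70 disease and 320
  benign draws, i.i.d., so duplicate and cross-cohort repeats can occur as
  in real surveys).

Because the generating AUC is exact, "the pipeline recovers the planted
signal" is a sharp statement: over ten cohort seeds the pooled tenfold-CV
ROC AUC averages within ±0.05 of 0.90 (single seeds scatter by roughly ±0.03
from 394-instance sampling noise plus learning loss), and with all effects
off it averages inside [0.4, 0.6].  What passing these studies does *not*
show: that the idealized geometry resembles any real fold, that the clash
proxy matches contact-dot scores numerically, or that the planted effect
structure matches any particular protein's variant biology — real-data use
still requires a real structure, alignment and curated labels.

## Degenerate inputs and tie-breaks

* Identical ref/alt, unknown residues, positions < 1: rejected at record
  construction.  Variant reference residues disagreeing with the
  protein/alignment reference: hard error, never silent renumbering.
* Discretizer: constant features give an empty cut set; the entropy-minimal
  split prefers the lowest cut value on ties.
* Deciles: need ≥ 10 scored positions; ties broken by position index.
* Clash: glycine substitutions and isolated residues score exactly 0;
  Cα-only models raise "insufficient atoms".
* All randomness flows from explicit integer seeds; every generator and the
  CV splitter are reproducible bit-for-bit under a fixed seed.

## Problem sizes

The bundled studies use a 192-residue modelled bundle (262-position
sequence, ~4,900-variant universe), 24-row alignments and 390-variant
cohorts over ten seeds — sizes chosen so the full study, including universe
featurization, completes in well under a minute while keeping per-seed AUC
noise near ±0.03.
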