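# Methods

`mircurve` predicts functional miRNA target sites on mRNA transcripts from
CLIP-seq-derived labels. The pipeline has five stages: candidate-site
generation, spatial profiling, functional (curve) feature extraction,
seed-pattern enrichment scoring, and linear-SVM classification under a
negative-subsampled cross-validation protocol. This note records the models,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Duplex model and candidate generation

A candidate site is an alignment of the full guide (miRNA, 5'→3') against a
target window, antiparallel, with no intramolecular pairs. The energy of a
duplex is

    ΔG = Σ stack(p_t, p_{t+1})  +  Σ_loops [init + ext·(L−1)]  +  ε·(unpaired guide ends)

where consecutive base pairs contribute nearest-neighbor stack energies,
an interior loop or bulge with `L = max(unpaired_guide, unpaired_target)`
unpaired bases costs `init + ext·(L−1)` (defaults 3.2 and 0.6 kcal/mol,
loops capped at 10 nt per strand), and each unpaired guide-terminal base
costs ε = 0.2 kcal/mol. Watson–Crick and G:U pairs are allowed; `N` never
pairs. The Watson–Crick/Watson–Crick stack table is the standard published
nearest-neighbor set; wobble-containing steps ship with coarse values and a
−0.5 kcal/mol default (the YAML config accepts any published set). Absolute
ΔG values are therefore model-dependent; every test compares against
internal oracles (exhaustive pairing enumeration), not published energies.

The minimum-energy duplex is found by a dynamic program over base pairings
(`O(m·n·L²)`, numba-compiled for window scans; a pure-Python implementation
with traceback produces the alignment columns and must agree exactly — this
is tested). Ties are broken deterministically: fewer gap columns, then the
5'-most site start. A window with no possible pair returns a no-alignment
sentinel, and window ΔG values are clamped at 0 (a duplex that costs energy
does not form).

Candidate generation applies two filters per (miRNA, transcript), over all
transcript regions:

- **energy filter** — stride-1 windows of length `len(miRNA) + 15`; runs of
  consecutive windows with ΔG below −15 kcal/mol are collapsed to their
  energy argmin and aligned;
- **seed filter** — every run of ≥ 6 consecutive Watson–Crick complements
  to guide positions 1–8 (found by direct string scan) yields a site
  regardless of energy, aligned with the seed pairs pinned. G:U wobbles
  never count toward a seed run.

Overlapping sites for the same pair are deduplicated keeping the
lower-energy one; a discarded overlapping seed site passes its seed flag to
the kept site (the locus has a canonical match even if the minimum-energy
duplex does not use it). A site is labeled +1 iff its interval is contained
in a merged AGO-CLIP interval of the same transcript.

The seed-alignment pattern encodes the columns spanning guide positions 1–8
as 1 (match), 2 (mismatch), 3 (gap), 4 (G:U); target bulges inside the span
appear as their own gap-coded columns, so patterns have length ≥ 8.

## Spatial profiles and accessibility

Each site yields six 27-point profiles (t = −13…13): duplex ΔG,
accessibility ΔΔG and AU fraction, at site resolution (width 46 nt, the
AGO-footprint scale) and seed resolution (width 9 nt). The t = 0 window is
the site (or seed-matched) interval itself, at its own width; flanking
windows abut it without overlap. Windows extending past the transcript are
masked and hold 0 (the model's missing-value convention). For seedless
sites the seed-resolution center is the 8-nt window inside the site with
the best guide-1–8 hybridization. Site-resolution energy curves use the
full guide; seed-resolution energy curves use guide nt 1–8.

ΔG_open is computed with a simplified intramolecular fold — weighted
base-pair maximization (WC −2.0, G:U −1.0, minimum hairpin loop 3) on the
window ± 100 nt of context — as E(context with the window forced unpaired)
− E(context unconstrained) ≥ 0, and ΔΔG = ΔG − ΔG_open ≤ ΔG. A partition
function would be more faithful thermodynamically; the simplified fold is
chosen because it is exactly verifiable against enumeration at desk scale,
and the fold model is pluggable.

One property worth noting: reversing a transcript reverses the AU and
opening-energy profiles exactly (both are orientation-symmetric), but not
the duplex ΔG profiles — the duplex is antiparallel and nearest-neighbor
stacks are orientation-specific, so no implementation could satisfy a
blanket reversal symmetry.

## Curve features

Each profile is projected on K cubic B-spline basis functions (clamped,
uniform knots over t = 0…26; default K = 20, shared by all six curves) by
solving the normal equations c = (ΨᵀΨ)⁻¹Ψᵀf, with a pseudo-inverse fallback
that is tested but unreachable for uniform knots at K ≤ 27. The reported
knot count follows the bookkeeping formula K − degree + 2 (19 at K = 20).
Fit error is non-increasing in K only along nested knot chains (K−3
dividing K′−3); uniform-knot spaces are not nested in general. K can be
selected by cross-validation maximizing the mean held-out TPR−FPR gap
(ties to the smaller K); the default 20 is used throughout.

## Seed-pattern enrichment

For a pattern **a** observed k times among n positive sites, the chance
probability of one specific length-|a| target word under an i.i.d. uniform
background is 0.25^|a|, and

    enrichment(a) = 1 − Binomial(k | n, 0.25^|a|)

with the binomial probability mass evaluated in log space (exact log-sum
binomial coefficients up to n = 10⁵). A config switch substitutes the upper
tail P(X ≥ k) — the statistically conventional reading — but the mass form
is the default. Unseen patterns score 0. Enrichment tables are always built
from training-fold positives only.

## Classifier

The linear SVM minimizes the L2-regularized hinge loss
`(1/n) Σ max(0, 1 − y·(w·x+b)) + (λ/2)‖w‖²` with λ = 0.001 and the
intercept unpenalized, trained by per-sample SGD with the strongly-convex
schedule η_t = 1/(λ(t+t₀)), t₀ = 1/λ, 50 epochs with per-epoch shuffling by
default, and Polyak–Ruppert averaging of the iterates over the last half of
training (last-iterate SGD oscillates several percent above the optimum at
this λ). Training is bit-reproducible given the seed. Scores are the raw
(uncalibrated) logistic of the margin, thresholded at 0.5 for class calls.

The design matrix has dimension 6K + 8: six K-coefficient curve blocks,
then seed enrichment, site/seed/off-seed mean conservation (seed terms are
0 for seedless sites), site length, two region dummies (CDS and 5' UTR,
with 3' UTR as baseline), and the site's relative location within its
region (0 = region 5' end, 1 = 3' end, denominator `region_len − 1`; the
region of the site's 5'-most nucleotide decides). Columns are z-scored with
training-split statistics stored in the model; features on kcal/mol and
[0,1] scales are otherwise badly conditioned for hinge-loss SGD.

## Validation protocol

Negatives outnumber positives, so each evaluation run keeps all positives
and draws an equal-size negative subsample without replacement. Each run is
split into stratified folds (default 10 × 10; the shipped acceptance
configuration scales this to 3 subsample runs × 5 folds); the entire
classifier — enrichment table, spline features, standardization, SVM — is
refit on each training split. TPR and FPR are computed on a fixed
probability-threshold grid and averaged pointwise across all runs × folds.
The grid is spaced evenly on the logit scale (expit of ±30, 403 points):
the uncalibrated logistic saturates confident scores, and a uniform [0,1]
grid measurably discards rank information in the tails. The best operating
point is the threshold maximizing TPR − FPR. A cross-species mode trains on
one dataset and scores another; a stratified report breaks shared scores
down by region × seed/seedless. All randomness flows from one master seed
through named substreams.

## Synthetic fixtures

The generator emulates the data signatures the real pipeline consumes:

- background transcripts are i.i.d. uniform over ACGU (configurable GC
  bias), so the 0.25^|a| chance model is exactly correct on unplanted
  sequence and enrichment calibration can be tested;
- 50 transcripts of 900–1100 nt with 15/45/40% 5'UTR/CDS/3'UTR splits and
  three embedded sites each (several hundred candidate sites in total, so
  cross-validated AUC estimates are stable); four 22-nt guides drawn
  AU-rich (0.7) — complementation preserves AU fraction, so embedded sites
  carry the elevated local-AU signature of functional sites, peaking at
  t = 0;
- embeddings complement 18 guide nt; half use non-canonical seed-alignment
  patterns (a mismatch-flanked 6mer and a wobble-interrupted seedless
  pattern) so non-canonical sites are over-represented among positives;
- CLIP regions 46–60 nt wide wrap every embedded site (a configurable
  fraction; misplacement probability `noise` defaults to 0); flanks are
  AU-enriched (0.8 over ±20 nt) and redrawn up to 6 times to leave the
  embedded site accessible (opening energy ≤ 1 kcal/mol);
- conservation is low piecewise-constant background with elevated blocks
  over wrapped embedded sites;
- the null condition (all signal toggles off) keeps the same embeddings
  but wraps CLIP regions around a fair-coin random subset of *all*
  candidate loci (embeddings, seed-complement hits and energy-scan loci,
  merged so each locus gets one coin, wrap probability 0.45). Positives
  are then a random subset of the candidate population — independent of
  every sequence feature by construction. Uniform random placement was
  rejected: interval containment favors short, interior sites, which
  measurably correlates labels with site length, position and duplex
  energy.

What the fixture does not emulate: crosslink-induced substitutions and
other read-level CLIP artifacts, transcript-abundance effects, shared seed
families, and realistic (non-i.i.d.) sequence composition. One property of
real CLIP labeling is deliberately kept: CLIP regions are miRNA-agnostic,
so a candidate for guide B inside a region bound by guide A is labeled
positive without carrying B's signal. Passing the signal-condition AUC
threshold therefore shows the pipeline recovers planted signal through that
ambiguity; it does not certify performance on real data.

## Problem sizes and numerics

The shipped end-to-end configuration (50 transcripts × 3 sites, 4 guides,
3 subsamples × 5 folds) was chosen so the full pipeline completes in a few
minutes on one CPU; larger protocols scale linearly. Energies compare with
a 1e-9 tie tolerance; curve coefficients reproduce a QR solve to 1e-8;
enrichment matches an exact binomial oracle to 1e-12 at n = 10⁴. Degenerate
inputs: single-class training data raises; folds that would leave a split
single-class are reshuffled with a warning; a stratum without both classes
reports an undefined (None) ROC; empty pattern tables score every lookup 0.

## Known limitations

- The energy model's wobble stacks are coarse; absolute ΔG values should
  not be compared against RNAhybrid/Vienna outputs (drop in a published
  table for that).
- ΔG_open ignores the thermodynamic ensemble (no partition function).
- The logistic probabilities are uncalibrated; they are ranking scores,
  not calibrated posteriors.
- The candidate scan collapses each run of threshold-passing windows to its
  energy minimum; sub-resolution multiple sites closer than one window
  length merge into one.
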