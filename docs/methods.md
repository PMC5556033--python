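# Methods

## Protein Block encoding

A Protein Block (PB) is one of 16 local-backbone prototypes, `a`…`p`, each
defined by 8 reference dihedrals over a five-residue window centred on the
assigned residue: ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1),
φ(i+2). The reference table ships as package data
(`pbflex/data/pb_prototypes.tsv`) with provenance: it is the table of the
alphabet's defining publication (de Brevern, Etchebest & Hazout, Proteins
2000), identical to the one distributed with the PBxplore assignment
tool. The alphabet is *not* re-derived here; unsupervised
re-training is out of scope.

Assignment: φ/ψ are computed per frame from N/CA/C coordinates with the
IUPAC sign convention; a residue's window is compared to all 16 prototypes
by RMSDA (root mean square deviation of angles, every difference wrapped to
[−180, 180] on the circle) and the argmin letter is taken. Ties — possible
only on a measure-zero set — break to the alphabetically lowest letter, so
assignment is deterministic. Angles are everywhere canonicalized to
(−180, 180]. Positions without a fully defined window (the two first and
two last residues of a chain, and neighbours of any undefined torsion, e.g.
at a degenerate near-collinear geometry) receive the uppercase placeholder
`Z`.

## Per-position statistics

With `f_x` the probability of PB `x` at a position (pooled over frames),

* `Neq = exp(−Σ f_x ln f_x)` (natural log; `0·ln 0 := 0`), in [1, 16];
* `ΔNeq = |Neq_A − Neq_B|`;
* `ΔPB = Σ_x |f_x^A − f_x^B|`, the L1 distance in [0, 2].

`Z` observations are removed from both numerator and denominator: the
statistics are defined over exactly 16 PBs, and a position whose every frame
is `Z` is undefined (NaN propagates). Pooling across runs is
**frame-weighted** (a 100 ns run contributes twice the frames of a 50 ns
run at fixed stride); per-run matrices can be combined run-weighted by
averaging the per-run frequency matrices instead, which `frequency_matrix`
of single runs plus a manual mean provides. Frame-weighted pooling is the
default because the pooled estimator is the maximum-likelihood estimate of
the stationary per-position distribution when all frames are regarded as
exchangeable draws.

Hotspot ranking orders positions by ΔPB, ties by ΔNeq and then by residue
number; the mutation site's own rank is reported alongside so distal
effects are explicit.

## Flexibility metrics

RMSD and RMSF are computed on Cα only. Each frame is least-squares
superposed (own SVD-based Kabsch with determinant correction; the test
suite cross-checks it against SciPy's independent `align_vectors`). RMSF
uses the standard convention the underlying analyses leave open: frames are
fitted to the first retained frame, a mean structure is formed, and the fit
is iterated once onto that mean before taking per-residue root mean square
displacements. Equilibration frames (default: first 5 ns, i.e. frame times
≤ 5000 ps) are discarded first; the first/last two residues are trimmed
from profile summaries by default because chain ends are artefactually
mobile when a neighbouring domain is absent.

B-factors are taken from the Cα atom by default (switchable to a
backbone-atom mean), keeping the three metrics Cα-comparable; B-factors are
never rescaled into RMSF units — the metrics are compared by rank. The
residue classifier uses upper-quantile cuts (default 0.80, configurable)
on RMSF and Neq; the discordant high-RMSF/low-Neq cell is labelled
`rigid-core-in-deformable-loop`. Because only ranks enter, classification
is invariant under monotone rescaling of either metric; a constant metric
classifies everything low, with a warning.

## Sammon mapping

One point per simulation (not per frame). A simulation's signature is its
per-position PB frequency matrix; the inter-simulation dissimilarity is the
mean per-position ΔPB over commonly defined positions, divided by 2 — a
scaled L1 metric in [0, 1]. This metric is a package decision (pluggable:
any symmetric zero-diagonal dissimilarity matrix can be passed to the
mapper directly), made because it reuses the repertoire distance the rest
of the pipeline is built on.

`SammonMapping` is an sklearn-style estimator minimizing
`E = (Σ δ_ij)⁻¹ · Σ (δ_ij − d_ij)²/δ_ij` by Sammon's diagonal second-order
update damped by a magic factor of 0.3, with step-halving: an update is
accepted only if stress does not increase, so `stress_history_` is
monotonically non-increasing by construction. Initialization is classical
metric scaling of the dissimilarities — exact (stress ≈ 0 immediately) when
the input distances are realizable in the target dimension — with a seeded
Gaussian fallback; `max_iter` 500 and relative tolerance 1e-9 by default.
Coincident simulations (zero off-diagonal dissimilarity) are jittered by a
documented epsilon with a warning, since the stress weights each pair by
1/δ. Barycentres are arithmetic means of each system's points, exactly.

## Synthetic ground truth

The generator emulates the study design the analysis conventions assume:
11 independent runs per system (5 × 50 ns + 6 × 100 ns = 850 ns), frames
saved every 100 ps, the first 5 ns treated as equilibration, two residues
trimmed per terminus. Those values are the generator defaults; tests that
need more statistical power scale the *frame count* (e.g. 10,000 pooled
frames), never the design constants.

* `distribution_for_neq` inverts the Neq formula on a two-level family (one
  dominant PB at p, the remaining support sharing 1−p equally) by bisection
  to |Neq − target| < 1e-6; the endpoints (one-hot, uniform) are returned
  in closed form.
* PB ensembles are i.i.d. categorical draws per frame and position — a
  deliberate simplification that drops MD autocorrelation and cross-residue
  coupling. Passing tests therefore demonstrate estimator correctness at a
  known effective sample size, not realistic MD convergence rates: on real
  trajectories the effective number of independent frames is smaller, so
  sampling-noise floors (e.g. the ΔPB ≈ 0.02 background in the README
  example) will be correspondingly higher.
* 3D backbones are built from φ/ψ by sequential internal-coordinate (NeRF)
  placement with fixed ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N
  1.329 Å; angles N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°; ω = 180°).
  Only φ/ψ vary, which suffices because PB assignment reads only φ/ψ.
* Planted PB strings: a residue's assignment window overlaps its
  neighbours' dihedrals, so an arbitrary letter string realized in 3D need
  not reproduce itself under assignment (uniform-random strings
  self-recover at only ~15–20% of positions). Real PB sequences are locally
  self-consistent; the generator reproduces that property by planting the
  fixed point of build-then-assign (`plant_pb_string`), reached by a short
  iteration from a random string. For such strings, zero-noise round-trip
  recovery is exactly 100% at all non-`Z` positions, and recovery degrades
  monotonically with dihedral noise.
* Noisy Cartesian ensembles add i.i.d. per-axis Gaussian noise of width σ_i
  per residue; the ground-truth RMSF is σ_i·√3.
* All generators are deterministic functions of (master seed, system, run),
  derived via independent seed sequences, so runs and systems are
  independent reproducible streams.

## Numerical and degenerate-input choices

* Angle wrapping to (−180, 180] everywhere; circular differences in
  [−180, 180].
* Torsions of near-collinear atom triplets (normal vector below 1e-10) are
  NaN, which propagates to `Z` assignments.
* Alternate locations resolve to the highest-occupancy conformer; insertion
  codes are rejected outright (unambiguous author numbering is assumed by
  every downstream table).
* Residues missing a backbone atom are kept in the model with NaN
  coordinates, logged, and excluded from the dihedral-capable set; an
  all-zero B-factor column triggers a stripped-file warning but still
  returns a profile.
* Frequency rows with at least one observation sum to 1 within 1e-9 by
  construction; `Neq` of an undefined row is NaN, never a fabricated value.
* Frame times must be strictly increasing; formats without time stamps get
  a uniform 100 ps stride starting at 100 ps, so "discard 5 ns" removes
  exactly the first 50 frames of a 100 ps-stride run (950 of 1000 frames of
  a 100 ns run are retained).

## Known limitations

* The synthetic ensembles have no kinetics: no autocorrelation, no
  transitions, no solvent. They validate estimators, not sampling adequacy.
* PB assignment windows at chain breaks are not special-cased; a chain with
  internal gaps (missing backbone atoms) simply yields `Z` stripes around
  the gap.
* The inter-simulation metric and the Sammon hyper-parameters are package
  choices, not reconstructions of any particular prior analysis; both are
  explicitly pluggable/configurable.
* Trajectory I/O covers multi-model PDB and GROMACS XTC (via biotite);
  XTC coordinates are quantized by the format (~0.01 Å), which is visible
  in strict round-trip comparisons.
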