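# Methods

## Scope and model

`bindmode` implements the analysis layer of a binding-mode study: given
per-frame MM-GBSA-style binding-energy components from replicate trajectories
of a kinase–ligand complex, it identifies co-existing binding modes
(macrostates), attributes each mode's binding energy to residues by
computational alanine scanning, and contrasts natural-ligand vs inhibitor
profiles to nominate resistance-mutation hotspots. Because real trajectories
require an MD engine, the package carries a synthetic-data layer that
generates every input with known ground truth; all quantitative claims in the
test suite are claims about recovery of that ground truth, not about real
kinase simulations.

## Synthetic energy series

Hidden-state model. Frames carry a hidden macrostate following a first-order
Markov chain. Given target occupancies π and a dwell scale d̄ (frames), the
chain is built from the embedded jump chain J_ij = π_j/(1−π_i) (jump targets
weighted by occupancy) with per-state mean dwell d_i = d̄·π_i/φ_i, where φ is
the stationary distribution of J. This gives a stationary distribution
*exactly* equal to π, a visit-averaged dwell of d̄, and — in the
equal-occupancy case — diagonal elements exactly 1 − 1/d̄. A chain with exact
stationarity *and* a constant diagonal does not exist once any occupancy
exceeds ½ (the flow into the dominant state cannot exceed the mass of the
others), so dominant modes dwell proportionally longer here; that long
residence in the dominant mode is also what multi-replicate kinase series
display. Default d̄ = 50 frames (500 ps at the 10 ps frame interval), chosen
to give dozens of mode visits per 5000-frame replicate while keeping dwells
long enough to segment.

Emissions. Each state prescribes means and SDs for the four components (vdW,
electrostatics, GB polar, nonpolar) and an SD for the total. In end-point
rescoring the electrostatic and polar-solvation components compensate almost
exactly, so the total fluctuates far less than the quadrature sum of the
component SDs (for the bundled reference states, by factors of 2–9). The
generator therefore draws the total deviation t ~ N(0, σ_tot²) and distributes
it over components by Gaussian conditioning: independent component deviations
z_i ~ N(0, σ_i²) are shifted by (σ_i²/Σσ²)(t − Σz). Per-frame additivity
(total = exact component sum), component means, and the total mean/SD are
reproduced exactly; marginal component SDs come out below their nominal
values whenever σ_tot ≪ √Σσ² — the price of matching the observable the
segmentation actually sees. Treating components as independent instead would
inflate the total noise several-fold and make every mode separation
undetectable, contradicting the reference statistics themselves.

Bundled reference states (`data/reference_macrostates.csv`) list the
per-subpopulation occupancies and component statistics for four systems
(EGFR/ErbB2, active + ATP·2Mg²⁺·3H₂O, inactive + lapatinib·1H₂O). Two rows
whose printed component means do not sum to their printed total within the
table's 0.15 rounding band are flagged `consistent=False` and excluded from
additivity checks; their printed values are kept verbatim.

## Segmentation and macrostates

Change-point step. Each replicate's total-energy series is segmented by exact
penalized optimal partitioning under the Gaussian mean-shift cost
Σ_seg SSE(seg) + β·(#segments − 1), solved by an O(n²) vectorized dynamic
program (provably the global minimizer; cross-checked against a plain
exhaustive DP in the tests). The noise scale σ̂ is estimated per replicate
from the median absolute first difference (MAD/(0.6745√2)), which is
insensitive to level shifts. The automatic penalty is β = σ̂²·log n with
minimum segment length 20 frames. This is deliberately liberal — about a
third of the classical 3σ̂²·log n BIC choice — because the binding-mode
problem is detection-limited: adjacent modes in the reference systems sit
1.6–6 kcal/mol apart at within-mode SDs of 3–8 kcal/mol, and a stiffer
penalty silently fuses the two dominant modes (a ~25-point occupancy error),
while the spurious within-mode splits a liberal penalty admits are absorbed
by the clustering step. The penalty and minimum length were calibrated on
synthetic mixtures generated from the bundled reference states — the problem
class the package exists for — by measuring dominant-occupancy and
state-mean recovery across seeds.

Clustering. Segment means from all replicates are clustered in 1-D with a
length-weighted Gaussian kernel density whose per-segment bandwidth is
1.2·σ̂/√L — 1.2× the sampling SE of that segment's mean, i.e. the resolution
the data actually support. Macrostates are the basins between density minima;
modes whose pooled means lie closer than `merge_gap` (default 2.0 kcal/mol)
are merged, nearest pair first. Nearest-neighbour (single-linkage) merging
was rejected: with segment-mean clouds of SE ≈ 0.5 kcal/mol around modes
2.3 kcal/mol apart, the clouds overlap and single linkage chains across any
positive gap, collapsing exactly the mode pairs the method must resolve. The
merge gap sits below the smallest separation the reference table treats as
two modes (2.3 kcal/mol) and above the segment-mean noise; mode pairs closer
than it (1.6 kcal/mol in one system) are knowingly reported as one state.

Refinement. Clustering assigns whole segments, so a segment that straddles a
missed change point takes all its frames to one side, biasing occupancies by
several points. After clustering, the frame assignment is sharpened by an
iterated penalized step-fit: with the K mode levels μ_k and SDs σ_k fixed
from the clustered frames, each replicate is relabelled by the exact 1-D
Potts dynamic program minimizing Σ_t [(y_t−μ_{k_t})²/σ_{k_t}² + 2 ln σ_{k_t}]
+ 2·ln(d−1)·#switches (d re-estimated from the current label runs), then the
μ_k are re-estimated and the fit repeated to convergence (≤10 iterations).
The σ_k stay fixed at their initial estimates — re-estimating them lets a
contaminated wide state swallow its neighbours. The heteroscedastic deviance
matters: modes of unequal width get a likelihood-ratio boundary, not a
midpoint, which removes a 2–3-point drain from wide dominant modes. No
transition matrix or emission model is fitted and the number of states is
fixed by the clustering step; this is penalized least-squares step-fitting,
not hidden-Markov-model estimation. On reference-parameterized synthetic runs
the refinement brings the method error of the dominant-mode occupancy to
within ±2 points of the ground-truth (empirical) occupancy; the remaining
spread against the *nominal* occupancy is dominated by the finite number of
mode visits in 3 × 5000 frames (SD ≈ 2.5 points), an intrinsic property of
the prescribed study size.

## Energy engine

Single-trajectory end-point scheme: complex, receptor and ligand share
coordinates, so vdW and Coulomb binding terms reduce exactly to
cross-partition pair sums, while solvation terms are computed as
complex − receptor − ligand. Units: kcal/mol, Å, elementary charges;
k_e = 332.0636 kcal·Å/(mol·e²); no distance cutoffs (toy systems are small).

* Coulomb: internal dielectric 1.
* Lennard-Jones 12-6 with Lorentz–Berthelot combining from per-element σ/ε.
* GB polar: canonical pairwise form with the Still smoothing
  f_GB = √(r² + RᵢRⱼ exp(−r²/4RᵢRⱼ)), self terms included (f_GB(0) = Rᵢ),
  ε_in = 1, ε_out = 80. Born radii are fixed per element (H 1.2, C 1.7,
  N 1.55, O 1.5, P 1.85, S 1.8, Mg 1.45 Å) rather than computed by an
  effective-radii integration: at desk scale this preserves the functional
  behaviour (exact Born self-energy, 1/r long-range limit, pairwise
  decomposability — which also makes alanine-scan deltas strictly local)
  while staying deterministic and closed-form testable.
* Nonpolar: γ·SASA + β with γ = 0.0072 kcal/(mol·Å²), β = 0 (community
  defaults; configurable). SASA is a sphere-point (Shrake–Rupley style)
  quadrature on a deterministic golden-spiral lattice, default 256
  points/atom, probe 1.4 Å; doubling the lattice changes toy-complex totals
  by <0.5 %.
* Binding partition: ligand side = ligand + ions + designated key waters;
  bulk waters are excluded from scoring entirely. The assignment of key
  waters to the ligand side is a configurable interpretation (they are part
  of the "natural ligand" definition used throughout).

Water analysis: per-water crystallographic-style B = (8π²/3)⟨|r−⟨r⟩|²⟩ about
the time-mean position; key waters are those with B ≤ κ·median(protein-atom
B), κ = 1.25 — "comparable to the protein" with a small allowance — sorted by
increasing B. κ is uncritical on the generator's bimodal mobility
distributions (ordered waters sit ~100× below bulk).

## Alanine scanning

Truncation beyond Cβ (backbone N, CA, C, O, H plus CB and its hydrogens
kept), no re-minimization, no charge redistribution — the single-point
local-perturbation convention. Net charge may change for charged residues;
this is standard and documented rather than corrected. Proline is truncated
like any residue (with a warning); Gly/Ala are reported as ΔΔG = 0 with a
not-mutated flag. ΔΔG = ΔG_mut − ΔG_wt is averaged over every `stride`-th
snapshot of one macrostate (default stride: one snapshot per 10 ps). Waters
are stripped before scanning except the ligand-side key waters (kept by
default — they are part of the scored complex; a flag disables this).

## Interactions

Hydrogen bonds: donor-heavy–acceptor distance ≤ 3.5 Å and, when the donor has
an explicit hydrogen, D–H···A angle ≥ 135°; hydrogen-free structures (the toy
complexes) are scored on distance alone. Ion coordination: O/N atoms within
2.6 Å (closed interval) of the ion. Dihedrals: signed, (−180°, 180°],
positive clockwise viewed along the central bond (the convention of the major
trajectory-analysis tools). Rotamers: gauche+ (0°, 120°], gauche− (−120°, 0°],
trans otherwise — a total, deterministic partition; boundary values are
assigned by the half-open rule, not physical significance. 2-D KDE:
product-Gaussian kernel with per-axis Silverman bandwidth σ·n^(−1/6) on a
square grid padded 3 bandwidths beyond the data.

## Hotspot scoring

Profiles are per-residue binding-energy contributions (−ΔΔG; negative =
favourable). Normalization maps max(0, −x) to [0, 1] by the strongest
favourable contributor — the minimal scheme that puts both systems on a
common [0, 1] axis with the top contributor at 1; unfavourable contributions
floor at 0 rather than extending the axis. Candidates require
norm_inhibitor ≥ τ_inh = 0.25 and norm_atp ≤ τ_atp = 0.10 (no published
thresholds exist; both are configurable and recorded in output metadata).
Profiles default to the tightest macrostate — the mode that best represents
the productive bound state — with per-macrostate output available. The
literature benchmark ships as an editable text file of residue positions;
overlap significance is the hypergeometric tail probability of the observed
intersection given the scanned residue universe.

## Toy complexes

The generator builds a pocket of `n_residues` five-atom-backbone residues on
a sphere (radius 11 Å) around an eight-atom uniformly charged ligand ring,
optional Mg²⁺ ions each in a rigid octahedral cage of six oxygens at 2.1 Å
(key waters, dedicated ligand oxygens, and carboxylate-like oxygens of
designated acidic residues — the Asp-coordination motif), ordered key waters
within 4 Å of the ligand, and mobile bulk waters on an outer shell.
Designated contact residues point positively charged side-chain tips at the
ligand (~3.5 Å); all other side chains point outward with negligible charge.
Trajectories are the static pose plus per-entity isotropic Gaussian jitter
(protein 0.15, ligand 0.10, ion 0.05, key water 0.10, bulk water 1.0 Å);
placement is validated against a 1 Å hard-sphere minimum with bounded,
deterministic retries.

What this emulates — and does not. The toys exercise every contract of the
analysis stages: partition bookkeeping, locality of mutation deltas, B-factor
separation of ordered vs bulk water, coordination geometry, and the
construction-backed hotspot logic (inhibitor-only contacts are flagged,
shared and ATP-critical residues are not). They are noise-decorated static
poses: no conformational transitions, no force-field realism, no solvent
structure. Passing tests therefore demonstrate correctness of the analysis
machinery on known ground truth, not predictive accuracy on real kinases.

## Numerical choices and degenerate inputs

Frames are 0-based; segment intervals half-open [start, end); angles in
degrees wrapped to (−180°, 180°] (wrap maps −180° to +180°); energies
kcal/mol. Coincident atoms across a partition, non-positive Born radii,
sub-32-point SASA lattices, series shorter than twice the minimum segment
length, and empty ligand partitions raise typed errors. All-zero emission SDs
reproduce state means exactly; a zero-noise series segments to a single
segment. All randomness flows through `numpy.random.default_rng(seed)`;
identical config + seed gives byte-identical outputs, and every CSV artifact
carries a `# key: value` header with the seed and a config hash.

## Known limitations

* Modes separated by less than the merge gap (2 kcal/mol) are reported as one
  state; the reference systems contain one such pair by construction.
* Occupancy recovery at the default study size (3 × 5000 frames, dwell 50)
  carries an irreducible ±2–3-point sampling spread from the finite number of
  mode visits; single-seed comparisons inherit it.
* The GB term uses fixed Born radii: absolute solvation energies are not
  comparable to effective-radii implementations, only the functional
  behaviour is.
* Component SDs of the synthetic series understate their nominal values when
  the total SD is much smaller than their quadrature sum (see Emissions).
* The nonpolar term of an alanine mutant is recomputed from scratch (SASA is
  not pairwise-decomposable), so scan cost scales with residues × snapshots.
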