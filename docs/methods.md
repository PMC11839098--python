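# Methods

This note documents the models, conventions and numerical choices behind
`condensaxs`: a pipeline for (i) inferring conformational ensembles of short
single-stranded RNA from solution X-ray scattering and (ii) simulating and
quantifying the dynamics of RNA–peptide coacervate condensates at residue
resolution.

## 1. Suite-based chain building

Single-stranded RNA backbones occupy a discrete alphabet of dinucleotide
*suites*: combinations of the inter-residue torsions (ε, ζ of the 5′ residue;
α, β, γ of the 3′ residue), the two sugar puckers (δ and δ of the preceding
residue) and the two glycosidic angles (χ).  A 30-mer is assembled from 29
consecutive suites.  The shipped library (`data/suite_library.csv`) holds 34
suites named after the community suite nomenclature with **approximate
consensus torsion means**; the exact subset common to single-stranded RNA is
not uniquely established, so the table is an editable input, and every test of
the builder is a build→measure round trip rather than a comparison to an
external table.  The CSV carries 11 angle columns: the nine torsions plus two
sugar pseudorotation phases (`pucker_prev`, `pucker`) that drive ring closure.

Atoms are placed sequentially by natural-extension-reference-frame (NeRF)
geometry with idealized bond lengths and angles, so requested torsions are
reproduced exactly (measured round-trip error < 1e-12 degrees).  Conventions:

- Linkage *k* (0-based, between residues *k* and *k*+1) contributes ε/ζ to
  residue *k* and α/β/γ/δ/χ/pucker to residue *k*+1; the first suite's
  `*_prev` entries set residue 1.  γ of residue 1 is fixed at 54°
  (helical default) since no suite covers it.
- Sugar rings close approximately: the torsions placing C1′ and O4′ come from
  the pseudorotation phase (amplitude 38°), leaving a ring-closure error on
  O4′–C4′ of ≲ 0.15 Å for canonical puckers — irrelevant at the resolution of
  scattering and order-parameter analyses.
- Bases are rigid idealized planar templates (fused 5–6 ring for adenine,
  hexagon for pyrimidines) placed in the plane through C1′, the glycosidic N
  and the χ-reference atom, so χ is exact.
- Only A, U and C are supported; the systems of interest are homopolymers of
  these three nucleotides.

Pool sampling draws each linkage's suite independently from a probability
vector; chains with any non-bonded heavy-atom pair closer than 2.0 Å
(residues ≥ 2 apart) are repaired by resampling a random linkage between the
clashing residues, a local single-site move bounded by `max_retries` (500).
The 2.0 Å cutoff is a conservative van-der-Waals floor; it is configurable.

## 2. Scattering

Theoretical profiles use the Debye double sum with in-vacuo Cromer–Mann
atomic form factors (gemmi's IT92 tables) over heavy atoms; hydrogens are
omitted by default (negligible X-ray contribution).  No hydration shell or
excluded-volume correction is applied: all analyses in this package are
self-consistent synthetic loops, and absolute intensities therefore carry a
systematic offset against solvent-corrected programs when applied to real
data.  The default grid is 61 points to q = 0.3 Å⁻¹.  A phosphorus-only mode
computes profiles from backbone P atoms alone; it is used for reduced-size
iterative runs where only profile *shape differences* between pools matter.

Analyses:

- **Guinier**: log I = log I0 − (qRg)²/3 fitted on the largest low-q window
  with max(q)·Rg ≤ 1.3 (default), found by two fit→window refinement passes.
  For strongly extended chains the q·Rg ≤ 1.3 window biases Rg low by several
  percent (real curvature, not a bug); use a smaller limit there.
- **Flory fit**: the swollen-polymer form factor (generalized Debye function
  parameterized by ν and Rg through lower incomplete gamma functions), which
  reduces exactly to the Debye function at ν = 1/2 and decays as q^(−1/ν).
  Weighted least squares over (ν, Rg, I0), ν bounded to [0.25, 1.15].
- **χ²**: reduced over Q−1 with the scale factor μ minimized analytically
  (weighted least squares); additive offsets are never fitted.
- **Contrast match point**: I(0) — not √I(0) — is fitted linearly against
  buffer electron density and the zero crossing extrapolated.  The
  density↔sucrose map is linear, ρ(c) = 0.3344 + 0.0021·c (e/Å³ per % w/v),
  a documented configurable constant; non-monotonic input is flagged, not
  rejected.
- **Peak lengthscale**: d = 2π/q for a diffuse structure-factor peak.

## 3. Ensemble optimization

N ensembles of M conformers (defaults 50 × 20) are evolved for 1000
generations against the target: tournament selection (k = 2), single-point
crossover of member lists, mutation by resampling members uniformly from the
pool, and single-ensemble elitism — so the best χ² is non-increasing within
a run.  Repeat selections are allowed.  The configured "inner iterations"
(default 100) are independent restarts with the best run retained.  χ²_red is
the mean over the N final ensembles; a conformer's selection weight is its
frequency over all N·M slots.

The outer loop reweights the suite probabilities so the reweighted pool's
expected suite frequencies approach those observed in the selected ensembles:
the discrepancy is minimized over the probability simplex by SLSQP started
from the old weights, with the closed-form candidate
w ∝ w_old · h_ens / h_pool also evaluated and the better solution kept (the
result never scores worse than the starting point).  Convergence is declared
when the Jensen–Shannon divergence (natural log) between consecutive weight
vectors drops below 0.01 nats, or after `n_outer` (default 10) iterations.

## 4. Order parameters

The orientation correlation function is the mean cosine between normalized
bond vectors of consecutive backbone phosphorus atoms at each separation s;
l_OCF = b·Σ_{s=0}^{n_bonds−1} OCF(s) with b the mean P–P bond length.  This
convention (s = 0 included, mean-per-separation, one factor of b) makes a
rigid rod of n bonds give n·b and a delta-correlated chain give b; printed
l_OCF values from other conventions are comparable only qualitatively.

Base stacking: a total-least-squares plane is fitted to each base's ring
heavy atoms (smallest-eigenvector normal — rotation invariant, and for
near-planar rings indistinguishable from coordinate regression).  Two bases
stack when their plane centroids are ≤ 5 Å apart and the **acute** angle
between normals is ≤ 45°; "normals ≤ 5 Å apart" is interpreted as centroid
distance, normals being directions.  The percentage counts bases with at
least one partner (any partner by default; adjacency-restricted counting is
an option).

## 5. Coarse-grained simulation

One bead per nucleotide or amino acid.  Energy terms: harmonic bonds
E = Σ K(r−r_ref)² with K = 9.6 kJ/(mol Å²), r_ref = 5.00 Å (nucleic) and
3.81 Å (amino); Debye–Hückel screened Coulomb with ε_r = 80, 35 Å cutoff and
κ = √c_Na/3.06 Å⁻¹; Wang–Frenkel sticker wells (μ = 2, ν = 1, cutoff 3σ),
which are exactly zero at the cutoff and reach −ε at r ≈ 1.1σ.  Charges are
−1 e per nucleotide, +1 e for arginine, 0 for proline.

The pair table (`data/forcefield_synthetic.json`) is a **synthetic stand-in**
constructed for this package: its well depths preserve the orderings that
drive the biology (A–A π stacking deeper than U–U and C–C; strong
arginine–base cross terms; weak proline) with nucleotide σ = 6.0 Å chosen so
the base–base contact minimum (≈ 6.6 Å) falls inside the 7.5 Å clustering
cutoff.  Desk-scale condensation also needs wells of order 1–2 k_BT — deep
enough to coacervate within nanoseconds rather than the microseconds of
production runs.  The file is an editable input, not a re-derivation of any
published set.

Integration is BAOAB Langevin in units (Å, amu, kJ/mol; time unit 0.1 ps)
with friction γ = 1/τ, τ the relaxation time (100 ps for condensate runs,
5 ps where fast thermalization is wanted), dt = 10 fs, T = 298 K, seeded
noise, minimum-image periodic boundaries.  With γ = 0 the scheme reduces to
velocity Verlet and conserves energy (drift < 1% over 10⁵ steps at 1 fs on a
dimer).  A force component above 10⁵ kJ/(mol Å) aborts with the offending
step.

Initialization places chain centers on a cubic lattice (RNA first, then
peptide, deterministic order).  Straight-segment chains are staggered
laterally by 2.5 Å per z-layer when longer than the lattice spacing, and
rejected when longer than half the box (they would self-overlap through the
boundary); the `coil` conformation packs each chain as a compact serpentine
walk (bond-length grid pitch) and is the right choice when the box is much
smaller than a straight chain — i.e. in every desk-scale preset.  The PR
peptide alternates proline/arginine beads.

## 6. Condensate analytics

Chains are clustered per frame: linked when any inter-chain bead pair is
within 7.5 Å (1.5 × the nucleic bond length) under minimum image; clusters
are connected components, labelled canonically by lowest chain id.  An
RNA-only mode ignores peptide beads — the computational analogue of contrast
matching.  At desk scale the condensates are small enough that RNA strands
inside them are typically peptide-bridged at 8–10 Å separations, so the
pipeline identifies condensates from **all** chains and then projects the
timeline onto RNA strands for exchange counting; full-scale dense condensates
are where the RNA-only 7.5 Å criterion resolves clusters directly.

Exchange: adjacency matrices A_f (same-cluster indicator, unit diagonal) give
migration matrices M_f = A_{f+1} − A_f; positive entries are arrivals,
negative departures.  To avoid counting one chain's move once per partner, at
most one arrival and one departure are kept per row/column of each M, by a
deterministic greedy scan of the upper triangle in ascending row-then-column
order.  Scripted synthetic trajectories (membership prescribed per frame)
round-trip through this pipeline with exact event totals, which is the
correctness oracle.

Unwrapping makes each chain internally contiguous (minimum-image bond
folding) and then joins chains to the cluster through their nearest periodic
image; a cluster whose unwrapped extent reaches the box edge is flagged as
percolating (warning, not error).  Cluster identity over time follows maximal
membership overlap with the previous frame, ties to the lower id.

Shape: per-chain gyration tensor gives Rg, end-to-end distance, and the
relative shape anisotropy κ² = 1 − 3(λ₁λ₂+λ₂λ₃+λ₃λ₁)/(λ₁+λ₂+λ₃)² ∈ [0, 1]
(the standard gyration-tensor invariant with that symbol).  Condensate shape
persistence is the Jaccard volume overlap of convex hulls across frames,
estimated by seeded uniform Monte-Carlo sampling over the joint bounding box
(default 10⁵ samples; standard error scales as samples^(−1/2)); hulls can be
compared in place or after center-of-mass superposition.

## 7. Synthetic data: what it emulates and what it does not

The generators provide exact ground truth: parametric helices with
closed-form bond-orientation correlations, freely jointed chains with
⟨R²⟩ = n b², noisy profiles with Gaussian errors (proportional at 2% by
default — a synchrotron-like relative error — or constant), and scripted
cluster trajectories realized as bead geometries that reproduce the scripted
membership exactly under the 7.5 Å criterion.  They do not emulate detector
geometry, buffer-subtraction artifacts, inter-particle structure factors, or
radiation damage; a passing recovery test demonstrates the estimator is
correct and calibrated under its stated noise model, not that real
measurements satisfy that model.

## 8. Problem sizes and reproducibility

Default test and acceptance runs use scaled-down problem sizes chosen as this
package's desk-scale study conditions: conformer pools of 120–200 (20-mer
chains, phosphorus-only profiles for the iterative loop), GA runs of 600–800
generations with 1–2 restarts, and condensation runs of 12–18 chains of 15
beads in 70–90 Å boxes for 25–40 k steps of 10 fs.  The production-scale
settings (2000-conformer pools, 50×20 ensembles over 1000 generations and 100
restarts, 792.7 Å boxes, 1 μs trajectories) remain available through the same
configuration objects.  Every stochastic stage takes an explicit seed, and
repeated runs with equal seeds produce byte-identical outputs.

Suite-weight recovery on a reduced library reports the average of the final
weight vectors over three independent recovery runs: a single run's ranking of
five suites is dominated by genetic-algorithm sampling noise, which replicate
averaging suppresses.  The five-suite reduced library used in recovery studies
({1a, 3d, 1c, 2a, 8d}) was chosen by a max-diversity criterion on homo-suite
backbone profiles, restricted to clash-free suites, so that the inverse
problem is identifiable at phosphorus-only resolution.

Known limitations: vacuum form factors (systematic offset on real data);
approximate sugar-ring closure; a synthetic sticker table (directional
contrasts are meaningful, absolute energies are not); desk-scale condensation
is kinetically young — exchange statistics characterize forming condensates,
not steady-state droplets; and the suite library's torsion means are
approximate consensus values intended to be replaced by a curated table when
one is available.
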