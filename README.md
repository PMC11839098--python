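# condensaxs

Tools for studying the conformations and dynamics of short single-stranded
RNA as it associates with polybasic peptides and condenses into
ribonucleoprotein (RNP) coacervates.

Contrast-variation small-angle X-ray scattering (CV-SAXS) can blank out the
peptide component of an RNA–peptide mixture by raising the buffer electron
density (with sucrose) to the peptide's match point, leaving a scattering
profile of the RNA alone.  `condensaxs` implements the computational side of
such a study end to end:

- **Chain building** — all-atom single-stranded RNA conformers assembled from
  dinucleotide backbone *suites* (discrete torsion-angle rotamers); pools are
  sampled from a probability vector over a 34-suite library with steric
  rejection.
- **Scattering** — Debye-formula profiles I(q) = Σᵢⱼ fᵢfⱼ sin(qr)/(qr) from
  atomic coordinates, Guinier fits (log I = log I₀ − (qRg)²/3 for qRg < 1.3),
  the swollen-polymer molecular form factor giving the Flory exponent ν,
  reduced χ² with an analytic scale factor, Kratky transforms, I(0)
  extrapolation and fold changes, the contrast match point, and the diffuse
  peak lengthscale d = 2π/q.
- **Ensemble optimization** — a genetic algorithm selects sub-ensembles of M
  conformers whose averaged profile fits a target; an outer loop reweights
  the suite probabilities toward the frequencies observed in the selected
  ensembles, with Jensen–Shannon divergence as the convergence metric.
- **Order parameters** — orientation correlation functions of the phosphate
  backbone (oscillation ⇒ helicity), the summed correlation length l_OCF,
  and base-stacking percentages from fitted base planes (stacked: centroids
  ≤ 5 Å, normals within 45°).
- **Condensate simulation** — residue-level coarse-grained Langevin dynamics
  (one bead per nucleotide/amino acid) with harmonic bonds
  (K = 9.6 kJ mol⁻¹ Å⁻²), Debye–Hückel electrostatics (κ = √c_Na/3.06 Å⁻¹)
  and Wang–Frenkel sticker wells in a periodic box.
- **Condensate analytics** — chain-level clustering at 7.5 Å, periodic
  unwrapping, arrival/departure counting through migration matrices
  M_f = A_{f+1} − A_f, convex-hull Jaccard shape persistence, and per-chain
  Rg/R_EE/κ² from the gyration tensor.
- **Synthetic data** — helices and random coils with closed-form statistics,
  noisy profiles with known error laws, and scripted cluster trajectories,
  so every stage is testable with exact ground truth.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Recover a planted radius of gyration and Flory exponent from a synthetic
measurement, then run a desk-scale condensation:

```python
import numpy as np
from condensaxs import synth, saxs, cgsim, condensates

# --- dilute phase: profile analysis -----------------------------------
q = np.linspace(0.001, 0.3, 200)
truth = saxs.ScatteringProfile(q, 7.0 * np.exp(-(q * 23.25) ** 2 / 3))
noisy = synth.gen_noisy_profile(truth, synth.NoiseModel(sigma=0.02, seed=1))
g = saxs.guinier_fit(noisy)
print(f"Rg = {g.Rg:.2f} +/- {g.Rg_err:.2f} A, I(0) = {g.I0:.2f}")
# Rg = 23.19 +/- 0.22 A, I(0) = 7.00   (planted: 23.25 A, 7.0)

qm = np.linspace(0.005, 0.3, 61)
I = 7.0 * saxs.mff_curve(qm, 0.551, 23.25)
fit = saxs.mff_fit(saxs.ScatteringProfile(qm, I, 0.02 * I))
print(f"nu = {fit.nu:.3f}")
# nu = 0.551   (planted: 0.551; > 0.5 means good-solvent statistics)

# --- condensed phase: coacervation run --------------------------------
ff = cgsim.ForceField.load()          # synthetic sticker table, A > U wells
system = cgsim.init_lattice(6, 12, 15, 80.0, rna_type="U", conformation="coil")
cfg = cgsim.SimConfig(box_edge=80.0, n_steps=35000, relaxation_ps=100.0,
                      c_na=0.15, seed=0, save_stride=1000)
traj = cgsim.run_langevin(system, ff, cfg)
tl = condensates.build_timeline(traj, rna_only=False)
ev = condensates.migration_events(condensates.restrict_chains(tl, np.arange(6)))
print(f"kappa = {cgsim.kappa_from_salt(0.15):.4f} 1/A, "
      f"largest condensate = {max(tl.cluster_sizes(tl.n_frames - 1).values())} chains, "
      f"{ev.total_arrivals} RNA arrivals / {ev.total_departures} departures")
# kappa = 0.1266 1/A, largest condensate = 18 chains, 27 RNA arrivals / 22 departures
```

At 150 mM salt the 18 chains collapse into a single condensate within the
run; at 600 mM (κ = 0.253 Å⁻¹) screening weakens the peptide bridging and the
condensates stay smaller.

A thin CLI wraps the same functions:

```bash
condensaxs saxs guinier profile.dat
condensaxs sim --salt 0.15 --seed 3 --outdir run/
condensaxs eom --target profile.dat --sequence UUUU... --outer 4
condensaxs run --config run.json
```

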