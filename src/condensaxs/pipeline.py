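"""End-to-end orchestration of the two analysis arms.

The dilute-phase arm chains pool sampling -> theoretical scattering ->
genetic sub-ensemble selection -> suite reweighting -> structural order
parameters; the condensed-phase arm chains the coarse-grained Langevin
simulator -> cluster/exchange/shape analytics.  Every stochastic stage is
seeded from the run configuration, so a repeated run writes byte-identical
report tables.  Reports are a directory of CSV/JSON files plus a plain-text
summary; every number in the summary is computed by a stage whose output file
sits next to it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cgsim, condensates, eom, order_params, saxs
from .chains import SuiteWeights, load_suite_library
from .saxs import ScatteringProfile

logger = logging.getLogger("condensaxs.pipeline")

__all__ = ["RunConfig", "run_eom_arm", "run_sim_arm", "run"]

EXIT_OK, EXIT_VALIDATION, EXIT_STAGE = 0, 2, 3


@dataclass
class RunConfig:
    """Serializable configuration for one end-to-end run."""

    arm: str = "both"                      # eom | simulate | both
    sequence: str = "U" * 30
    target_profile: str | None = None      # path to 3-column text (eom arm)
    outdir: str = "condensaxs_run"
    seed: int = 0
    # dilute-phase (ensemble optimization) block
    pool_size: int = 200
    n_outer: int = 4
    ga: dict = field(default_factory=lambda: dict(
        n_generations=600, n_ensembles=40, curves_per_ensemble=15,
        mutations_per_ensemble=1, inner_iterations=1))
    scattering_atoms: str = "heavy"        # or "phosphorus" for reduced runs
    # condensed-phase (simulation) block
    salt: float = 0.15
    n_rna: int = 10
    n_peptide: int = 10
    beads_per_chain: int = 20
    box_edge: float = 110.0
    n_steps: int = 30_000
    relaxation_ps: float = 100.0
    save_stride: int = 500
    cluster_cutoff: float = condensates.DEFAULT_CUTOFF
    forcefield: str = "default"
    rna_type: str = "U"

    def validate(self) -> None:
        if self.arm not in ("eom", "simulate", "both"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.arm in ("eom", "both"):
            if not self.target_profile:
                raise ValueError("eom arm requires a target profile path")
            if not Path(self.target_profile).exists():
                raise ValueError(f"target profile {self.target_profile} not found")
        if self.salt < 0 or self.n_steps < 1:
            raise ValueError("invalid simulation block")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _ensemble_ocf(pool, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    curves = []
    for c in pool.conformers:
        r = order_params.ocf(c)
        curves.append(r.ocf)
    curves = np.array(curves)
    w = weights / weights.sum()
    return np.arange(curves.shape[1]), curves.T @ w


def run_eom_arm(cfg: RunConfig) -> dict:
    """Dilute-phase arm; returns the report dict (also written to outdir/eom)."""
    cfg.validate()
    out = Path(cfg.outdir) / "eom"
    out.mkdir(parents=True, exist_ok=True)
    target = ScatteringProfile.read(cfg.target_profile)
    if target.sigma is None or np.all(target.sigma == 0):
        target.sigma = 0.02 * np.abs(target.I)  # nominal 2% relative error
    library = load_suite_library()
    ga_cfg = eom.GAConfig(**cfg.ga, seed=cfg.seed)
    logger.info("eom arm: pool %d, %d outer iterations", cfg.pool_size, cfg.n_outer)
    pool, sel, trace = eom.iterate_eom(
        cfg.sequence, target, library, ga_cfg, n_outer=cfg.n_outer,
        seed=cfg.seed, pool_size=cfg.pool_size, atoms=cfg.scattering_atoms)

    model = eom.ensemble_average(
        [pool.profiles[k] for k in sel.members[sel.best_index]],
        np.full(sel.members.shape[1], 1.0 / sel.members.shape[1]))
    fit = saxs.chi_square(model, target)
    seps, ens_ocf = _ensemble_ocf(pool, sel.frequency)
    locf_vals = []
    stack_vals = []
    for c in pool.conformers:
        locf_vals.append(order_params.locf(order_params.ocf(c)))
        try:
            stack_vals.append(order_params.stacking_fraction(c).percent_stacked)
        except (KeyError, ValueError):
            stack_vals.append(np.nan)
    locf_mean, locf_sd = order_params.ensemble_weighted_metric(locf_vals, sel.frequency)
    stack = np.asarray(stack_vals)
    if np.all(np.isnan(stack)):
        stack_mean = stack_sd = float("nan")
    else:
        ok = ~np.isnan(stack)
        stack_mean, stack_sd = order_params.ensemble_weighted_metric(
            stack[ok], sel.frequency[ok])
    try:
        gres = saxs.guinier_fit(target)
        guinier = {"Rg": gres.Rg, "I0": gres.I0}
    except saxs.GuinierError as exc:
        guinier = {"error": str(exc)}
    try:
        mff = saxs.mff_fit(target)
        flory = {"nu": mff.nu, "Rg": mff.Rg}
    except RuntimeError as exc:
        flory = {"error": str(exc)}

    pd.DataFrame({"separation": seps, "ocf": ens_ocf}).to_csv(
        out / "ensemble_ocf.csv", index=False)
    pd.DataFrame({"q": target.q, "I_target": target.I, "sigma": target.sigma,
                  "I_model": fit.mu * np.interp(target.q, model.q, model.I)}
                 ).to_csv(out / "model_vs_target.csv", index=False)
    report = {
        "chi2_trace": trace.chi2_red,
        "jsd_trace": trace.jsd,
        "final_weights": trace.weights[-1].tolist(),
        "best_ensemble_chi2": float(sel.chi2.min()),
        "chi2_red": float(sel.chi2_red),
        "model_vs_target_chi2": fit.chi2,
        "locf_A": {"mean": locf_mean, "sd": locf_sd},
        "percent_stacked": {"mean": stack_mean, "sd": stack_sd},
        "guinier": guinier,
        "flory": flory,
        "files": ["ensemble_ocf.csv", "model_vs_target.csv"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def run_sim_arm(cfg: RunConfig) -> dict:
    """Condensed-phase arm; returns the report dict (also written to outdir/sim)."""
    cfg.validate()
    out = Path(cfg.outdir) / "sim"
    out.mkdir(parents=True, exist_ok=True)
    ff = cgsim.ForceField.load(cfg.forcefield)
    kappa = cgsim.kappa_from_salt(cfg.salt)
    sim_cfg = cgsim.SimConfig(box_edge=cfg.box_edge, n_steps=cfg.n_steps,
                              relaxation_ps=cfg.relaxation_ps, c_na=cfg.salt,
                              seed=cfg.seed, save_stride=cfg.save_stride)
    system = cgsim.init_lattice(cfg.n_rna, cfg.n_peptide, cfg.beads_per_chain,
                                cfg.box_edge, rna_type=cfg.rna_type,
                                conformation="coil")
    logger.info("sim arm: %d+%d chains, %d steps, kappa %.3f 1/A",
                cfg.n_rna, cfg.n_peptide, cfg.n_steps, kappa)
    traj = cgsim.run_langevin(system, ff, sim_cfg)
    traj.write_xyz(out / "trajectory.xyz")

    # condensates are identified from all chains; exchange events are counted
    # for RNA strands within them (the RNA-only 7.5 A clustering of the
    # full-scale analysis needs condensates much larger than the desk preset)
    timeline = condensates.build_timeline(traj, cutoff=cfg.cluster_cutoff,
                                          rna_only=False)
    rna_timeline = condensates.restrict_chains(timeline, np.arange(cfg.n_rna))
    events = condensates.migration_events(rna_timeline)
    tracks, n_per_frame, track_labels = condensates.cluster_growth_series(
        timeline, return_labels=True)

    rows = []
    for f in range(timeline.n_frames):
        sizes = timeline.cluster_sizes(f)
        rows.append({"frame": f, "time_ps": traj.times[f],
                     "n_clusters": len(sizes),
                     "largest": max(sizes.values()) if sizes else 0})
    pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)
    pd.DataFrame(
        [{"frame": f, "chain": c, "partner": p, "type": "arrival"}
         for f, c, p in events.arrivals] +
        [{"frame": f, "chain": c, "partner": p, "type": "departure"}
         for f, c, p in events.departures]).to_csv(out / "events.csv", index=False)

    # shape metrics of RNA chains in the last frame (unwrapped along the chain)
    shapes = []
    last = traj.frames[-1]
    for c in range(cfg.n_rna):
        p = last[traj.chain_ids == c].copy()
        steps = np.diff(p, axis=0)
        steps -= traj.box_edge * np.round(steps / traj.box_edge)
        p[1:] = p[0] + np.cumsum(steps, axis=0)
        s = condensates.chain_shape(p)
        shapes.append({"chain": c, "Rg": s.Rg, "REE": s.REE, "kappa2": s.kappa2})
    pd.DataFrame(shapes).to_csv(out / "chain_shapes.csv", index=False)

    # shape persistence of the largest tracked cluster (hull Jaccard, consecutive frames)
    jaccards = []
    biggest = max(tracks, key=lambda t: max(tracks[t].values())) if tracks else None
    if biggest is not None:
        frames_of = sorted(tracks[biggest])
        usable = [f for f in frames_of if tracks[biggest][f] >= 2]
        for f0, f1 in zip(usable[:-1], usable[1:]):
            try:
                lab0 = track_labels[biggest][f0]
                lab1 = track_labels[biggest][f1]
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    a = condensates.unwrap_clusters(traj, timeline, f0)[lab0]
                    b = condensates.unwrap_clusters(traj, timeline, f1)[lab1]
                jaccards.append(condensates.hull_jaccard(
                    a, b, n_samples=20_000, seed=cfg.seed, align_com=True))
            except (ValueError, KeyError):
                continue
    report = {
        "kappa_invA": kappa,
        "salt_M": cfg.salt,
        "arrivals": events.total_arrivals,
        "departures": events.total_departures,
        "largest_cluster_final": int(rows[-1]["largest"]),
        "n_clusters_final": int(rows[-1]["n_clusters"]),
        "mean_hull_jaccard": float(np.mean(jaccards)) if jaccards else None,
        "mean_final_kappa2": float(np.mean([s["kappa2"] for s in shapes])),
        "files": ["trajectory.xyz", "clusters.csv", "events.csv", "chain_shapes.csv"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def run(cfg: RunConfig) -> dict:
    """Execute the configured arm(s); returns {'eom': ..., 'sim': ...}."""
    cfg.validate()
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    cfg.to_json(Path(cfg.outdir) / "config.json")
    result = {}
    if cfg.arm in ("eom", "both"):
        result["eom"] = run_eom_arm(cfg)
    if cfg.arm in ("simulate", "both"):
        result["sim"] = run_sim_arm(cfg)
    summary = Path(cfg.outdir) / "summary.txt"
    lines = [f"condensaxs run (seed {cfg.seed})"]
    if "eom" in result:
        r = result["eom"]
        lines.append(f"  eom: best chi2 {r['best_ensemble_chi2']:.4g}, "
                     f"lOCF {r['locf_A']['mean']:.2f} A, "
                     f"stacked {r['percent_stacked']['mean']:.1f}%")
    if "sim" in result:
        r = result["sim"]
        lines.append(f"  sim: kappa {r['kappa_invA']:.3f} 1/A, "
                     f"{r['arrivals']} arrivals / {r['departures']} departures, "
                     f"largest cluster {r['largest_cluster_final']}")
    summary.write_text("\n".join(lines) + "\n")
    return result
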