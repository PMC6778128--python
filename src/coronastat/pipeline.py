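"""End-to-end orchestration: configuration in, AdsorptionReport out.

A declarative config (dict or YAML file) names the protein source, the
surface spec, the trajectory source and the analysis parameters; the
pipeline runs io → surface building → per-frame metrics → aggregation
in a fixed order and echoes every effective parameter into the report,
so identical config and inputs give identical reports.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .contacts import census_timeseries, contact_census
from .energetics import ForceFieldTable, energy_timeseries
from .flexibility import delta_rmsf, rmsf
from .model import ProteinStructure, System, Trajectory, select_window
from .moment import protein_mean_uH
from .sasa import csa_timeseries
from .secondary import assign_ss, delta_ss, ss_content
from .surfaces import SurfaceSpec, assemble_system, build_surface
from .synthetic import (make_adsorption_path, make_ideal_helix,
                        make_jitter_trajectory, make_toy_protein)

__all__ = ["AdsorptionReport", "run_analysis", "compare_systems",
           "ConfigError"]

log = logging.getLogger("coronastat")

_DEFAULT_ANALYSIS = {
    "window": "last:0.25",
    "contact_cutoff": 0.5,
    "energy_cutoff": 1.2,
    "probe": 0.14,
    "n_points": 960,
    "min_helix_len": 6,
    "active_site": None,
    "metrics": ["csa", "contacts", "energy", "ss", "uh"],
}


class ConfigError(ValueError):
    """Raised before any computation when the config does not validate."""


@dataclass
class AdsorptionReport:
    """Aggregated per-system analysis record.

    Every number is traceable to one module operation; ``parameters``
    echoes the full effective configuration including defaults.
    """

    system: dict
    parameters: dict
    csa: dict | None = None
    energy: dict | None = None
    census: dict | None = None
    ss: dict | None = None
    moment: dict | None = None
    rmsf_summary: dict | None = None

    def to_dict(self) -> dict:
        out = {"system": self.system, "parameters": self.parameters}
        for key in ("csa", "energy", "census", "ss", "moment", "rmsf_summary"):
            v = getattr(self, key)
            if v is not None:
                out[key] = v
        return out

    def rows(self) -> list[dict]:
        return [io_formats._flatten(self.to_dict())]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping or a YAML file path")
    return copy.deepcopy(config)


def _validate(cfg: dict) -> dict:
    for key in ("protein", "surface"):
        if key not in cfg:
            raise ConfigError(f"config missing required section {key!r}")
    analysis = dict(_DEFAULT_ANALYSIS)
    analysis.update(cfg.get("analysis", {}))
    unknown = set(analysis) - set(_DEFAULT_ANALYSIS)
    if unknown:
        raise ConfigError(f"unknown analysis keys {sorted(unknown)}")
    bad = set(analysis["metrics"]) - {"csa", "contacts", "energy", "ss", "uh",
                                      "rmsf"}
    if bad:
        raise ConfigError(f"unknown metrics {sorted(bad)}")
    cfg["analysis"] = analysis
    cfg.setdefault("assembly", {"gap": 1.0})
    cfg.setdefault("seed", 0)
    return cfg


def _make_protein(spec: dict) -> ProteinStructure:
    kind = spec.get("kind", "pdb")
    if kind == "pdb":
        if "path" not in spec:
            raise ConfigError("protein.kind=pdb requires protein.path")
        chains = spec.get("chain_filter")
        return io_formats.read_pdb(spec["path"],
                                   chain_filter=set(chains) if chains else None)
    if kind == "synthetic_helix":
        return make_ideal_helix(spec.get("sequence", "LKALEEKLKALEEKLKAL"))
    if kind == "synthetic_toy":
        return make_toy_protein(seed=spec.get("seed", 0))
    raise ConfigError(f"unknown protein.kind {kind!r}")


def _make_trajectory(cfg: dict, system: System) -> Trajectory | None:
    spec = cfg.get("trajectory")
    if spec is None:
        return None
    kind = spec.get("kind", "adsorption_path")
    if kind == "file":
        return io_formats.read_trajectory(spec["path"], system)
    if kind == "adsorption_path":
        return make_adsorption_path(
            system,
            start_gap=spec.get("start_gap", 1.0),
            end_gap=spec.get("end_gap", 0.25),
            n_steps=spec.get("n_steps", 16),
            jitter_sigma=spec.get("jitter_sigma", 0.0),
            seed=spec.get("seed", cfg["seed"]),
        )
    raise ConfigError(f"unknown trajectory.kind {kind!r}")


def _protein_frames(system: System, traj: Trajectory, window: str):
    work = system.protein.copy()
    for k in select_window(len(traj), window):
        p, _ = system.split_frame(traj.frames[k])
        work.set_coords(p)
        yield work


def run_analysis(config) -> AdsorptionReport:
    """Execute the full analysis described by a config.

    Stages run in fixed order (inputs → surface → per-frame metrics →
    aggregation); stage timings go to the ``coronastat`` logger and
    every effective parameter is echoed into the report.
    """
    cfg = _validate(_load_config(config))
    ana = cfg["analysis"]
    t0 = time.perf_counter()

    protein = _make_protein(cfg["protein"])
    spec = SurfaceSpec(**cfg["surface"])
    surface = build_surface(spec)
    system = assemble_system(protein, surface, gap=cfg["assembly"].get("gap", 1.0))
    traj = _make_trajectory(cfg, system)
    log.info("setup done in %.2fs (%d protein atoms, %d surface atoms)",
             time.perf_counter() - t0, len(protein), len(surface))

    surf_meta = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()}
    report = AdsorptionReport(
        system={"protein_source": protein.source, "surface": surf_meta,
                "n_frames": None if traj is None else len(traj)},
        parameters={**ana, "gap": cfg["assembly"].get("gap", 1.0),
                    "seed": cfg["seed"]},
    )
    metrics = ana["metrics"]
    window = ana["window"]

    if "csa" in metrics:
        t = time.perf_counter()
        if traj is not None:
            mean, sem, _ = csa_timeseries(traj, system, window,
                                          ana["probe"], ana["n_points"])
        else:
            from .sasa import compute_csa
            v = compute_csa(system, probe=ana["probe"], n_points=ana["n_points"])
            mean, sem = v.value, 0.0
        report.csa = {"mean_nm2": mean, "sem_nm2": sem}
        log.info("csa in %.2fs", time.perf_counter() - t)

    if "contacts" in metrics:
        if traj is not None:
            means, sems = census_timeseries(traj, system,
                                            ana["contact_cutoff"], window)
            final = contact_census(system, traj.frames[-1],
                                   ana["contact_cutoff"])
        else:
            final = contact_census(system, cutoff=ana["contact_cutoff"])
            means = {**{k: float(v) for k, v in final.counts.items()},
                     "total": float(final.total)}
            sems = {k: 0.0 for k in means}
        report.census = {"mean": means, "sem": sems,
                         "final_frame": {**final.counts, "total": final.total}}

    if "energy" in metrics:
        ff = ForceFieldTable.default()
        if traj is not None:
            e = energy_timeseries(traj, system, ff, ana["energy_cutoff"], window)
        else:
            from .energetics import interaction_energy
            d = interaction_energy(system, ff=ff, cutoff=ana["energy_cutoff"])
            e = {"lj": (d.lj, 0.0), "coulomb": (d.coulomb, 0.0)}
        report.energy = {
            "lj_kJmol": e["lj"][0], "lj_sem": e["lj"][1],
            "coulomb_kJmol": e["coulomb"][0], "coulomb_sem": e["coulomb"][1],
        }

    free_assignment = assign_ss(protein)
    if "ss" in metrics:
        free = ss_content(free_assignment)
        entry = {"free": free.as_dict()}
        if traj is not None:
            acc = np.zeros(4)
            count = 0
            for work in _protein_frames(system, traj, window):
                c = ss_content(assign_ss(work))
                acc += [c.helix, c.sheet, c.turn, c.coil]
                count += 1
            from .secondary import SSContent
            adsorbed = SSContent(*(acc / count))
            entry["adsorbed"] = adsorbed.as_dict()
            entry["delta_free_minus_adsorbed"] = delta_ss(free, adsorbed)
        report.ss = entry

    if "uh" in metrics:
        try:
            m = protein_mean_uH(protein, free_assignment,
                                min_helix_len=ana["min_helix_len"])
            report.moment = {
                "mean_uH": m.mean_uH,
                "mean_uH_length_weighted": m.mean_uH_weighted,
                "n_helices": len(m.per_helix),
                "homogeneous": bool(m.amphipathic_flag),
            }
        except ValueError as exc:
            report.moment = {"error": str(exc)}

    if "rmsf" in metrics:
        free_spec = cfg.get("free_trajectory", {})
        sigma = free_spec.get("sigma", 0.02)
        n_frames = free_spec.get("n_frames", 50)
        fseed = free_spec.get("seed", cfg["seed"] + 1)
        free_traj = make_jitter_trajectory(
            protein, sigma, n_frames, seed=fseed
        )
        if traj is None:
            raise ConfigError("rmsf metric needs a trajectory")
        idx = select_window(len(traj), window)
        pframes = [system.split_frame(traj.frames[k])[0] for k in idx]
        if len(pframes) < 2:
            pframes = [system.split_frame(f)[0] for f in traj.frames]
        ads_traj = Trajectory(protein, pframes)
        span = ana["active_site"]
        if span is None:
            rs = [r.res_seq for r in protein.residues()]
            span = (min(rs), max(rs))
        summary = delta_rmsf(rmsf(ads_traj), rmsf(free_traj),
                             active_site=tuple(span))
        report.rmsf_summary = {
            "active_site": list(summary.active_site_span),
            "n_positive": summary.n_positive,
            "n_negative": summary.n_negative,
            "n_zero": summary.n_zero,
            "verdict": summary.verdict,
            "mean_delta_nm": float(summary.delta.mean()),
        }

    log.info("analysis complete in %.2fs", time.perf_counter() - t0)
    return report


def compare_systems(configs: list) -> pd.DataFrame:
    """Run several configs and tabulate per-metric comparisons.

    One row per system; for each scalar metric a rank column is added
    (1 = largest) with ties flagged when the values' s.e.m. intervals
    overlap.
    """
    if len(configs) < 2:
        raise ConfigError("compare_systems needs at least 2 configs")
    rows = []
    for cfg in configs:
        rep = run_analysis(cfg)
        flat = io_formats._flatten(rep.to_dict())
        rows.append(flat)
    df = pd.DataFrame(rows)
    for metric, sem_col in (("csa.mean_nm2", "csa.sem_nm2"),
                            ("energy.lj_kJmol", "energy.lj_sem")):
        if metric in df:
            vals = df[metric].astype(float)
            df[metric + ".rank"] = vals.rank(ascending=False, method="min")
            if sem_col in df:
                sem = df[sem_col].astype(float)
                lo, hi = vals - sem, vals + sem
                tie = [
                    any((lo[i] <= hi[j]) and (lo[j] <= hi[i])
                        for j in range(len(df)) if j != i)
                    for i in range(len(df))
                ]
                df[metric + ".tie"] = tie
    return df
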