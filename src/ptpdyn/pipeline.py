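"""Run configuration and stage orchestration.

A run is declared in a single YAML config (paths, loop definitions,
thresholds, seeds); stages execute in dependency order and every stage writes
its outputs plus a provenance record (config digest, seed, package version),
so a rerun with identical config and seed is bit-identical for deterministic
stages.  The pipeline never mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import ptpdyn
from ptpdyn import synthetic
from ptpdyn.correlation import compute_dccm
from ptpdyn.ensemble import LoopDefinition, load_structure
from ptpdyn.evb import anova_tukey, barrier_stats, fep_increments, gap_profile
from ptpdyn.loops import (
    anchor_point,
    build_landscape,
    build_reference,
    classify_states,
    compute_com_distance,
    compute_drmsd,
    compute_rmsf,
    default_reactive_criteria,
    reactive_fraction,
)
from ptpdyn.plan import SimulationPlan, plan_accounting
from ptpdyn.spm import build_graph, mean_ca_distance_matrix, shortest_path_map
from ptpdyn.variants import VariantTable, classify_vs_spm, hotspot_positions

STAGE_ORDER = ["plan", "synth", "metrics", "landscape", "rmsf", "dccm", "spm", "variants", "evb", "stats"]

DEFAULT_THRESHOLDS = {
    "contact_cutoff": 6.0,
    "usage_threshold": 0.3,
    "hotspot_cutoff": 4.0,
    "histogram_bins": 50,
    "reactive_asp_cutoff": 4.5,
    "reactive_gln_cutoff": 8.0,
}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    inputs: dict = field(default_factory=dict)      # named paths
    loops: dict = field(default_factory=dict)       # name -> [start, stop]
    thresholds: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    evb: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for key, value in self.thresholds.items():
            if not isinstance(value, (int, float)) or value <= 0:
                raise ConfigError(f"threshold {key!r} must be a positive number")
        for name, path in self.inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"input {name!r}: path {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        return cls(
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            inputs=raw.get("inputs", {}) or {},
            loops=raw.get("loops", {}) or {},
            thresholds=raw.get("thresholds", {}) or {},
            synth=raw.get("synth", {}) or {},
            evb=raw.get("evb", {}) or {},
            raw=raw,
        )

    def digest(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.raw.items()} or {"out_dir": str(self.out_dir), "seed": self.seed},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def loop(self, name: str) -> LoopDefinition:
        if name not in self.loops:
            raise ConfigError(f"loop {name!r} not defined in config")
        start, stop = self.loops[name]
        return LoopDefinition.from_range(name, int(start), int(stop))


def _provenance(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": ptpdyn.__version__,
    }


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig, stages=None) -> dict[str, dict]:
    """Execute the requested stages in dependency order.

    ``stages=None`` runs everything applicable; an empty collection validates
    the config and returns without outputs.  Returns a dict of per-stage
    result summaries.  A stage whose upstream artifact is missing raises a
    dependency error naming the stage.
    """
    if stages is None:
        requested = list(STAGE_ORDER)
    else:
        requested = [s for s in STAGE_ORDER if s in set(stages)]
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    results: dict[str, dict] = {}
    if not requested:
        return results
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}

    def need(name: str, stage: str):
        if name in artifacts:
            return artifacts[name]
        raise ConfigError(f"stage {stage!r}: missing upstream artifact {name!r}")

    for stage in requested:
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)

        if stage == "plan":
            if "plan_csv" not in config.inputs:
                raise ConfigError("stage 'plan': config input plan_csv required")
            plan = SimulationPlan.from_csv(config.inputs["plan_csv"])
            acc = plan_accounting(plan)
            payload = {
                "per_entry": {k: float(v) for k, v in acc["per_entry"].items()},
                "cumulative_us": acc["cumulative_us"],
                "provenance": _provenance(config, stage),
            }
            _write_json(stage_dir / "accounting.json", payload)
            results[stage] = payload

        elif stage == "synth":
            s = config.synth
            n_res = int(s.get("n_residues", 12))
            sep = float(s.get("open_shift", 6.0))
            closed = np.column_stack(
                [np.linspace(0, 3.8 * (n_res - 1), n_res), np.zeros(n_res), np.zeros(n_res)]
            )
            # displace only the first (WPD) half of the chain: a rigid shift
            # of the whole loop set is invisible to internal-distance metrics
            open_ = closed.copy()
            open_[: n_res // 2, 1] += sep
            spec = synthetic.TwoStateLoopSpec(
                open_coordinates=open_,
                closed_coordinates=closed,
                occupancy_closed=float(s.get("occupancy_closed", 0.7)),
                mean_dwell=float(s.get("mean_dwell", 50)),
                jitter_sd=float(s.get("jitter_sd", 0.3)),
                n_frames=int(s.get("n_frames", 5000)),
                seed=config.seed,
            )
            ens, labels = synthetic.gen_two_state_loop(spec)
            ens.to_npz(stage_dir / "two_state.npz")
            pd.DataFrame({"frame": np.arange(len(labels)), "state": labels}).to_csv(
                stage_dir / "true_states.csv", index=False, lineterminator="\n"
            )
            table = synthetic.gen_variant_table(
                seed=config.seed, n_positions=int(s.get("n_variant_positions", 20))
            )
            table.to_csv(stage_dir / "variants.csv")
            evb_cfg = config.evb
            hspec = synthetic.HarmonicDiabatSpec(
                k_force=float(evb_cfg.get("k_force", 100.0)),
                x1=float(evb_cfg.get("x1", 0.0)),
                x2=float(evb_cfg.get("x2", 1.0)),
                dG0=float(evb_cfg.get("dG0", -2.0)),
                H12=float(evb_cfg.get("H12", 1.0)),
                temperature=float(evb_cfg.get("temperature", 300.0)),
                lambdas=np.linspace(0, 1, int(evb_cfg.get("n_windows", 51))),
                frames_per_window=int(evb_cfg.get("frames_per_window", 2000)),
                seed=config.seed + 1,
            )
            series = synthetic.gen_evb_windows(hspec)
            series.to_csv(stage_dir / "evb_windows.csv")
            artifacts["ensemble"] = ens
            artifacts["labels"] = labels
            artifacts["spec"] = spec
            artifacts["variant_table"] = table
            artifacts["evb_series"] = series
            artifacts["evb_spec"] = hspec
            payload = {"n_frames": ens.n_frames, "provenance": _provenance(config, stage)}
            _write_json(stage_dir / "summary.json", payload)
            results[stage] = payload

        elif stage in ("metrics", "landscape"):
            ens = artifacts.get("ensemble")
            if ens is None:
                if "trajectory" not in config.inputs:
                    raise ConfigError(f"stage {stage!r}: missing upstream artifact 'ensemble'")
                ens = load_structure(config.inputs["trajectory"])
                artifacts["ensemble"] = ens
            spec = artifacts.get("spec")
            n_res = ens.n_atoms
            half = n_res // 2
            wpd = (
                config.loop("WPD")
                if "WPD" in config.loops
                else LoopDefinition.from_range("WPD", 1, half)
            )
            ploop = (
                config.loop("P")
                if "P" in config.loops
                else LoopDefinition.from_range("P", half + 1, n_res)
            )
            if spec is not None:
                from ptpdyn.ensemble import ensemble_from_arrays

                ref_closed = ensemble_from_arrays(
                    spec.closed_coordinates, res_ids=np.arange(1, n_res + 1)
                )
                ref_open = ensemble_from_arrays(
                    spec.open_coordinates, res_ids=np.arange(1, n_res + 1)
                )
            else:
                ref_closed = load_structure(config.inputs["reference_closed"])
                ref_open = load_structure(config.inputs["reference_open"])
            ref = build_reference(ref_closed, wpd, ploop, source="closed reference")
            drmsd = compute_drmsd(ens, ref)
            com = compute_com_distance(ens, wpd, ploop)
            anchors = {
                "closed": anchor_point(ref_closed, ref, wpd, ploop),
                "open": anchor_point(ref_open, ref, wpd, ploop),
            }
            states = classify_states(drmsd, com, anchors)
            pd.DataFrame(
                {"frame": np.arange(len(drmsd)), "drmsd": drmsd, "com_distance": com, "state": states}
            ).to_csv(stage_dir / "metrics.csv", index=False, lineterminator="\n")
            hist = build_landscape(
                drmsd, com, bins=int(config.thresholds["histogram_bins"]), anchors=anchors
            )
            hist.to_dataframe().to_csv(stage_dir / "landscape.csv", index=False, lineterminator="\n")
            payload = {
                "n_frames": int(hist.n_frames),
                "closed_fraction": float(np.mean(states == "closed")),
                "anchors": {k: list(map(float, v)) for k, v in anchors.items()},
                "provenance": _provenance(config, stage),
            }
            _write_json(stage_dir / "summary.json", payload)
            artifacts["states"] = states
            results[stage] = payload

        elif stage == "rmsf":
            ens = need("ensemble", stage)
            profile = compute_rmsf(ens)
            pd.DataFrame({"res_id": profile.residue_ids, "rmsf": profile.values}).to_csv(
                stage_dir / "rmsf.csv", index=False, lineterminator="\n"
            )
            payload = {
                "mean_rmsf": float(profile.values.mean()),
                "provenance": _provenance(config, stage),
            }
            _write_json(stage_dir / "summary.json", payload)
            results[stage] = payload

        elif stage == "dccm":
            ens = need("ensemble", stage)
            cmap = compute_dccm(ens)
            cmap.to_csv(stage_dir / "dccm.csv")
            artifacts["dccm"] = cmap
            payload = {
                "n_residues": len(cmap.residue_ids),
                "provenance": _provenance(config, stage),
            }
            _write_json(stage_dir / "summary.json", payload)
            results[stage] = payload

        elif stage == "spm":
            cmap = need("dccm", stage)
            ens = need("ensemble", stage)
            dmat, _ = mean_ca_distance_matrix(ens, cmap.residue_ids)
            graph = build_graph(cmap, dmat, contact_cutoff=config.thresholds["contact_cutoff"])
            spm = shortest_path_map(graph, usage_threshold=config.thresholds["usage_threshold"])
            spm.to_dataframe().to_csv(stage_dir / "spm_edges.csv", index=False, lineterminator="\n")
            (stage_dir / "spm_residues.txt").write_text(
                "\n".join(str(r) for r in sorted(spm.spm_residues)) + "\n"
            )
            artifacts["spm"] = spm
            payload = {
                "n_edges": len(graph.edges),
                "n_spm_residues": len(spm.spm_residues),
                "provenance": _provenance(config, stage),
            }
            _write_json(stage_dir / "summary.json", payload)
            results[stage] = payload

        elif stage == "variants":
            table = artifacts.get("variant_table")
            if table is None:
                if "variants_csv" not in config.inputs:
                    raise ConfigError("stage 'variants': missing upstream artifact 'variant_table'")
                table = VariantTable.from_csv(config.inputs["variants_csv"])
            spm = need("spm", stage)
            ens = need("ensemble", stage)
            hotspots = hotspot_positions(table)
            # restrict to positions the structure can resolve
            resolvable = hotspots & set(ens.atoms["res_id"].astype(int).tolist())
            classification = classify_vs_spm(
                sorted(resolvable) if resolvable else sorted(hotspots),
                spm.spm_residues,
                ens,
                cutoff=config.thresholds["hotspot_cutoff"],
            )
            classification.to_csv(stage_dir / "hotspots.csv")
            payload = {
                "n_hotspots": len(hotspots),
                "n_classified": int(len(classification.table)),
                "provenance": _provenance(config, stage),
            }
            _write_json(stage_dir / "summary.json", payload)
            results[stage] = payload

        elif stage == "evb":
            series = artifacts.get("evb_series")
            if series is None:
                from ptpdyn.evb import EVBWindowSeries

                if "evb_csv" not in config.inputs:
                    raise ConfigError("stage 'evb': missing upstream artifact 'evb_series'")
                series = EVBWindowSeries.from_csv(
                    config.inputs["evb_csv"],
                    h12=float(config.evb.get("H12", 0.0)),
                    temperature=float(config.evb.get("temperature", 300.0)),
                )
            dg = fep_increments(series)
            profile = gap_profile(series, dg)
            profile.to_dataframe().to_csv(stage_dir / "profile.csv", index=False, lineterminator="\n")
            payload = {
                "dg_act": profile.dg_act,
                "dg_rxn": profile.dg_rxn,
                "provenance": _provenance(config, stage),
            }
            _write_json(stage_dir / "summary.json", payload)
            artifacts["profile"] = profile
            results[stage] = payload

        elif stage == "stats":
            if "barriers_csv" in config.inputs:
                df = pd.read_csv(config.inputs["barriers_csv"])
                replicates = {
                    str(s): g["dg_act"].tolist() for s, g in df.groupby("system")
                }
            else:
                raise ConfigError("stage 'stats': config input barriers_csv required")
            stats_df = barrier_stats(replicates)
            res = anova_tukey(replicates)
            stats_df.to_csv(stage_dir / "barrier_stats.csv", lineterminator="\n")
            res.pairwise.to_csv(stage_dir / "tukey.csv", index=False, lineterminator="\n")
            payload = {
                "anova_F": res.f_statistic,
                "anova_p": res.p_value,
                "provenance": _provenance(config, stage),
            }
            _write_json(stage_dir / "summary.json", payload)
            results[stage] = payload

    return results
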