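"""End-to-end pipeline runs: config, stage orchestration and manifests.

A run is described by one YAML config (paths, copy numbers, PCA grid,
stability threshold, FBA options, seed, output directory).  Stages execute
in dependency order; every output directory gets a ``manifest.json``
recording the seed, a config hash, and per-stage status and outputs, so a
run is reproducible and auditable.  A failed stage marks downstream stages
skipped and the run failed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from calorimix import io as cio
from calorimix.calorimetry import baseline_and_integrate, segment_phases
from calorimix.community import abundance_table, reconstruct_strain_heat, strain_growth_rates_in_consortium
from calorimix.fba import depletion_screen, fba, fva, sample_fluxes
from calorimix.fixtures import FIXTURE_TRUTH, SCENARIOS, generate_fixtures
from calorimix.gems import builtin_gem, load_gem
from calorimix.metabolites import compare_consortium_vs_stack, concentration_deltas, replicate_deltas
from calorimix.stability import assemble_passage_matrix, assess_resilience, detect_stable_passage, pca_scores

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("calorimix")

STAGES = ("fixtures", "kinetics", "composition", "stability", "resilience", "metabolites", "fba")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIOS))
    copy_numbers: dict[str, int] = field(default_factory=lambda: dict(FIXTURE_TRUTH["copy_numbers"]))
    grid: dict = field(default_factory=lambda: {"start": 0.0, "stop": 24.0, "step": 0.1})
    stability_k: float = 1.5
    fba_options: dict = field(default_factory=lambda: {"model": "builtin:am_like", "fraction": 0.9, "n_samples": 200})
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc, base=Path(path).parent)

    @classmethod
    def from_dict(cls, doc: dict, base: Path = Path(".")) -> "RunConfig":
        if "outdir" not in doc:
            raise ValueError("config must set 'outdir'")
        cfg = cls(
            outdir=(base / doc["outdir"]).resolve(),
            seed=int(doc.get("seed", 0)),
            stages=list(doc.get("stages", STAGES)),
            scenarios=list(doc.get("scenarios", SCENARIOS)),
            copy_numbers={k: int(v) for k, v in doc.get("copy_numbers", FIXTURE_TRUTH["copy_numbers"]).items()},
            grid=dict(doc.get("grid", {"start": 0.0, "stop": 24.0, "step": 0.1})),
            stability_k=float(doc.get("stability_k", 1.5)),
            fba_options={**{"model": "builtin:am_like", "fraction": 0.9, "n_samples": 200}, **doc.get("fba", {})},
            inputs={k: (base / v) for k, v in doc.get("inputs", {}).items()},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)} (valid: {STAGES})")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ValueError(f"input {key!r}: no such file {path}")
        model = self.fba_options.get("model", "")
        if not str(model).startswith("builtin:") and not Path(model).exists():
            raise ValueError(f"FBA model file not found: {model}")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def grid_values(self) -> np.ndarray:
        g = self.grid
        return np.arange(g["start"], g["stop"] + 1e-9, g["step"])


def _heatflow_path(cfg: RunConfig, name: str) -> Path:
    if name in cfg.inputs:
        return Path(cfg.inputs[name])
    return cfg.outdir / "fixtures" / name


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
        "ok": True,
    }
    failed = False
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        entry = {"status": "skipped (upstream failure)"} if failed else None
        if entry is None:
            t0 = time.time()
            try:
                outputs = _STAGE_FUNCS[stage](cfg)
                entry = {"status": "ok", "outputs": outputs, "wall_s": round(time.time() - t0, 2)}
                log.info("stage %s ok (%.1fs)", stage, time.time() - t0)
            except Exception as exc:  # noqa: BLE001 - manifest records any stage failure
                entry = {"status": "failed", "error": str(exc), "wall_s": round(time.time() - t0, 2)}
                log.error("stage %s failed: %s", stage, exc)
                failed = True
                manifest["ok"] = False
        manifest["stages"][stage] = entry
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_fixtures(cfg: RunConfig) -> list[str]:
    out = []
    for scenario in cfg.scenarios:
        written = generate_fixtures(scenario, seed=cfg.seed, outdir=cfg.outdir / "fixtures")
        out += [str(p) for p in written]
    return out


def _kinetics_condition_files(cfg: RunConfig) -> dict[str, Path]:
    files = {}
    for cond, fname in (
        ("am", "monoculture_am_heatflow.csv"),
        ("bt", "monoculture_bt_heatflow.csv"),
        ("fp", "monoculture_fp_heatflow.csv"),
        ("consortium", "consortium_heatflow.csv"),
    ):
        p = _heatflow_path(cfg, fname)
        if p.exists():
            files[cond] = p
    if not files:
        raise FileNotFoundError("no heat-flow inputs found; run the fixtures stage or set inputs")
    return files


def _stage_kinetics(cfg: RunConfig) -> list[str]:
    rows = []
    outputs = []
    for cond, path in _kinetics_condition_files(cfg).items():
        series = cio.read_heatflow_csv(path)
        last_passage = max(s.passage for s in series)
        for s in series:
            if s.passage != last_passage:
                continue
            curve = baseline_and_integrate(s, baseline_window=0.0)
            for i, ph in enumerate(segment_phases(curve, max_phases=3), start=1):
                rows.append(
                    {
                        "condition": cond,
                        "replicate": s.replicate,
                        "passage": s.passage,
                        "phase": i,
                        "t_start_h": ph.t_start,
                        "t_end_h": ph.t_end,
                        "mu_per_h": ph.mu,
                        "r2": ph.fit_r2,
                    }
                )
    out = cfg.outdir / "kinetics_phases.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.6g")
    outputs.append(str(out))
    return outputs


def _stage_composition(cfg: RunConfig) -> list[str]:
    ab_path = cfg.inputs.get("abundance", cfg.outdir / "fixtures" / "consortium_abundance.tsv")
    hf_path = _heatflow_path(cfg, "consortium_heatflow.csv")
    reads = cio.read_abundance_tsv(ab_path)
    ab = abundance_table(reads, cfg.copy_numbers)
    series = [s for s in cio.read_heatflow_csv(hf_path)]
    last = max(s.passage for s in series)
    ref = next(s for s in series if s.passage == last and s.replicate == "r2")
    curve = baseline_and_integrate(ref, baseline_window=0.0)
    per = reconstruct_strain_heat(curve, ab)
    dt = float(np.median(np.diff(curve.time)))
    win = max(3, int(round(1.5 / dt)) | 1)
    phases = strain_growth_rates_in_consortium(per, max_phases=3, smooth_window=win, min_points=win)
    rows = []
    for strain, pl in phases.items():
        for i, ph in enumerate(pl, start=1):
            rows.append(
                {"strain": strain, "phase": i, "t_start_h": ph.t_start, "t_end_h": ph.t_end,
                 "mu_per_h": ph.mu, "r2": ph.fit_r2}
            )
    out1 = cfg.outdir / "composition_fractions.csv"
    ab.to_csv(out1, index=False, float_format="%.6g")
    out2 = cfg.outdir / "consortium_strain_phases.csv"
    pd.DataFrame(rows).to_csv(out2, index=False, float_format="%.6g")
    return [str(out1), str(out2)]


def _stability_report_json(report, pca) -> dict:
    return {
        "passages_to_stability": report.passages_to_stability,
        "reached": report.reached,
        "d_w": report.d_w,
        "k": report.k,
        "centroids": {str(p): [float(x) for x in c] for p, c in report.centroids.items()},
        "shifts": {f"{a}->{b}": v for (a, b), v in report.shifts.items()},
        "explained_variance_ratio": [float(x) for x in pca.explained_variance_ratio[:2]],
    }


def _stage_stability(cfg: RunConfig) -> list[str]:
    grid = cfg.grid_values()
    outputs = []
    results = {}
    for cond in ("consortium", "am", "bt", "fp"):
        p = _heatflow_path(cfg, f"stability_{cond}_heatflow.csv")
        if not p.exists():
            continue
        series = cio.read_heatflow_csv(p)
        mat = assemble_passage_matrix(series, grid)
        pca = pca_scores(mat)
        report = detect_stable_passage(pca.scores, mat.passages, k=cfg.stability_k)
        results[cond] = _stability_report_json(report, pca)
        scores = pd.DataFrame(
            {"passage": mat.passages, "replicate": mat.replicates,
             "pc1": pca.scores[:, 0], "pc2": pca.scores[:, 1]}
        )
        sp = cfg.outdir / f"stability_{cond}_scores.csv"
        scores.to_csv(sp, index=False, float_format="%.6g")
        outputs.append(str(sp))
    if not results:
        raise FileNotFoundError("no stability heat-flow inputs found")
    out = cfg.outdir / "stability_report.json"
    out.write_text(json.dumps(results, indent=2, sort_keys=True))
    outputs.append(str(out))
    return outputs


def _stage_resilience(cfg: RunConfig) -> list[str]:
    grid = cfg.grid_values()
    results = {}
    for scen in ("resilience_am", "resilience_bt", "resilience_fp"):
        ref_p = _heatflow_path(cfg, f"{scen}_reference_heatflow.csv")
        pert_p = _heatflow_path(cfg, f"{scen}_perturbed_heatflow.csv")
        if not (ref_p.exists() and pert_p.exists()):
            continue
        ref_mat = assemble_passage_matrix(cio.read_heatflow_csv(ref_p), grid)
        pca = pca_scores(ref_mat)
        report = detect_stable_passage(pca.scores, ref_mat.passages, k=cfg.stability_k)
        pert_mat = assemble_passage_matrix(cio.read_heatflow_csv(pert_p), grid)
        res = assess_resilience(pert_mat, pca, report)
        results[scen] = {
            "recovery_passage": res.recovery_passage,
            "recovered": res.recovered,
            "distances": {str(p): d for p, d in res.distances.items()},
            "threshold": res.threshold,
            "reference_stable_passage": report.passages_to_stability,
        }
    if not results:
        raise FileNotFoundError("no resilience heat-flow inputs found")
    out = cfg.outdir / "resilience_report.json"
    out.write_text(json.dumps(results, indent=2, sort_keys=True))
    return [str(out)]


def _stage_metabolites(cfg: RunConfig) -> list[str]:
    fixdir = cfg.outdir / "fixtures"
    mono = {}
    for cond in ("monoculture_am", "monoculture_bt", "monoculture_fp"):
        p = cfg.inputs.get(f"{cond}_metabolites", fixdir / f"{cond}_metabolites.csv")
        if Path(p).exists():
            mono[cond] = replicate_deltas(cio.read_metabolite_csv(p))
    cons_p = cfg.inputs.get("consortium_metabolites", fixdir / "consortium_metabolites.csv")
    if not mono or not Path(cons_p).exists():
        raise FileNotFoundError("need monoculture and consortium metabolite tables")
    cons_tbl = cio.read_metabolite_csv(cons_p)
    cons = replicate_deltas(cons_tbl)
    comparison = compare_consortium_vs_stack(mono, cons)
    out1 = cfg.outdir / "metabolite_comparison.csv"
    comparison.to_csv(out1, index=False, float_format="%.6g")
    deltas = concentration_deltas(cons_tbl)
    out2 = cfg.outdir / "consortium_deltas.csv"
    deltas.to_csv(out2, index=False, float_format="%.6g")
    return [str(out1), str(out2)]


def _stage_fba(cfg: RunConfig) -> list[str]:
    opts = cfg.fba_options
    model_ref = str(opts["model"])
    if model_ref.startswith("builtin:"):
        gem = builtin_gem(model_ref.removeprefix("builtin:"))
    else:
        gem = load_gem(model_ref)
    sol = fba(gem)
    result = {
        "model": gem.model_id,
        "status": sol.status,
        "mu_pred": sol.objective_value,
    }
    screen = depletion_screen(gem)
    out1 = cfg.outdir / "fba_depletion_screen.csv"
    screen.to_csv(out1, index=False, float_format="%.6g")
    ranges = fva(gem, fraction=float(opts["fraction"]))
    out2 = cfg.outdir / "fba_fva.csv"
    ranges.to_csv(out2, index=False, float_format="%.6g")
    sampled = sample_fluxes(gem, n=int(opts["n_samples"]), fraction=float(opts["fraction"]), seed=cfg.seed)
    out3 = cfg.outdir / "fba_sampled_fluxes.csv"
    sampled.to_csv(out3, index=False, float_format="%.6g")
    out4 = cfg.outdir / "fba_summary.json"
    out4.write_text(json.dumps(result, indent=2, sort_keys=True))
    return [str(out1), str(out2), str(out3), str(out4)]


_STAGE_FUNCS = {
    "fixtures": _stage_fixtures,
    "kinetics": _stage_kinetics,
    "composition": _stage_composition,
    "stability": _stage_stability,
    "resilience": _stage_resilience,
    "metabolites": _stage_metabolites,
    "fba": _stage_fba,
}
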