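"""Packaged study fixtures: parameter sets, design truths and file generation.

The fixtures encode a three-strain gut consortium study design:
*A. muciniphila* (AM), *B. thetaiotaomicron* (BT) and *F. prausnitzii* (FP)
grown in 2 mL IMC ampoules on a synthetic mucin-containing medium, passaged
daily at 1% v/v with three replicate ampoule lineages per condition.

Ground truths (growth-phase rates and their SDs, 16S copy numbers, the
final consortium composition, passages-to-stability per condition and the
resilience recovery ordering) are taken from published monoculture and
consortium measurements of this consortium; everything else (pool sizes,
yields, heat yields, noise levels) is the study design of this package and
is documented in the methods note.

Replicates are three persistent lineages with small deterministic rate
offsets (parallel passage series of the same stock differ reproducibly),
plus seed-controlled additive instrument noise.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from calorimix import io as cio
from calorimix.calorimetry import HeatFlowSeries
from calorimix.params import AdaptationSchedule, CommunityParams, load_community_yaml
from calorimix.simulate import (
    SimulationResult,
    add_measurement_noise,
    endpoint_metabolites,
    sample_reads,
    simulate_serial_passages,
)

__all__ = [
    "FIXTURE_TRUTH",
    "SCENARIOS",
    "community_params",
    "lineage_community",
    "simulate_condition",
    "generate_fixtures",
]

#: Ground truths and design constants for the packaged fixtures.
FIXTURE_TRUTH = {
    # phase-specific growth rates (h^-1) with reported SDs, monocultures
    "phases": {
        "AM": [(0.57, 0.02)],
        "BT": [(0.88, 0.06), (0.20, 0.01), (0.07, 0.002)],
        "FP": [(1.00, 0.08), (0.21, 0.01), (0.09, 0.004)],
    },
    "copy_numbers": {"AM": 3, "BT": 5, "FP": 6},
    # final consortium composition (fraction, SD) as reported for the
    # biological consortium; the simulator's own steady state differs
    "composition": {"BT": (0.52, 0.02), "AM": (0.34, 0.02), "FP": (0.13, 0.01)},
    # passages to stability per condition (PCA criterion)
    "stability_passages": {"consortium": 3, "am": 4, "bt": 2, "fp": 2},
    # designed heat-flow recovery passages of the 100x under-inoculation runs
    "resilience_recovery": {"resilience_am": 5, "resilience_bt": 4, "resilience_fp": 3},
    # design constants
    "n_replicates": 3,
    "n_passages": 7,
    "duration_h": 24.0,
    "lineage_spread": {"am": 0.014, "bt": 0.015, "fp": 0.015, "consortium": 0.015},
    "drift": {  # initial (mu multiplier, lag multiplier) of the adaptation schedule
        "am": (0.70, 10.0),
        "bt": (0.93, 3.0),
        "fp": (0.85, 5.0),
        "consortium": (0.85, 5.0),
    },
    "noise_frac_of_peak": 5e-4,
    "read_depth": 100_000,
    "metabolite_noise_mM": 0.1,
}

_CONDITION_YAML = {
    "am": "monoculture_am.yaml",
    "bt": "monoculture_bt.yaml",
    "fp": "monoculture_fp.yaml",
    "consortium": "consortium.yaml",
}

SCENARIOS = (
    "monoculture_am",
    "monoculture_bt",
    "monoculture_fp",
    "consortium",
    "resilience_am",
    "resilience_bt",
    "resilience_fp",
    "stability_suite",
)


def community_params(condition: str) -> CommunityParams:
    """Load the packaged parameter set for a condition (am/bt/fp/consortium)."""
    if condition not in _CONDITION_YAML:
        raise ValueError(f"unknown condition {condition!r}; choose from {sorted(_CONDITION_YAML)}")
    ref = resources.files("calorimix.data") / _CONDITION_YAML[condition]
    with resources.as_file(ref) as path:
        return load_community_yaml(path)


def lineage_community(params: CommunityParams, factor: float) -> CommunityParams:
    """A replicate lineage: all maximum rates scaled by a small factor."""
    strains = [
        dc_replace(s, mu_max={k: v * factor for k, v in s.mu_max.items()}) for s in params.strains
    ]
    return dc_replace(params, strains=strains)


def _with_drift(params: CommunityParams, condition: str) -> CommunityParams:
    mu0, lag0 = FIXTURE_TRUTH["drift"][condition]
    conv = FIXTURE_TRUTH["stability_passages"][condition]
    names = params.strain_names
    sched = AdaptationSchedule(
        lag_multiplier={n: lag0 for n in names},
        mu_multiplier={n: mu0 for n in names},
        convergence_passage=conv,
    )
    return dc_replace(params, adaptation=sched)


def simulate_condition(
    condition: str,
    seed: int | None = None,
    n_passages: int | None = None,
    dt: float = 0.05,
    drift: bool = False,
    per_strain_dilution: dict[str, float] | None = None,
    noise: bool = True,
) -> tuple[list[HeatFlowSeries], list[list[SimulationResult]]]:
    """Simulate one condition across its three replicate lineages.

    Returns the (optionally noisy) heat-flow series for every ampoule and
    the underlying simulation results grouped by lineage.
    """
    truth = FIXTURE_TRUTH
    n_passages = n_passages or truth["n_passages"]
    spread = truth["lineage_spread"][condition]
    base = community_params(condition)
    if drift:
        base = _with_drift(base, condition)
    rng = np.random.default_rng(seed)
    runs_by_lineage = []
    peak = 0.0
    for factor in (1.0 - spread, 1.0, 1.0 + spread):
        comm = lineage_community(base, factor)
        runs = simulate_serial_passages(
            comm,
            n_passages,
            per_strain_dilution=per_strain_dilution,
            duration=truth["duration_h"],
            dt=dt,
        )
        runs_by_lineage.append(runs)
        peak = max(peak, max(r.total_heat_flow.max() for r in runs))
    series = []
    sd = truth["noise_frac_of_peak"] * peak if noise else 0.0
    for rep, runs in enumerate(runs_by_lineage, start=1):
        for r in runs:
            s = r.heat_flow_series(replicate=f"r{rep}", condition=condition)
            series.append(add_measurement_noise(s, sd=sd, seed=rng) if noise else s)
    return series, runs_by_lineage


def hourly_abundance_reads(
    result: SimulationResult, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Hourly 16S read counts over one passage (long table: time_h, strain, reads)."""
    rng = np.random.default_rng(seed)
    copies = [FIXTURE_TRUTH["copy_numbers"][s] for s in result.strain_names]
    rows = []
    for th in range(int(result.time[-1]) + 1):
        i = int(np.searchsorted(result.time, th))
        b = result.biomass[:, i]
        fr = b / b.sum()
        reads = sample_reads(fr, copies, FIXTURE_TRUTH["read_depth"], rng)
        rows += [(float(th), s, int(rd)) for s, rd in zip(result.strain_names, reads)]
    return pd.DataFrame(rows, columns=["time_h", "strain", "reads"])


def endpoint_composition_reads(
    runs: list[SimulationResult], seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """End-of-passage 16S reads per passage (columns: passage, strain, reads)."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in runs:
        fr = r.final_fractions()
        copies = [FIXTURE_TRUTH["copy_numbers"][s] for s in r.strain_names]
        reads = sample_reads([fr[s] for s in r.strain_names], copies, FIXTURE_TRUTH["read_depth"], rng)
        rows += [(r.passage, s, int(rd)) for s, rd in zip(r.strain_names, reads)]
    return pd.DataFrame(rows, columns=["passage", "strain", "reads"])


def generate_fixtures(scenario: str, seed: int = 0, outdir: str | Path = ".") -> list[Path]:
    """Write a scenario's input files (heat flow, reads, metabolites) to disk."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {', '.join(SCENARIOS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    def emit_heatflow(series, name):
        p = outdir / name
        cio.write_heatflow_csv(series, p)
        written.append(p)

    if scenario.startswith("monoculture_"):
        cond = scenario.removeprefix("monoculture_")
        series, runs = simulate_condition(cond, seed=int(rng.integers(2**31)), dt=0.02, noise=False)
        emit_heatflow(series, f"{scenario}_heatflow.csv")
        met = endpoint_metabolites(
            runs[1][-1],
            noise_sd=FIXTURE_TRUTH["metabolite_noise_mM"],
            n_replicates=FIXTURE_TRUTH["n_replicates"],
            seed=rng,
            sample=scenario,
        )
        p = outdir / f"{scenario}_metabolites.csv"
        cio.write_metabolite_csv(met, p)
        written.append(p)
    elif scenario == "consortium":
        series, runs = simulate_condition("consortium", seed=int(rng.integers(2**31)), dt=0.02, noise=False)
        emit_heatflow(series, "consortium_heatflow.csv")
        reads = hourly_abundance_reads(runs[1][-1], seed=rng)
        p = outdir / "consortium_abundance.tsv"
        cio.write_abundance_tsv(reads, p)
        written.append(p)
        met = endpoint_metabolites(
            runs[1][-1],
            noise_sd=FIXTURE_TRUTH["metabolite_noise_mM"],
            n_replicates=FIXTURE_TRUTH["n_replicates"],
            seed=rng,
            sample="consortium",
        )
        p = outdir / "consortium_metabolites.csv"
        cio.write_metabolite_csv(met, p)
        written.append(p)
    elif scenario.startswith("resilience_"):
        victim = scenario.removeprefix("resilience_").upper()
        ref_series, _ = simulate_condition("consortium", seed=int(rng.integers(2**31)))
        pert_series, pert_runs = simulate_condition(
            "consortium", seed=int(rng.integers(2**31)), per_strain_dilution={victim: 0.01}
        )
        for s in ref_series:
            s.condition = "reference"
        for s in pert_series:
            s.condition = scenario
        emit_heatflow(ref_series, f"{scenario}_reference_heatflow.csv")
        emit_heatflow(pert_series, f"{scenario}_perturbed_heatflow.csv")
        comp = endpoint_composition_reads(pert_runs[1], seed=rng)
        p = outdir / f"{scenario}_composition.tsv"
        comp.to_csv(p, sep="\t", index=False)
        written.append(p)
    elif scenario == "stability_suite":
        for cond in ("consortium", "am", "bt", "fp"):
            series, _ = simulate_condition(cond, seed=int(rng.integers(2**31)), drift=True)
            emit_heatflow(series, f"stability_{cond}_heatflow.csv")
    return written
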