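"""Synthetic consortium simulator.

Batch growth of a multi-strain community on a shared metabolite pool is
modelled as a consumer-resource ODE with Monod kinetics:

    dX_i/dt = mu_i(S) * X_i            (after the strain's lag time)
    mu_i(S) = sum_k mu_max_ik * S_k / (K_ik + S_k),  capped at max_k mu_max_ik
    dS_k/dt = - sum_i r_ik * X_i / yield_X_ik
    dP_j/dt = + sum_ik yield_P_ikj * (r_ik * X_i / yield_X_ik)

where ``r_ik`` is substrate k's (cap-rescaled) contribution to strain i's
growth rate.  Products live in the same concentration pool as substrates, so
cross-feeding (e.g. acetate produced by one strain and consumed by another)
emerges without special casing.

Heat release is growth-associated only: strain i's heat flow is
``Y_Q,i * dX_i/dt`` scaled to the ampoule volume, and its cumulative heat is
exactly ``Y_Q,i * (X_i(t) - X_i(0)) * V`` — the linear heat–biomass
relationship that justifies calorimetric growth-rate estimation.

Serial passaging transfers a fixed volume fraction (default 1% v/v) of the
culture into fresh medium; a per-strain dilution at passage 1 reproduces
under-inoculation (resilience) designs.  Read sampling, endpoint metabolite
tables and measurement noise provide the observation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from calorimix.calorimetry import HeatFlowSeries
from calorimix.params import CommunityParams, StrainParams

__all__ = [
    "SimulationResult",
    "simulate_batch",
    "simulate_serial_passages",
    "sample_reads",
    "endpoint_metabolites",
    "add_measurement_noise",
]

SECONDS_PER_HOUR = 3600.0


class IntegrationFailure(RuntimeError):
    """Raised when the ODE state becomes non-finite."""


@dataclass
class SimulationResult:
    """Trajectories of one batch (one passage) of a community culture.

    Attributes
    ----------
    time:
        Time grid, h.
    strain_names, metabolite_names:
        Row labels for ``biomass`` and ``concentrations``.
    biomass:
        Per-strain biomass, gDW/L, shape (n_strains, n_time).
    concentrations:
        Metabolite concentrations, mmol/L, shape (n_metabolites, n_time).
    heat_flow:
        Per-strain heat flow, W per ampoule, shape (n_strains, n_time).
    cumulative_heat:
        Per-strain cumulative heat, J per ampoule, same shape.
    passage:
        1-based passage index this batch belongs to.
    """

    time: np.ndarray
    strain_names: list[str]
    metabolite_names: list[str]
    biomass: np.ndarray
    concentrations: np.ndarray
    heat_flow: np.ndarray
    cumulative_heat: np.ndarray
    passage: int = 1

    @property
    def total_heat_flow(self) -> np.ndarray:
        return self.heat_flow.sum(axis=0)

    @property
    def total_cumulative_heat(self) -> np.ndarray:
        return self.cumulative_heat.sum(axis=0)

    def final_biomass(self) -> dict[str, float]:
        return {n: float(b) for n, b in zip(self.strain_names, self.biomass[:, -1])}

    def final_fractions(self) -> dict[str, float]:
        end = self.biomass[:, -1]
        total = end.sum()
        if total <= 0:
            raise ValueError("no biomass at end of simulation")
        return {n: float(b / total) for n, b in zip(self.strain_names, end)}

    def concentration(self, name: str) -> np.ndarray:
        return self.concentrations[self.metabolite_names.index(name)]

    def heat_flow_series(
        self, replicate: str = "r1", condition: str = "sim", total: bool = True, strain: str | None = None
    ) -> HeatFlowSeries:
        """Package (total or per-strain) heat flow as a HeatFlowSeries."""
        if strain is not None:
            power = self.heat_flow[self.strain_names.index(strain)]
        elif total:
            power = self.total_heat_flow
        else:
            raise ValueError("need total=True or a strain name")
        return HeatFlowSeries(
            time=self.time.copy(),
            power=np.asarray(power, dtype=float).copy(),
            replicate=replicate,
            passage=self.passage,
            condition=condition,
        )


def _growth_rates(strain: StrainParams, conc: dict[str, float]) -> dict[str, float]:
    """Cap-rescaled per-substrate growth-rate contributions r_ik (h^-1)."""
    rates = {}
    for sub, mu in strain.mu_max.items():
        s = max(conc.get(sub, 0.0), 0.0)
        if s > 0.0 and mu > 0.0:
            rates[sub] = mu * s / (strain.K[sub] + s)
    total = sum(rates.values())
    cap = strain.mu_cap
    if total > cap > 0.0:
        scale = cap / total
        rates = {k: v * scale for k, v in rates.items()}
    return rates


def simulate_batch(
    params: CommunityParams,
    duration: float = 24.0,
    dt: float = 0.01,
    seed: int | None = None,
    initial_biomass: dict[str, float] | None = None,
    passage: int = 1,
    rtol: float = 1e-8,
) -> SimulationResult:
    """Integrate one batch culture and return trajectories on a regular grid.

    ``seed`` is accepted for interface uniformity; the batch ODE itself is
    deterministic.  ``initial_biomass`` overrides the community default (used
    by the passaging loop).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")

    strains = params.strains
    mets = params.metabolite_names()
    n_s, n_m = len(strains), len(mets)
    met_idx = {m: i for i, m in enumerate(mets)}

    x0 = initial_biomass if initial_biomass is not None else params.initial_biomass
    y0 = np.zeros(n_s + n_m)
    for i, s in enumerate(strains):
        y0[i] = x0.get(s.name, 0.0)
    for m, c0 in params.substrates.items():
        y0[n_s + met_idx[m]] = c0

    # Pre-index substrate/product couplings for the RHS.
    couplings = []
    for i, s in enumerate(strains):
        subs = []
        for sub in s.mu_max:
            prods = [(met_idx[p], y) for p, y in s.yield_P.get(sub, {}).items()]
            subs.append((sub, met_idx[sub], s.yield_X[sub], prods))
        couplings.append((i, s, subs))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        conc = {m: y[n_s + j] for m, j in met_idx.items()}
        for i, s, subs in couplings:
            if t < s.lag_h:
                continue
            x = y[i]
            if x <= 0.0:
                continue
            rates = _growth_rates(s, conc)
            if not rates:
                continue
            dy[i] = sum(rates.values()) * x
            for sub, j, yx, prods in subs:
                r = rates.get(sub)
                if r is None:
                    continue
                uptake = r * x / yx  # mmol/L/h
                dy[n_s + j] -= uptake
                for jp, yp in prods:
                    dy[n_s + jp] += yp * uptake
        return dy

    n_steps = int(math.floor(duration / dt + 1e-9))
    t_grid = np.arange(n_steps + 1) * dt
    t_grid[-1] = min(t_grid[-1], duration)
    # Integrate in segments split at lag times so the RHS is smooth per segment.
    lag_times = sorted({s.lag_h for s in strains if 0.0 < s.lag_h < duration})
    bounds = [0.0, *lag_times, duration]
    t = t_grid
    ys = np.empty((y0.size, t.size))
    y = y0.copy()
    for a, b in zip(bounds[:-1], bounds[1:]):
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", dense_output=True, rtol=rtol, atol=1e-12)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            bad = np.where(~np.isfinite(sol.y).all(axis=0))[0]
            t_bad = sol.t[bad[0]] if bad.size else b
            raise IntegrationFailure(f"non-finite state first at t = {t_bad:.4f} h")
        mask = (t >= a - 1e-12) & (t <= b + 1e-12)
        if np.any(mask):
            ys[:, mask] = sol.sol(np.clip(t[mask], a, b))
        y = sol.y[:, -1]

    biomass = np.clip(ys[:n_s], 0.0, None)
    conc = np.clip(ys[n_s:], 0.0, None)

    vol = params.ampoule_volume_L
    heat_flow = np.zeros((n_s, t.size))
    for j in range(t.size):
        dy = rhs(t[j], ys[:, j])
        heat_flow[:, j] = [strains[i].heat_yield * dy[i] * vol / SECONDS_PER_HOUR for i in range(n_s)]
    cum_heat = np.array(
        [strains[i].heat_yield * (biomass[i] - biomass[i, 0]) * vol for i in range(n_s)]
    )

    return SimulationResult(
        time=t,
        strain_names=[s.name for s in strains],
        metabolite_names=mets,
        biomass=biomass,
        concentrations=conc,
        heat_flow=heat_flow,
        cumulative_heat=cum_heat,
        passage=passage,
    )


def simulate_serial_passages(
    params: CommunityParams,
    n_passages: int,
    per_strain_dilution: dict[str, float] | None = None,
    seed: int | None = None,
    duration: float = 24.0,
    dt: float = 0.01,
) -> list[SimulationResult]:
    """Simulate ``n_passages`` serial batches with 1% v/v transfers.

    ``per_strain_dilution`` multiplies the passage-1 inoculum of named strains
    only (e.g. ``{"AM": 0.01}`` under-inoculates *A. muciniphila* 100-fold, the
    resilience design).  The inoculum of passage p+1 is ``transfer_fraction``
    times the end-of-passage-p biomass; substrates are fresh each passage.
    An adaptation schedule, when present, drifts lag times and maximum rates
    toward their asymptotes passage by passage.
    """
    if n_passages < 1:
        raise ValueError("n_passages must be >= 1")
    dilution = per_strain_dilution or {}
    unknown = set(dilution) - set(params.strain_names)
    if unknown:
        raise ValueError(f"per_strain_dilution names unknown strains: {sorted(unknown)}")

    inoculum = {
        n: params.initial_biomass.get(n, 0.0) * dilution.get(n, 1.0) for n in params.strain_names
    }
    results = []
    for p in range(1, n_passages + 1):
        if params.adaptation is not None:
            strains_p = [params.adaptation.apply(s, p) for s in params.strains]
            params_p = dc_replace(params, strains=strains_p, adaptation=None)
        else:
            params_p = params
        res = simulate_batch(params_p, duration=duration, dt=dt, initial_biomass=inoculum, passage=p)
        results.append(res)
        end = res.final_biomass()
        inoculum = {n: params.transfer_fraction * end[n] for n in params.strain_names}
    return results


def sample_reads(
    biomass_fractions,
    copy_numbers,
    depth: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw 16S amplicon read counts for a known community composition.

    Reads are multinomial with probabilities proportional to
    ``fraction_i * copy_number_i``: sequencing sees gene copies, not cells,
    so strains with more 16S copies are over-represented and downstream
    analysis must divide them back out.
    """
    f = np.asarray(biomass_fractions, dtype=float)
    c = np.asarray(copy_numbers, dtype=float)
    if f.shape != c.shape:
        raise ValueError("fractions and copy numbers must have the same length")
    if np.any(f < 0):
        raise ValueError("fractions must be >= 0")
    if not math.isclose(f.sum(), 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"fractions must sum to 1, got {f.sum():.6f}")
    if np.any(c < 1):
        raise ValueError("copy numbers must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    p = f * c
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, p)


def endpoint_metabolites(
    result: SimulationResult,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator | None = None,
    sample: str = "sim",
    metabolites: list[str] | None = None,
) -> pd.DataFrame:
    """Emulate endpoint metabolite quantification (HPLC/UPLC-style tables).

    Returns a long-format table with columns ``sample, replicate, metabolite,
    timepoint, conc_mM``; start/end concentrations are the simulation's first
    and last grid points plus additive Gaussian noise truncated at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    names = metabolites if metabolites is not None else result.metabolite_names
    rows = []
    for m in names:
        traj = result.concentration(m)
        for tp, conc in (("start", traj[0]), ("end", traj[-1])):
            for r in range(1, n_replicates + 1):
                val = conc + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((sample, f"r{r}", m, tp, max(val, 0.0)))
    return pd.DataFrame(rows, columns=["sample", "replicate", "metabolite", "timepoint", "conc_mM"])


def add_measurement_noise(
    series: HeatFlowSeries,
    sd: float = 0.0,
    drift: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> HeatFlowSeries:
    """Additive Gaussian noise (W) plus a linear baseline drift (W/h)."""
    if not (math.isfinite(sd) and math.isfinite(drift)):
        raise ValueError("sd and drift must be finite")
    rng = np.random.default_rng(seed)
    power = series.power + drift * series.time
    if sd > 0:
        power = power + rng.normal(0.0, sd, size=series.power.shape)
    return dc_replace(series, power=power)
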