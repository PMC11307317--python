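"""Flux balance analysis and derived screens on GEMs.

All operations solve linear programs over the steady-state flux polytope
{v : S v = 0, lb <= v <= ub}:

- :func:`fba` maximizes the biomass objective c^T v and returns one optimal
  vertex with the optimum mu_pred (h^-1 when the objective is biomass);
- :func:`apply_measured_constraints` narrows exchange bounds to measured
  uptake/production rates (mmol gDW^-1 h^-1, negative = consumption);
- :func:`depletion_screen` zeroes one substrate's uptake at a time and
  classifies it essential / limiting / dispensable by the re-solved optimum;
- :func:`fva` reports per-reaction flux ranges at a fraction of the optimum;
- :func:`sample_fluxes` summarizes the near-optimal polytope by optimizing
  random objective directions (uniform on the unit sphere) and reporting
  per-reaction vertex means and SDs.

Because optima are often degenerate, only objective values, FVA intervals
and sampled statistics are stable quantities; the specific optimal vertex is
solver-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from calorimix.gems import GEM

__all__ = [
    "FluxResult",
    "ExchangeRate",
    "fba",
    "apply_measured_constraints",
    "depletion_screen",
    "fva",
    "sample_fluxes",
]

#: Predicted growth below this is treated as no growth.
ESSENTIALITY_TOL = 1e-6
#: "Limiting" when growth drops below this fraction of the reference optimum.
LIMITING_FRACTION = 0.95

_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}

_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxResult:
    """One LP solution: flux vector, objective value and solver status."""

    fluxes: np.ndarray | None
    objective_value: float | None
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class ExchangeRate:
    """A measured specific exchange rate (negative = consumption)."""

    metabolite: str
    rate: float
    sd: float = 0.0


def _solve(c: np.ndarray, gem: GEM, extra_A_ub=None, extra_b_ub=None) -> FluxResult:
    """Maximize c^T v over the flux polytope (optionally with extra <= rows)."""
    res = linprog(
        -c,
        A_eq=gem.S,
        b_eq=np.zeros(len(gem.metabolites)),
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        bounds=np.column_stack([gem.lb, gem.ub]),
        method="highs",
        options=_LP_OPTIONS,
    )
    status = _STATUS.get(res.status, "numerical")
    if res.status != 0:
        return FluxResult(fluxes=None, objective_value=None, status=status)
    return FluxResult(fluxes=res.x, objective_value=float(-res.fun), status="optimal")


def fba(gem: GEM) -> FluxResult:
    """Maximize the biomass objective; infeasible/unbounded become statuses,
    not exceptions."""
    return _solve(gem.objective, gem)


def apply_measured_constraints(
    gem: GEM,
    rates: list[ExchangeRate],
    sd_mode: str = "span",
    metabolite_map: dict[str, str] | None = None,
) -> GEM:
    """Constrain exchange reactions to measured rates.

    Each rate's exchange reaction is found via ``metabolite_map`` (measured
    name -> model metabolite id) or directly by metabolite id.  In ``"span"``
    mode the new bounds are ``[q - sd, q + sd]`` clipped into the model's
    original bounds; ``"fixed"`` pins the flux to ``q`` exactly.  A rate of
    0 +/- 0 therefore closes the exchange (depletion semantics).  Unmappable
    metabolites raise an error listing all of them.
    """
    if sd_mode not in ("span", "fixed"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    name_map = metabolite_map or {}
    out = gem.copy()
    missing = []
    for r in rates:
        met = name_map.get(r.metabolite, r.metabolite)
        try:
            rxn = out.exchange_for_metabolite(met)
        except KeyError:
            missing.append(r.metabolite)
            continue
        j = out.reaction_index(rxn)
        if sd_mode == "fixed" or r.sd == 0:
            lo = hi = r.rate
        else:
            lo, hi = r.rate - r.sd, r.rate + r.sd
        lo = float(np.clip(lo, gem.lb[j], gem.ub[j]))
        hi = float(np.clip(hi, gem.lb[j], gem.ub[j]))
        out.lb[j], out.ub[j] = lo, hi
    if missing:
        raise KeyError(f"no exchange reaction found for metabolites: {missing}")
    return out


def depletion_screen(gem: GEM, exchanges: list[str] | None = None) -> pd.DataFrame:
    """Substrate-depletion screen: close one uptake at a time and re-solve.

    For each exchange reaction the uptake direction (negative flux) is closed
    while the model is otherwise untouched; the resulting optimum classifies
    the substrate as ``essential`` (predicted growth < 1e-6), ``limiting``
    (< 95% of the reference optimum) or ``dispensable``.  Solver failures are
    recorded per row and never abort the screen.
    """
    if exchanges is None:
        exchanges = [r for r in gem.exchanges if gem.lb[gem.reaction_index(r)] < 0]
    for rxn in exchanges:
        gem.reaction_index(rxn)  # raises KeyError for unknown reactions
    ref = fba(gem)
    if not ref.ok:
        raise ValueError(f"reference FBA failed with status {ref.status!r}")
    mu_ref = ref.objective_value
    rows = []
    for rxn in exchanges:
        j = gem.reaction_index(rxn)
        trial = gem.with_bounds(rxn, max(gem.lb[j], 0.0), gem.ub[j])
        res = fba(trial)
        if res.ok:
            mu = res.objective_value + 0.0  # normalize -0.0
        else:
            mu = 0.0  # no feasible flux distribution at all without this uptake
        if mu < ESSENTIALITY_TOL:
            cls = "essential"
        elif mu < LIMITING_FRACTION * mu_ref:
            cls = "limiting"
        else:
            cls = "dispensable"
        rows.append(
            {
                "exchange": rxn,
                "metabolite": gem.exchanges[rxn],
                "mu_pred": mu,
                "mu_reference": mu_ref,
                "classification": cls,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)


def _optimum_constraint(gem: GEM, fraction: float):
    ref = fba(gem)
    if not ref.ok:
        raise ValueError(f"FBA failed with status {ref.status!r}; no optimum to constrain to")
    # c^T v >= fraction * mu*  as  -c^T v <= -fraction * mu*
    A_ub = -gem.objective[np.newaxis, :]
    b_ub = np.array([-fraction * ref.objective_value])
    return ref, A_ub, b_ub


def fva(gem: GEM, fraction: float = 0.9) -> pd.DataFrame:
    """Flux variability analysis: per-reaction [min, max] at a fraction of
    the biomass optimum."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    _, A_ub, b_ub = _optimum_constraint(gem, fraction)
    rows = []
    for j, rxn in enumerate(gem.reactions):
        d = np.zeros(gem.n_reactions)
        d[j] = 1.0
        lo = _solve(-d, gem, A_ub, b_ub)
        hi = _solve(d, gem, A_ub, b_ub)
        if not (lo.ok and hi.ok):
            raise ValueError(f"FVA subproblem for {rxn!r} failed ({lo.status}/{hi.status})")
        rows.append({"reaction": rxn, "min": -lo.objective_value, "max": hi.objective_value})
    return pd.DataFrame(rows)


def sample_fluxes(
    gem: GEM,
    n: int = 5000,
    fraction: float = 0.9,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Random-objective vertex sampling of the near-optimal flux polytope.

    Solves ``n`` LPs with objective directions drawn uniformly on the unit
    sphere, all constrained to at least ``fraction`` of the biomass optimum,
    and returns per-reaction means and SDs of the optimal vertices.  With a
    single sample the SD is reported as 0 and flagged undefined.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    _, A_ub, b_ub = _optimum_constraint(gem, fraction)
    rng = np.random.default_rng(seed)
    nr = gem.n_reactions
    samples = np.empty((n, nr))
    for i in range(n):
        d = rng.standard_normal(nr)
        d /= np.linalg.norm(d)
        res = _solve(d, gem, A_ub, b_ub)
        if not res.ok:
            raise ValueError(f"sampling LP {i} failed with status {res.status!r}")
        samples[i] = res.fluxes
    sd = samples.std(axis=0, ddof=1) if n > 1 else np.zeros(nr)
    return pd.DataFrame(
        {
            "reaction": gem.reactions,
            "mean": samples.mean(axis=0),
            "sd": sd,
            "sd_defined": n > 1,
        }
    )
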