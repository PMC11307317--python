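"""Strain and community parameter containers for the consortium simulator.

Parameters are deliberately close to what a wet-lab practitioner would
tabulate: per-substrate maximum specific growth rates and half-saturation
constants (Monod kinetics), biomass and product yields, a growth-associated
heat yield, 16S rRNA gene copy numbers and a lag time.  Communities add the
medium composition, inoculum sizes, the serial-transfer fraction and an
optional per-passage adaptation schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = ["StrainParams", "CommunityParams", "AdaptationSchedule", "load_community_yaml"]


@dataclass
class StrainParams:
    """Kinetic and composition parameters of one strain.

    Parameters
    ----------
    name:
        Strain label (e.g. ``"AM"`` for *A. muciniphila*).
    mu_max:
        Maximum specific growth rate on each substrate, h^-1.  The realized
        rate is the sum of Monod terms over substrates, capped at the largest
        single-substrate ``mu_max`` (diauxie-like behaviour without explicit
        catabolite repression).
    K:
        Monod half-saturation constant per substrate, mmol/L.
    yield_X:
        Biomass yield per substrate, gDW per mmol.
    yield_P:
        Product stoichiometry: ``{substrate: {product: mmol product per mmol
        substrate}}``.
    heat_yield:
        Growth-associated heat release Y_Q, J per gDW of new biomass.
    copy_number:
        16S rRNA gene copies per genome (>= 1), used by the read sampler.
    lag_h:
        Lag time in hours; no growth or uptake before it.
    """

    name: str
    mu_max: dict[str, float]
    K: dict[str, float]
    yield_X: dict[str, float]
    yield_P: dict[str, dict[str, float]] = field(default_factory=dict)
    heat_yield: float = 20_000.0
    copy_number: int = 1
    lag_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu_max or max(self.mu_max.values()) <= 0:
            raise ValueError(f"strain {self.name!r}: needs >=1 substrate with mu_max > 0")
        for d, what in ((self.mu_max, "mu_max"), (self.K, "K"), (self.yield_X, "yield_X")):
            for k, v in d.items():
                if v < 0 or not math.isfinite(v):
                    raise ValueError(f"strain {self.name!r}: {what}[{k!r}] = {v} must be >= 0 and finite")
        for sub in self.mu_max:
            if sub not in self.K:
                raise ValueError(f"strain {self.name!r}: missing K for substrate {sub!r}")
            if sub not in self.yield_X:
                raise ValueError(f"strain {self.name!r}: missing yield_X for substrate {sub!r}")
        if self.copy_number < 1 or int(self.copy_number) != self.copy_number:
            raise ValueError(f"strain {self.name!r}: copy_number must be an integer >= 1")
        if self.heat_yield < 0:
            raise ValueError(f"strain {self.name!r}: heat_yield must be >= 0")
        if self.lag_h < 0:
            raise ValueError(f"strain {self.name!r}: lag_h must be >= 0")

    @property
    def mu_cap(self) -> float:
        """Cap on the summed Monod rate: the largest single-substrate mu_max."""
        return max(self.mu_max.values())

    @property
    def substrates(self) -> list[str]:
        return list(self.mu_max)


@dataclass
class AdaptationSchedule:
    """Per-passage geometric drift of strain parameters toward asymptotes.

    Serial passaging of freezer stocks shows adaptation: curves of early
    passages differ and converge over passages.  This is modelled as
    multiplicative offsets on lag time and on all ``mu_max`` values that decay
    geometrically per passage.  At passage ``p`` (1-based) the multiplier is::

        m(p) = 1 + (m0 - 1) * r**(p - 1)

    with ``r`` chosen so the residual offset is 1% of the initial offset at
    ``convergence_passage`` (``r = 0.01**(1/(convergence_passage-1))``), or
    given directly via ``rate``.

    Parameters
    ----------
    lag_multiplier:
        Initial multiplier on ``lag_h`` per strain name (drifts to 1).
    mu_multiplier:
        Initial multiplier on every ``mu_max`` per strain name (drifts to 1).
    convergence_passage:
        Passage at which parameters are within 1% of their asymptotes.
    rate:
        Explicit per-passage decay factor in [0, 1); overrides
        ``convergence_passage`` when given.
    """

    lag_multiplier: dict[str, float] = field(default_factory=dict)
    mu_multiplier: dict[str, float] = field(default_factory=dict)
    convergence_passage: int | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        if self.rate is None:
            if self.convergence_passage is None:
                self.rate = 0.5
            elif self.convergence_passage <= 1:
                self.rate = 0.01
            else:
                self.rate = 0.01 ** (1.0 / (self.convergence_passage - 1))
        if not 0.0 <= self.rate < 1.0:
            raise ValueError(f"adaptation rate must be in [0, 1), got {self.rate}")

    def multiplier(self, m0: float, passage: int) -> float:
        return 1.0 + (m0 - 1.0) * self.rate ** (passage - 1)

    def apply(self, strain: StrainParams, passage: int) -> StrainParams:
        """Return the strain's effective parameters at a given passage."""
        lag0 = self.lag_multiplier.get(strain.name, 1.0)
        mu0 = self.mu_multiplier.get(strain.name, 1.0)
        if lag0 == 1.0 and mu0 == 1.0:
            return strain
        m_lag = self.multiplier(lag0, passage)
        m_mu = self.multiplier(mu0, passage)
        return replace(
            strain,
            lag_h=strain.lag_h * m_lag,
            mu_max={k: v * m_mu for k, v in strain.mu_max.items()},
        )


@dataclass
class CommunityParams:
    """A community: strains, medium, inoculum and passaging regime."""

    strains: list[StrainParams]
    substrates: dict[str, float]
    initial_biomass: dict[str, float]
    transfer_fraction: float = 0.01
    adaptation: AdaptationSchedule | None = None
    ampoule_volume_L: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 < self.transfer_fraction < 1.0:
            raise ValueError("transfer_fraction must be in (0, 1)")
        names = [s.name for s in self.strains]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate strain names: {names}")
        for n in names:
            if self.initial_biomass.get(n, 0.0) < 0:
                raise ValueError(f"initial biomass for {n!r} must be >= 0")
        for k, v in self.substrates.items():
            if v < 0:
                raise ValueError(f"initial concentration of {k!r} must be >= 0")
        if self.ampoule_volume_L <= 0:
            raise ValueError("ampoule_volume_L must be > 0")

    @property
    def strain_names(self) -> list[str]:
        return [s.name for s in self.strains]

    def metabolite_names(self) -> list[str]:
        """All metabolites touched by the community: medium + products."""
        names = list(self.substrates)
        for s in self.strains:
            for sub in s.mu_max:
                if sub not in names:
                    names.append(sub)
            for prods in s.yield_P.values():
                for p in prods:
                    if p not in names:
                        names.append(p)
        return names


def load_community_yaml(path) -> CommunityParams:
    """Load a :class:`CommunityParams` from a YAML fixture file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    strains = [StrainParams(**s) for s in doc["strains"]]
    adapt = doc.get("adaptation")
    schedule = AdaptationSchedule(**adapt) if adapt else None
    return CommunityParams(
        strains=strains,
        substrates={k: float(v) for k, v in doc["substrates"].items()},
        initial_biomass={k: float(v) for k, v in doc["initial_biomass"].items()},
        transfer_fraction=float(doc.get("transfer_fraction", 0.01)),
        adaptation=schedule,
        ampoule_volume_L=float(doc.get("ampoule_volume_L", 0.002)),
    )
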