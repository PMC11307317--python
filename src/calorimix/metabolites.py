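"""Endpoint metabolite exchange analysis.

Concentration differences between the start and end of fermentation (mmol/L;
positive = production, negative = consumption) are summarized per replicate,
compared between a consortium and the *stacked* monocultures (the no-
interaction null: per-replicate sums of the individual strains' deltas) with
a two-sided equal-variance Student's t-test and the conventional star codes,
profiled by PCA for free amino acids, and converted to specific exchange
rates q = (dC / X) * mu in mmol gDW^-1 h^-1 for constraint-based modeling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from calorimix.stability import PCAResult, pca_scores

__all__ = [
    "replicate_deltas",
    "concentration_deltas",
    "compare_consortium_vs_stack",
    "significance_stars",
    "exchange_rate",
    "amino_acid_profile_pca",
    "od_to_gdw",
]

TABLE_COLUMNS = ["sample", "replicate", "metabolite", "timepoint", "conc_mM"]

#: Default OD600 -> gDW/L conversion; instrument- and strain-dependent,
#: exposed because endpoint biomass is usually recorded as OD.
OD_TO_GDW_DEFAULT = 0.4


def _check_table(table: pd.DataFrame) -> None:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"metabolite table is missing columns {sorted(missing)}")


def replicate_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate end-minus-start deltas, long format.

    Every (sample, replicate, metabolite) must have both a ``start`` and an
    ``end`` row; a missing pair is an error naming the offender.
    """
    _check_table(table)
    wide = table.pivot_table(
        index=["sample", "replicate", "metabolite"],
        columns="timepoint",
        values="conc_mM",
        aggfunc="first",
    )
    for tp in ("start", "end"):
        if tp not in wide.columns:
            raise ValueError(f"no {tp!r} timepoint rows in the table")
    incomplete = wide[wide[["start", "end"]].isna().any(axis=1)]
    if len(incomplete):
        s, r, m = incomplete.index[0]
        raise ValueError(f"missing start/end pair for sample={s!r} replicate={r!r} metabolite={m!r}")
    out = wide.reset_index()
    out["delta_mM"] = out["end"] - out["start"]
    return out[["sample", "replicate", "metabolite", "delta_mM"]]


def concentration_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample SD of end-minus-start deltas across replicates."""
    deltas = replicate_deltas(table)
    g = deltas.groupby(["sample", "metabolite"])["delta_mM"]
    out = g.agg(delta_mean="mean", delta_sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] < 2, "delta_sd"] = np.nan
    return out


def significance_stars(p: float) -> str:
    """Conventional star code: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided equal-variance Student's t-test, with the zero-variance
    degenerate case made explicit (identical groups: t=0, p=1; separated
    constant groups: p -> 0)."""
    pooled_var = np.var(a, ddof=1) + np.var(b, ddof=1)
    if pooled_var == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_consortium_vs_stack(
    mono_deltas: dict[str, pd.DataFrame],
    consortium_deltas: pd.DataFrame,
) -> pd.DataFrame:
    """Consortium vs stacked-monoculture deltas per metabolite.

    Inputs are per-replicate delta tables (from :func:`replicate_deltas`).
    The stacked value of replicate r is the sum over strains of that strain's
    replicate-r delta — summing per replicate rather than summing means keeps
    a replicate-level variance for the test while reproducing the stacked
    means exactly.  Returns one row per metabolite with means, SDs, the
    t statistic, p-value and star code.
    """
    cons = consortium_deltas.pivot(index="replicate", columns="metabolite", values="delta_mM")
    stack = None
    for strain, tbl in mono_deltas.items():
        w = tbl.pivot(index="replicate", columns="metabolite", values="delta_mM")
        if stack is None:
            stack = w.copy()
        else:
            if len(w.index) != len(stack.index):
                raise ValueError(
                    f"strain {strain!r} has {len(w.index)} replicates, expected {len(stack.index)}"
                )
            stack = stack.add(w.set_axis(stack.index), fill_value=0.0)
    if stack is None:
        raise ValueError("no monoculture tables given")
    if len(cons.index) != len(stack.index):
        raise ValueError(
            f"consortium has {len(cons.index)} replicates but the stack has {len(stack.index)}"
        )
    if len(cons.index) < 2:
        raise ValueError("need >= 2 replicates per condition")
    rows = []
    for met in cons.columns:
        c = cons[met].to_numpy(float)
        s = stack[met].to_numpy(float) if met in stack.columns else np.zeros_like(c)
        t, p = _t_test(c, s)
        rows.append(
            {
                "metabolite": met,
                "consortium_mean": c.mean(),
                "consortium_sd": c.std(ddof=1),
                "stack_mean": s.mean(),
                "stack_sd": s.std(ddof=1),
                "t": t,
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)


def exchange_rate(delta_mM: float, biomass_gdw: float, mu: float, sd_mM: float = 0.0):
    """Specific exchange rate q = (dC / X) * mu, mmol gDW^-1 h^-1.

    Negative q is consumption (standard exchange-flux sign convention).
    The SD scales identically with biomass and growth rate.
    """
    if biomass_gdw <= 0:
        raise ValueError("biomass must be > 0")
    if mu < 0:
        raise ValueError("growth rate must be >= 0")
    q = delta_mM / biomass_gdw * mu
    q_sd = abs(sd_mM) / biomass_gdw * mu
    return q, q_sd


def od_to_gdw(od600: float, factor: float = OD_TO_GDW_DEFAULT) -> float:
    """Convert an OD600 reading to gDW/L with a configurable factor."""
    return od600 * factor


def amino_acid_profile_pca(profiles: pd.DataFrame) -> tuple[PCAResult, list[str]]:
    """PCA of endpoint amino-acid concentration profiles.

    ``profiles`` is wide: one row per sample (including the blank-medium
    reference), one column per amino acid, values in mmol/L.  All samples
    must share the same metabolite set (no missing values).  Centered and
    scaled, as is conventional for concentration blocks.
    """
    if profiles.isna().any().any():
        bad = profiles.columns[profiles.isna().any()].tolist()
        raise ValueError(f"mismatched metabolite sets; missing values in {bad}")
    pca = pca_scores(profiles.to_numpy(float), center=True, scale=True)
    return pca, list(profiles.index)
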