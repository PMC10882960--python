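"""Fate factors: change in the alien species fraction per unit transport.

The fate factor (FF) of an ordered country pair converts a transport rate
into a change in the importer's alien species fraction (ASF), in units of
ASF * year / kg.  Two variants are produced from the fitted count model:

* average — the predicted change in alien species between zero trade and
  the full cumulative quantity, divided by the mean transport rate over the
  150-year history (retrospective view);
* marginal — the predicted change from one additional year of trade at the
  recent annual rate (last decade's mean), divided by that rate
  (forward-looking view).

Both divide the species change by the total number of species present in
the importing country, so an extra alien moves the ASF less in a species-
rich country.  Because introductions accumulate concavely with imports
(species-import curve), the marginal FF never exceeds the average FF.
Pairs trading less than 100 kg/yr on average are excluded as too uncertain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .nbglmm import GLMMFit, predict_mean

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_YEARS = 150
TRADE_RATE_THRESHOLD_KG_PER_YR = 100.0


@dataclass
class FateFactor:
    exporter: str
    importer: str
    kind: str  # "marginal" | "average"
    value: float  # ASF * year / kg
    delta_AS: float
    denominator_rate: float  # kg / year
    S_total_i: int


def asf(alien_count: float, native_count: float) -> float:
    """Alien species fraction AS / (AS + S); in [0, 1)."""
    if alien_count < 0 or native_count < 0:
        raise ValueError("species counts must be nonnegative")
    total = alien_count + native_count
    if total == 0:
        raise ValueError("ASF undefined when no species are present")
    return alien_count / total


@dataclass
class PairState:
    """Per-pair covariates at the end of the study period."""

    exporter: str
    importer: str
    cum_final: float  # cumulative kg at the last decade endpoint
    cum_prev: float  # cumulative kg one decade earlier
    D: float
    S_e: float
    S_i: float


def pair_states(panel: pd.DataFrame) -> list[PairState]:
    """Extract final-period covariates for every ordered pair in the panel."""
    states = []
    last = int(panel["decade_end"].max())
    prev = last - 10
    for (e, i), grp in panel.groupby(["e", "i"], sort=True):
        by_decade = grp.set_index("decade_end")
        row = by_decade.loc[last]
        cum_prev = float(by_decade.loc[prev, "TR"]) if prev in by_decade.index else 0.0
        states.append(
            PairState(
                exporter=str(e),
                importer=str(i),
                cum_final=float(row["TR"]),
                cum_prev=cum_prev,
                D=float(row["D"]),
                S_e=float(row["S_e"]),
                S_i=float(row["S_i"]),
            )
        )
    return states


def filter_pairs(
    panel: pd.DataFrame,
    horizon_years: int = DEFAULT_HORIZON_YEARS,
    threshold_kg_per_yr: float = TRADE_RATE_THRESHOLD_KG_PER_YR,
) -> set[tuple[str, str]]:
    """Pairs whose mean transport rate reaches the eligibility threshold.

    The rate is the final cumulative quantity divided by the full horizon;
    a pair exactly at the threshold is eligible.
    """
    eligible = set()
    for state in pair_states(panel):
        if state.cum_final / horizon_years >= threshold_kg_per_yr:
            eligible.add((state.exporter, state.importer))
    return eligible


def average_ff(
    fit: GLMMFit,
    state: PairState,
    S_total_i: int,
    horizon_years: int = DEFAULT_HORIZON_YEARS,
) -> FateFactor | None:
    """Average FF from the zero-trade vs full-history prediction contrast."""
    if state.cum_final <= 0:
        logger.info(
            "skipping average FF for %s->%s: zero cumulative trade",
            state.exporter,
            state.importer,
        )
        return None
    mu_hi = predict_mean(fit, state.cum_final, state.D, state.S_e, state.S_i)
    mu_lo = predict_mean(fit, 0.0, state.D, state.S_e, state.S_i)
    delta_as = float(mu_hi - mu_lo)
    rate = state.cum_final / horizon_years
    value = (delta_as / S_total_i) / rate
    return FateFactor(
        state.exporter, state.importer, "average", value, delta_as, rate, S_total_i
    )


def marginal_ff(fit: GLMMFit, state: PairState, S_total_i: int) -> FateFactor | None:
    """Marginal FF from one additional year of trade at the recent rate."""
    q = (state.cum_final - state.cum_prev) / 10.0
    if q <= 0:
        logger.info(
            "skipping marginal FF for %s->%s: no trade in the final decade",
            state.exporter,
            state.importer,
        )
        return None
    mu_plus = predict_mean(fit, state.cum_final + q, state.D, state.S_e, state.S_i)
    mu_now = predict_mean(fit, state.cum_final, state.D, state.S_e, state.S_i)
    delta_as = float(mu_plus - mu_now)
    value = (delta_as / S_total_i) / q
    return FateFactor(
        state.exporter, state.importer, "marginal", value, delta_as, q, S_total_i
    )


def species_present(
    natives: Mapping[str, int],
    aliens: Mapping[str, int],
    include_aliens: bool = True,
) -> dict[str, int]:
    """Total species present per country (natives plus recorded aliens).

    ``include_aliens=False`` restricts the FF weighting to native richness.
    """
    out = {}
    for country, n_native in natives.items():
        total = int(n_native) + (int(aliens.get(country, 0)) if include_aliens else 0)
        out[country] = total
    return out


def compute_fate_factors(
    fit: GLMMFit,
    panel: pd.DataFrame,
    s_total: Mapping[str, int],
    horizon_years: int = DEFAULT_HORIZON_YEARS,
    threshold_kg_per_yr: float = TRADE_RATE_THRESHOLD_KG_PER_YR,
) -> pd.DataFrame:
    """Marginal and average FFs for all eligible pairs.

    Returns a frame with columns (e, i, kind, value, delta_AS,
    denominator_rate, S_total_i, eligible); ineligible pairs are listed with
    eligible=False and NaN values for audit.
    """
    eligible = filter_pairs(panel, horizon_years, threshold_kg_per_yr)
    rows = []
    for state in pair_states(panel):
        key = (state.exporter, state.importer)
        s_tot = int(s_total[state.importer])
        if key not in eligible:
            rows.append((*key, "average", np.nan, np.nan, np.nan, s_tot, False))
            rows.append((*key, "marginal", np.nan, np.nan, np.nan, s_tot, False))
            continue
        for maker, kind in ((average_ff, "average"), (marginal_ff, "marginal")):
            ff = (
                maker(fit, state, s_tot, horizon_years)
                if kind == "average"
                else maker(fit, state, s_tot)
            )
            if ff is None:
                rows.append((*key, kind, np.nan, np.nan, np.nan, s_tot, False))
            else:
                rows.append(
                    (
                        *key,
                        kind,
                        ff.value,
                        ff.delta_AS,
                        ff.denominator_rate,
                        s_tot,
                        True,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "e",
            "i",
            "kind",
            "value",
            "delta_AS",
            "denominator_rate",
            "S_total_i",
            "eligible",
        ],
    )
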