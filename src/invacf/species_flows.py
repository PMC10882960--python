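"""Species pools, exporter attribution and assembly of the GLMM panel.

A country's species pool in year y is its native flora plus every alien
species first-recorded there by year y.  Including earlier arrivals in the
pool captures bridgehead invasions: an established alien population can seed
further introductions elsewhere.  Each first record of species s in importer
i at year y is credited, in full, to every country e != i that held s in its
pool at year y-1 — all plausible transport routes contribute.  Attributed
counts are then aggregated to 10-year intervals and joined with cumulative
trade, distance and species-richness covariates into one row per
exporter x importer x decade.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .trade_history import decade_endpoints

logger = logging.getLogger(__name__)


@dataclass
class SpeciesPools:
    """Year-resolved species pools for every country.

    ``natives`` maps country -> frozenset of native species; ``arrivals``
    maps country -> list of (year, species) first records sorted by year.
    Pools are monotonically nondecreasing in time by construction.
    """

    natives: dict[str, frozenset[str]]
    arrivals: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def members(self, country: str, year: int) -> frozenset[str]:
        """Pool of ``country`` at ``year`` (arrivals up to and including year)."""
        base = self.natives.get(country)
        if base is None:
            raise KeyError(f"unknown country id {country!r}")
        arr = self.arrivals.get(country, [])
        k = bisect_right(arr, (year, "\uffff"))
        if k == 0:
            return base
        return base | frozenset(s for _, s in arr[:k])

    def size(self, country: str, year: int) -> int:
        base = self.natives.get(country)
        if base is None:
            raise KeyError(f"unknown country id {country!r}")
        arr = self.arrivals.get(country, [])
        k = bisect_right(arr, (year, "\uffff"))
        # arrivals are pre-filtered against natives, so no double counting
        return len(base) + k


def build_pools(
    native_ranges: Mapping[str, Iterable[str]],
    first_records: pd.DataFrame,
    year_range: tuple[int, int],
) -> SpeciesPools:
    """Construct year-resolved pools from native ranges and first records.

    ``first_records`` has columns (species, country, year).  Records of a
    species in a country where it is native are dropped with a warning;
    records outside ``year_range`` raise.
    """
    natives = {c: frozenset(s) for c, s in native_ranges.items()}
    arrivals: dict[str, list[tuple[int, str]]] = {c: [] for c in natives}
    start, end = year_range
    n_dropped = 0
    for row in first_records.itertuples(index=False):
        species, country, year = str(row.species), str(row.country), int(row.year)
        if country not in natives:
            raise KeyError(f"first record references unknown country {country!r}")
        if not start <= year <= end:
            raise ValueError(
                f"first record of {species} in {country} at {year} outside "
                f"{start}-{end}"
            )
        if species in natives[country]:
            n_dropped += 1
            logger.warning(
                "dropping first record of %s in %s (%d): species is native there",
                species,
                country,
                year,
            )
            continue
        arrivals[country].append((year, species))
    for country in arrivals:
        arrivals[country].sort()
        # keep only the earliest record per species so pool sizes stay exact
        seen: set[str] = set()
        deduped = []
        for year, species in arrivals[country]:
            if species not in seen:
                seen.add(species)
                deduped.append((year, species))
        arrivals[country] = deduped
    if n_dropped:
        logger.warning("dropped %d native-in-country first records", n_dropped)
    return SpeciesPools(natives=natives, arrivals=arrivals)


def attribute_introductions(
    first_records: pd.DataFrame, pools: SpeciesPools
) -> dict[tuple[str, str, int], int]:
    """Credit each first record to every candidate exporter.

    A record (s, i, y) increments count(e, i, y) by one for every e != i
    with s in pool(e, y-1) — full credit per candidate, no fractional
    splitting.  Records with no candidate exporter are counted nowhere and
    logged.  Records dropped by :func:`build_pools` (native in the recording
    country) are ignored here as well.
    """
    # invert membership once: species -> native countries, and per-country
    # first-record years for bridgehead candidacy
    native_of: dict[str, set[str]] = {}
    for country, members in pools.natives.items():
        for s in members:
            native_of.setdefault(s, set()).add(country)
    arrival_year: dict[tuple[str, str], int] = {}
    for country, arr in pools.arrivals.items():
        for year, s in arr:
            key = (s, country)
            if key not in arrival_year or year < arrival_year[key]:
                arrival_year[key] = year

    counts: dict[tuple[str, str, int], int] = {}
    n_orphan = 0
    for row in first_records.itertuples(index=False):
        s, i, y = str(row.species), str(row.country), int(row.year)
        if s in pools.natives.get(i, frozenset()):
            continue  # dropped by build_pools
        candidates = set(native_of.get(s, ()))
        for country in pools.natives:
            if (s, country) in arrival_year and arrival_year[(s, country)] <= y - 1:
                candidates.add(country)
        candidates.discard(i)
        if not candidates:
            n_orphan += 1
            logger.info("first record of %s in %s (%d) has no candidate exporter", s, i, y)
            continue
        for e in candidates:
            key = (e, i, y)
            counts[key] = counts.get(key, 0) + 1
    if n_orphan:
        logger.warning("%d first records had no candidate exporter", n_orphan)
    return counts


def aggregate_panel(
    counts: Mapping[tuple[str, str, int], int],
    decade_trade: pd.DataFrame,
    distances: Mapping[tuple[str, str], float] | pd.DataFrame,
    pools: SpeciesPools,
    year_range: tuple[int, int],
) -> pd.DataFrame:
    """Assemble the exporter x importer x decade panel for the GLMM.

    One row per ordered pair and decade: AS summed over the decade's years,
    TR cumulative at the decade end (from ``decade_trade`` with columns
    e, i, decade_end, cum_kg; missing pairs count as zero trade), S_e the
    exporter pool size at the decade's first year, S_i the importer's native
    species count, D the pair distance.  All-zero-trade rows are retained;
    eligibility filtering happens later.
    """
    from .trade_history import pair_distance

    endpoints = decade_endpoints(*year_range)
    countries = sorted(pools.natives)

    trade_map: dict[tuple[str, str, int], float] = {}
    for row in decade_trade.itertuples(index=False):
        e, i = str(row.e), str(row.i)
        if e not in pools.natives or i not in pools.natives:
            raise KeyError(f"decade trade references unknown country pair ({e}, {i})")
        trade_map[(e, i, int(row.decade_end))] = float(row.cum_kg)

    for e, i, _y in counts:
        if e not in pools.natives or i not in pools.natives:
            raise KeyError(f"attributed counts reference unknown pair ({e}, {i})")

    # decade membership of each attributed year
    decade_of: dict[int, int] = {}
    for endpoint in endpoints:
        for y in range(endpoint - 9, endpoint + 1):
            decade_of[y] = endpoint
    as_by_decade: dict[tuple[str, str, int], int] = {}
    for (e, i, y), n in counts.items():
        endpoint = decade_of.get(y)
        if endpoint is None:
            raise ValueError(f"attributed year {y} outside decade range")
        key = (e, i, endpoint)
        as_by_decade[key] = as_by_decade.get(key, 0) + n

    rows = []
    for e in countries:
        for i in countries:
            if e == i:
                continue
            d_km = pair_distance(distances, e, i)
            s_i = len(pools.natives[i])
            for endpoint in endpoints:
                rows.append(
                    (
                        e,
                        i,
                        endpoint,
                        trade_map.get((e, i, endpoint), 0.0),
                        d_km,
                        pools.size(e, endpoint - 9),
                        s_i,
                        as_by_decade.get((e, i, endpoint), 0),
                    )
                )
    return pd.DataFrame(
        rows, columns=["e", "i", "decade_end", "TR", "D", "S_e", "S_i", "AS"]
    )
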