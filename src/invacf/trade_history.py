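"""Reconstruction of bilateral transported mass and decade cumulation.

Recent trade statistics report transported mass (kg) directly, but only for
the last few decades; older records exist only as monetary flows.  For every
ordered country pair a zero-intercept quadratic regression

    mass = c1 * money + c2 * money**2

is fitted on the years where both series overlap and used to back-cast mass
for the historical years.  The merged yearly series is then cumulated into
10-year timesteps; with the default 1870-2019 range this yields 15 decade
endpoints (1879, 1889, ..., 2019).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class BackcastUnfitError(RuntimeError):
    """Raised when a prediction is requested from an unfit back-cast model."""


@dataclass
class PairSeries:
    """Yearly mass and money flows for one ordered (exporter, importer) pair."""

    exporter: str
    importer: str
    mass_by_year: dict[int, float] = field(default_factory=dict)
    money_by_year: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, series in (("mass", self.mass_by_year), ("money", self.money_by_year)):
            for year, value in series.items():
                if value < 0:
                    raise ValueError(
                        f"negative {name} for {self.exporter}->{self.importer} in {year}"
                    )


@dataclass
class BackcastModel:
    """Zero-intercept quadratic mass-from-money model for one ordered pair."""

    exporter: str
    importer: str
    coef1: float = 0.0
    coef2: float = 0.0
    r_squared: float = float("nan")
    fitted: bool = False
    n_overlap: int = 0


def fit_backcast(pair: PairSeries, overlap_years: Iterable[int]) -> BackcastModel:
    """Fit mass = c1*money + c2*money^2 (no intercept) on the overlap years.

    Years lacking either observation are ignored.  Fewer than 3 usable
    overlap years leaves the model unfit; predictions for that pair then
    fall back to zero pre-window mass (handled by the caller via
    :func:`merge_mass_series`), with a warning.
    """
    years = sorted(
        y
        for y in overlap_years
        if y in pair.mass_by_year and y in pair.money_by_year
    )
    model = BackcastModel(pair.exporter, pair.importer, n_overlap=len(years))
    if len(years) < 3:
        logger.warning(
            "backcast unfit for %s->%s: only %d overlap years",
            pair.exporter,
            pair.importer,
            len(years),
        )
        return model

    money = np.array([pair.money_by_year[y] for y in years], dtype=float)
    mass = np.array([pair.mass_by_year[y] for y in years], dtype=float)
    design = np.column_stack([money, money**2])
    coefs, *_ = np.linalg.lstsq(design, mass, rcond=None)
    fitted_vals = design @ coefs
    ss_res = float(np.sum((mass - fitted_vals) ** 2))
    ss_tot = float(np.sum((mass - mass.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-12 * max(1.0, float(np.sum(mass**2))) else -math.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    model.coef1 = float(coefs[0])
    model.coef2 = float(coefs[1])
    model.r_squared = r2
    model.fitted = True
    return model


def predict_mass(model: BackcastModel, money: float) -> float:
    """Predicted transported mass (kg) for a monetary flow; clamped at zero."""
    if not model.fitted:
        raise BackcastUnfitError(
            f"backcast model for {model.exporter}->{model.importer} is unfit "
            f"({model.n_overlap} overlap years); cannot predict"
        )
    raw = model.coef1 * money + model.coef2 * money**2
    if raw < 0:
        logger.info(
            "clamped negative mass prediction %.3g to 0 for %s->%s",
            raw,
            model.exporter,
            model.importer,
        )
        return 0.0
    return float(raw)


def merge_mass_series(
    observed: Mapping[int, float],
    model: BackcastModel,
    money_by_year: Mapping[int, float],
    years: Iterable[int],
) -> dict[int, float]:
    """Yearly mass over ``years``: observed where available, else back-cast.

    An observed value is never overwritten by a prediction.  Years with
    neither an observation nor money data (or an unfit model) contribute
    zero mass.
    """
    out: dict[int, float] = {}
    for year in years:
        if year in observed:
            out[year] = float(observed[year])
        elif model.fitted and year in money_by_year:
            out[year] = predict_mass(model, money_by_year[year])
        else:
            out[year] = 0.0
    return out


def decade_endpoints(start_year: int, end_year: int) -> list[int]:
    """Decade endpoints {start+9, start+19, ..., end}; range must align."""
    span = end_year - start_year + 1
    if span <= 0 or span % 10 != 0:
        raise ValueError(
            f"year range {start_year}-{end_year} does not split into whole decades"
        )
    return list(range(start_year + 9, end_year + 1, 10))


def cumulate_decades(
    mass_by_year: Mapping[int, float], start_year: int, end_year: int
) -> dict[int, float]:
    """Running cumulative mass evaluated at each decade endpoint.

    Every year in [start_year, end_year] contributes (missing years count as
    zero); masses must be nonnegative so the series is nondecreasing.
    """
    endpoints = decade_endpoints(start_year, end_year)
    for year, value in mass_by_year.items():
        if value < 0:
            raise ValueError(f"negative mass {value} in year {year}")
    out: dict[int, float] = {}
    running = 0.0
    year = start_year
    for endpoint in endpoints:
        while year <= endpoint:
            running += float(mass_by_year.get(year, 0.0))
            year += 1
        out[endpoint] = running
    return out


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two lat/lon points in km (R=6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def pair_distance(
    distances: Mapping[tuple[str, str], float] | pd.DataFrame | None,
    exporter: str,
    importer: str,
    centroids: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Distance (km) between two countries.

    Looks up the (symmetric) distance table first; falls back to the
    great-circle distance between centroids when the pair is missing, with a
    log entry.  Same country gives 0.
    """
    if exporter == importer:
        return 0.0
    table: Mapping[tuple[str, str], float] | None
    if isinstance(distances, pd.DataFrame):
        table = {
            (str(r.e), str(r.i)): float(r.km) for r in distances.itertuples(index=False)
        }
    else:
        table = distances
    if table is not None:
        for key in ((exporter, importer), (importer, exporter)):
            if key in table:
                d = float(table[key])
                if d < 0:
                    raise ValueError(f"negative distance for pair {key}")
                return d
    if centroids is not None:
        try:
            lat1, lon1 = centroids[exporter]
            lat2, lon2 = centroids[importer]
        except KeyError as exc:
            raise KeyError(f"unknown country id {exc.args[0]!r}") from None
        logger.info(
            "distance for %s-%s missing from table; haversine fallback",
            exporter,
            importer,
        )
        return haversine_km(lat1, lon1, lat2, lon2)
    raise KeyError(f"no distance available for pair ({exporter}, {importer})")


def backcast_all_pairs(
    trade_mass: pd.DataFrame,
    trade_money: pd.DataFrame,
    start_year: int,
    end_year: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Back-cast and cumulate every ordered pair appearing in either table.

    ``trade_mass`` has columns (e, i, year, kg) for the recent window;
    ``trade_money`` has columns (e, i, year, value) for the historical
    window.  Returns the decade panel (e, i, decade_end, cum_kg) and a
    per-pair back-cast report (e, i, coef1, coef2, r2, n_overlap, fitted).
    """
    years = range(start_year, end_year + 1)
    mass_map: dict[tuple[str, str], dict[int, float]] = {}
    for row in trade_mass.itertuples(index=False):
        mass_map.setdefault((str(row.e), str(row.i)), {})[int(row.year)] = float(row.kg)
    money_map: dict[tuple[str, str], dict[int, float]] = {}
    for row in trade_money.itertuples(index=False):
        money_map.setdefault((str(row.e), str(row.i)), {})[int(row.year)] = float(
            row.value
        )

    pairs = sorted(set(mass_map) | set(money_map))
    panel_rows = []
    report_rows = []
    for e, i in pairs:
        pair = PairSeries(e, i, mass_map.get((e, i), {}), money_map.get((e, i), {}))
        overlap = set(pair.mass_by_year) & set(pair.money_by_year)
        model = fit_backcast(pair, overlap)
        merged = merge_mass_series(pair.mass_by_year, model, pair.money_by_year, years)
        cum = cumulate_decades(merged, start_year, end_year)
        for decade_end, kg in cum.items():
            panel_rows.append((e, i, decade_end, kg))
        report_rows.append(
            (e, i, model.coef1, model.coef2, model.r_squared, model.n_overlap, model.fitted)
        )
    panel = pd.DataFrame(panel_rows, columns=["e", "i", "decade_end", "cum_kg"])
    report = pd.DataFrame(
        report_rows, columns=["e", "i", "coef1", "coef2", "r2", "n_overlap", "fitted"]
    )
    return panel, report
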