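"""Self-consistent synthetic worlds with recorded ground truth.

The generator emulates every data stream the characterization pipeline
consumes — countries with areas and locations, native vascular-plant ranges,
a 150-year bilateral trade history (mass observed only in a recent window,
money further back), alien first records, Red-List style threat tables and
global extinction probabilities — from a single seeded configuration whose
parameters are echoed back as ground truth.

The species-relocation process mirrors the statistical model used downstream:
for every exporter x importer x decade cell the latent introduction count is
drawn from a negative binomial with log-mean built from the same covariates
and transforms the fitting module uses (z-scored log cumulative trade, raw
distance, log species pools) plus Gaussian importer-within-period and
exporter-within-period intercepts.  Latent counts are realised into dated
first records by sampling species from the exporter's decade-start pool that
are not yet present in the importer; pools grow decade-wise so bridgehead
re-exports become possible one decade after arrival.  Draws exceeding the
available pool are truncated and logged.

Country-level impact data follow PDF = ef_slope * ASF + eps with eps drawn
half-normal (strictly nonnegative): real-world confounders can only inflate
the share of threatened species, which is exactly the asymmetry the
low-quantile effect-factor regression exploits.  The planted PDF is
discretised into per-species category/threat/severity rows (rounding the
threatened count up, again one-sided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._io import read_csv, write_csv
from .trade_history import decade_endpoints, haversine_km

TAXON_GROUPS = ("amphibians", "birds", "mammals")

DEFAULT_BETA = {
    "intercept": -6.0,
    "logTR": 9.3e-3,
    "D": -3.6e-5,
    "logS_e": 8.4e-1,
    "logS_i": 3.3e-1,
}
DEFAULT_RE_SD = {"importer_period": 0.25, "exporter_period": 0.25}


@dataclass
class WorldConfig:
    """Parameters of the synthetic generative process.

    The defaults describe the study conditions the pipeline is exercised
    under: 25 countries trading over 1870-2019, introduction-count
    coefficients at the values the fitted model is expected to recover, an
    effect-factor slope of 0.038 PDF/ASF and one-sided confounder noise on
    the country PDFs.
    """

    seed: int = 0
    n_countries: int = 25
    n_species: int = 5000
    year_range: tuple[int, int] = (1870, 2019)
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    theta: float = 1.5
    re_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RE_SD))
    ef_slope: float = 0.038
    confounder_scale: float = 0.02

    # trade process
    mass_window_start: int = 1995  # first year with directly observed mass
    money_window_end: int = 2014  # last year with monetary records
    trade_log_mean: float = math.log(2.0e4)  # median base rate, kg/yr
    trade_log_sd: float = 2.5
    trade_distance_scale_km: float = 8000.0
    trade_growth_rate: float = 0.03  # per year, exponential growth to 2019
    mass_noise_sd: float = 0.3  # lognormal sd of yearly mass
    price_per_kg: float = 0.5  # currency units per kg
    price_noise_sd: float = 0.05  # lognormal sd of the price

    # impact-data process
    n_assessed_mean: int = 600  # assessed amphibian/bird/mammal natives
    dd_fraction: float = 0.05
    unknown_severity_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_countries < 3:
            raise ValueError("need at least 3 countries")
        if self.n_species < 10:
            raise ValueError("need at least 10 species")
        if self.theta <= 0:
            raise ValueError("NB dispersion theta must be positive")
        if any(sd < 0 for sd in self.re_sd.values()):
            raise ValueError("random-effect standard deviations must be >= 0")
        if self.ef_slope < 0:
            raise ValueError("ef_slope must be >= 0")
        if self.confounder_scale < 0:
            raise ValueError("confounder_scale must be >= 0")
        start, end = self.year_range
        if (end - start + 1) % 10 != 0:
            raise ValueError("year range must span whole decades")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["year_range"] = list(self.year_range)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "WorldConfig":
        data = dict(data)
        if "year_range" in data:
            data["year_range"] = tuple(data["year_range"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorldConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class World:
    """A generated synthetic world plus its ground truth."""

    config: WorldConfig
    countries: pd.DataFrame  # id, area_km2, lat, lon
    native_ranges: dict[str, frozenset[str]]  # species -> native countries
    natives_by_country: dict[str, frozenset[str]]
    distances: dict[tuple[str, str], float]
    gep: pd.DataFrame  # country, taxon_group, gep
    trade_mass: dict[tuple[str, str, int], float]  # recent window only
    trade_money: dict[tuple[str, str, int], float]
    first_records: pd.DataFrame  # species, country, year
    threat_table: pd.DataFrame
    truth: dict

    @property
    def latent_panel(self) -> pd.DataFrame:
        """The generator's own pair x decade table (realised AS counts)."""
        return self.truth["panel"]


def _assign_natives(
    rng: np.random.Generator, country_ids: list[str], n_species: int
) -> dict[str, frozenset[str]]:
    """Assign each species a single native country with uneven richness."""
    n = len(country_ids)
    weights = rng.lognormal(0.0, 0.6, n)
    probs = weights / weights.sum()
    species = [f"S{k:05d}" for k in range(n_species)]
    assignment = {}
    # guarantee at least one native everywhere, then fill at random
    for k, country in enumerate(country_ids):
        assignment[species[k]] = country
    draws = rng.choice(n, size=n_species - n, p=probs)
    for sp, c_idx in zip(species[n:], draws):
        assignment[sp] = country_ids[int(c_idx)]
    by_country: dict[str, set[str]] = {c: set() for c in country_ids}
    for sp, country in assignment.items():
        by_country[country].add(sp)
    return {c: frozenset(s) for c, s in by_country.items()}


THREAT_COLUMNS = (
    "species",
    "country",
    "category",
    "threat_code",
    "severity",
    "dd_predicted_threatened",
)


def _threat_rows_for_country(
    rng: np.random.Generator,
    country: str,
    pdf: float,
    n_assessed: int,
    dd_fraction: float,
    unknown_severity_fraction: float,
) -> list[tuple]:
    """Discretise a planted country PDF into per-species threat rows.

    The threatened count rounds *up* (ceil), so discretisation error is
    one-sided like the confounder noise.  Non-qualifying species exercise
    every exclusion rule: threatened by other stressors, alien pressure on
    least-concern species, data-deficient labels (with and without a
    threatened prediction), and unknown-severity rows outside the
    denominator.
    """
    rows: list[tuple] = []
    k_threatened = math.ceil(pdf * n_assessed) if pdf > 0 else 0
    for j in range(n_assessed):
        sp = f"A_{country}_{j:04d}"
        if j < k_threatened:
            category = str(rng.choice(["VU", "EN", "CR"]))
            threat_code = "8.1"
            severity = str(rng.choice(["slow_significant", "rapid", "very_rapid"]))
            dd = ""
            if rng.random() < dd_fraction:
                category, dd = "DD", "True"
        else:
            roll = rng.random()
            if roll < 0.1:
                # threatened, but by something else entirely
                category, threat_code = str(rng.choice(["VU", "EN"])), "2.1"
                severity = str(rng.choice(["slow_significant", "rapid"]))
                dd = ""
            elif roll < 0.2:
                # alien pressure documented but the species is not threatened
                category, threat_code = "LC", "8.1"
                severity = str(rng.choice(["slow_significant", "rapid"]))
                dd = ""
                if rng.random() < dd_fraction:
                    category, dd = "DD", "False"
            else:
                category, threat_code = str(rng.choice(["LC", "LC", "NT"])), "2.1"
                severity = str(rng.choice(["none", "slow_significant"]))
                dd = ""
        rows.append((sp, country, category, threat_code, severity, dd))
    for j in range(int(unknown_severity_fraction * n_assessed)):
        rows.append((f"A_{country}_u{j:04d}", country, "LC", "2.1", "unknown", ""))
    return rows


def synthetic_effect_inputs(
    n_countries: int = 140,
    ef_slope: float = 0.038,
    confounder_scale: float = 0.02,
    seed: int = 0,
    n_assessed_mean: int = 600,
    dd_fraction: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, int], dict[str, float]]:
    """Country-level inputs for the effect-factor stage alone.

    A light-weight companion to :func:`generate_world` for studying the
    quantile regression at realistic country counts without simulating the
    full trade/introduction history: country alien fractions are drawn from
    a Beta distribution, the planted PDF is ``ef_slope * ASF`` plus
    half-normal confounder noise, and the same discretisation into threat
    rows is applied.  Returns (threats, natives_count, alien_count,
    area_km2) ready for :func:`~invacf.effect_factor.build_effect_rows`.
    """
    rng = np.random.default_rng(seed)
    threats = []
    natives_count: dict[str, int] = {}
    alien_count: dict[str, int] = {}
    area: dict[str, float] = {}
    for k in range(n_countries):
        c = f"C{k:03d}"
        asf = float(rng.beta(2.0, 4.0))
        total = int(rng.integers(200, 2000))
        n_alien = int(round(asf * total))
        natives_count[c] = total - n_alien
        alien_count[c] = n_alien
        area[c] = float(10 ** rng.uniform(2.0, 7.0))
        eps = abs(rng.normal(0.0, confounder_scale)) if confounder_scale > 0 else 0.0
        realized_asf = n_alien / total
        pdf = min(0.95, ef_slope * realized_asf + eps)
        size = max(50, int(rng.lognormal(math.log(n_assessed_mean), 0.3)))
        threats.extend(
            _threat_rows_for_country(rng, c, pdf, size, dd_fraction, 0.05)
        )
    threats_df = pd.DataFrame(threats, columns=THREAT_COLUMNS)
    return threats_df, natives_count, alien_count, area


def generate_world(config: WorldConfig) -> World:
    """Generate a world; identical configs give identical worlds."""
    rng = np.random.default_rng(config.seed)
    n = config.n_countries
    start_year, end_year = config.year_range
    endpoints = decade_endpoints(start_year, end_year)
    country_ids = [f"C{k:03d}" for k in range(n)]

    area = 10 ** rng.uniform(3.5, 7.0, n)
    lat = rng.uniform(-60.0, 70.0, n)
    lon = rng.uniform(-180.0, 180.0, n)
    countries = pd.DataFrame(
        {"id": country_ids, "area_km2": area, "lat": lat, "lon": lon}
    )
    distances: dict[tuple[str, str], float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            distances[(country_ids[a], country_ids[b])] = haversine_km(
                lat[a], lon[a], lat[b], lon[b]
            )

    gep_rows = []
    for country in country_ids:
        for group in TAXON_GROUPS:
            gep_rows.append((country, group, float(rng.beta(1.5, 8.0))))
    gep = pd.DataFrame(gep_rows, columns=["country", "taxon_group", "gep"])

    natives_by_country = _assign_natives(rng, country_ids, config.n_species)
    native_ranges: dict[str, set[str]] = {}
    for country, members in natives_by_country.items():
        for sp in members:
            native_ranges.setdefault(sp, set()).add(country)

    # --- trade history (exogenous) -------------------------------------
    pairs = [(e, i) for e in country_ids for i in country_ids if e != i]
    years = np.arange(start_year, end_year + 1)
    growth = np.exp(config.trade_growth_rate * (years - end_year))
    true_mass: dict[tuple[str, str], np.ndarray] = {}
    for e, i in pairs:
        d_km = distances.get((e, i), distances.get((i, e), 0.0))
        base = math.exp(
            rng.normal(config.trade_log_mean, config.trade_log_sd)
            - d_km / config.trade_distance_scale_km
        )
        noise = rng.lognormal(0.0, config.mass_noise_sd, len(years))
        true_mass[(e, i)] = base * growth * noise

    trade_mass: dict[tuple[str, str, int], float] = {}
    trade_money: dict[tuple[str, str, int], float] = {}
    for e, i in pairs:
        series = true_mass[(e, i)]
        price_noise = rng.lognormal(0.0, config.price_noise_sd, len(years))
        for idx, year in enumerate(years):
            year = int(year)
            if year >= config.mass_window_start and series[idx] > 0:
                trade_mass[(e, i, year)] = float(series[idx])
            if year <= config.money_window_end and series[idx] > 0:
                trade_money[(e, i, year)] = float(
                    series[idx] * config.price_per_kg * price_noise[idx]
                )

    # cumulative transported mass at each decade endpoint (the latent TR)
    cum_tr: dict[tuple[str, str, int], float] = {}
    for e, i in pairs:
        running = np.cumsum(true_mass[(e, i)])
        for endpoint in endpoints:
            cum_tr[(e, i, endpoint)] = float(running[endpoint - start_year])

    # z-scoring constants for log trade, over the full pair x decade grid —
    # the same row set the fitting module will see, so scalings coincide
    log_tr_all = np.log1p(np.array([cum_tr[(e, i, d)] for e, i in pairs for d in endpoints]))
    tr_mean, tr_sd = float(np.mean(log_tr_all)), float(np.std(log_tr_all))
    if tr_sd == 0:
        tr_sd = 1.0

    # --- species relocation process ------------------------------------
    beta = config.beta
    sd_ip = config.re_sd.get("importer_period", 0.0)
    sd_ep = config.re_sd.get("exporter_period", 0.0)
    u_ip = {
        (c, d): float(rng.normal(0.0, sd_ip)) if sd_ip > 0 else 0.0
        for d in endpoints
        for c in country_ids
    }
    u_ep = {
        (c, d): float(rng.normal(0.0, sd_ep)) if sd_ep > 0 else 0.0
        for d in endpoints
        for c in country_ids
    }

    s_i_native = {c: len(natives_by_country[c]) for c in country_ids}
    present: dict[str, set[str]] = {c: set() for c in country_ids}  # aliens
    records: list[tuple[str, str, int]] = []
    truncations: list[dict] = []
    panel_rows = []

    for endpoint in endpoints:
        d_start = endpoint - 9
        pool_start = {
            c: natives_by_country[c] | frozenset(present[c]) for c in country_ids
        }
        s_e_start = {c: len(pool_start[c]) for c in country_ids}
        for e, i in pairs:
            d_km = distances.get((e, i), distances.get((i, e), 0.0))
            tr = cum_tr[(e, i, endpoint)]
            eta = (
                beta["intercept"]
                + beta["logTR"] * (math.log1p(tr) - tr_mean) / tr_sd
                + beta["D"] * d_km
                + beta["logS_e"] * math.log(s_e_start[e])
                + beta["logS_i"] * math.log(s_i_native[i])
                + u_ip[(i, endpoint)]
                + u_ep[(e, endpoint)]
            )
            mu = math.exp(min(eta, 30.0))
            latent = int(rng.poisson(rng.gamma(config.theta, mu / config.theta)))
            candidates = sorted(pool_start[e] - natives_by_country[i] - present[i])
            realized = latent
            if latent > len(candidates):
                realized = len(candidates)
                truncations.append(
                    {
                        "e": e,
                        "i": i,
                        "decade_end": endpoint,
                        "latent": latent,
                        "realized": realized,
                    }
                )
            if realized > 0:
                chosen = rng.choice(candidates, size=realized, replace=False)
                # arrival years exclude the decade's first year so the pool
                # at the decade start is unambiguous
                arrival_years = rng.integers(d_start + 1, endpoint + 1, realized)
                for sp, year in zip(chosen, arrival_years):
                    records.append((str(sp), i, int(year)))
                    present[i].add(str(sp))
            panel_rows.append(
                (
                    e,
                    i,
                    endpoint,
                    cum_tr[(e, i, endpoint)],
                    d_km,
                    s_e_start[e],
                    s_i_native[i],
                    realized,
                    latent,
                )
            )

    records.sort()
    first_records = pd.DataFrame(records, columns=["species", "country", "year"])
    panel = pd.DataFrame(
        panel_rows,
        columns=["e", "i", "decade_end", "TR", "D", "S_e", "S_i", "AS", "AS_latent"],
    )

    # ground-truth attribution: every country holding the species the year
    # before the record gets full credit (native range or earlier record)
    first_by_sc: dict[tuple[str, str], int] = {}
    for sp, c, y in records:
        key = (sp, c)
        if key not in first_by_sc or y < first_by_sc[key]:
            first_by_sc[key] = y
    expected_attribution: dict[tuple[str, str, int], int] = {}
    for sp, i, y in records:
        candidates = set(native_ranges.get(sp, ()))
        for c in country_ids:
            if first_by_sc.get((sp, c), 10**9) <= y - 1:
                candidates.add(c)
        candidates.discard(i)
        for e in candidates:
            key = (e, i, y)
            expected_attribution[key] = expected_attribution.get(key, 0) + 1

    # --- impact data ----------------------------------------------------
    asf_true = {}
    pdf_true = {}
    for c in country_ids:
        aliens = len(present[c])
        asf_true[c] = aliens / (aliens + s_i_native[c])
        eps = abs(rng.normal(0.0, config.confounder_scale)) if config.confounder_scale > 0 else 0.0
        pdf_true[c] = min(0.95, config.ef_slope * asf_true[c] + eps)

    threat_rows = []
    n_assessed = {}
    for c in country_ids:
        size = max(30, int(rng.lognormal(math.log(config.n_assessed_mean), 0.3)))
        n_assessed[c] = size
        threat_rows.extend(
            _threat_rows_for_country(
                rng,
                c,
                pdf_true[c],
                size,
                config.dd_fraction,
                config.unknown_severity_fraction,
            )
        )
    threat_table = pd.DataFrame(threat_rows, columns=THREAT_COLUMNS)

    truth = {
        "config": config.to_dict(),
        "beta": dict(beta),
        "theta": config.theta,
        "re_sd": dict(config.re_sd),
        "scaling": {"logTR": (tr_mean, tr_sd)},
        "u_importer_period": u_ip,
        "u_exporter_period": u_ep,
        "panel": panel,
        "truncations": truncations,
        "expected_attribution": expected_attribution,
        "asf": asf_true,
        "pdf": pdf_true,
        "n_assessed": n_assessed,
        "aliens_final": {c: len(present[c]) for c in country_ids},
        "true_mass_years": years.tolist(),
    }

    return World(
        config=config,
        countries=countries,
        native_ranges={sp: frozenset(cs) for sp, cs in native_ranges.items()},
        natives_by_country=natives_by_country,
        distances=distances,
        gep=gep,
        trade_mass=trade_mass,
        trade_money=trade_money,
        first_records=first_records,
        threat_table=threat_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# CSV round-trip

CSV_FILES = (
    "countries.csv",
    "distances.csv",
    "gep.csv",
    "natives.csv",
    "first_records.csv",
    "trade_mass.csv",
    "trade_money.csv",
    "threats.csv",
)


def world_to_csv(world: World, directory: str | Path) -> list[Path]:
    """Write the world as the CSV set the pipeline readers accept.

    Floats are written with full repr precision, so reading the files back
    reproduces the in-memory values exactly and re-serialising a seed-fixed
    world is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = directory / name
        write_csv(frame, path)
        written.append(path)

    _write("countries.csv", world.countries)
    dist = pd.DataFrame(
        [(e, i, km) for (e, i), km in sorted(world.distances.items())],
        columns=["e", "i", "km"],
    )
    _write("distances.csv", dist)
    _write("gep.csv", world.gep)
    natives = pd.DataFrame(
        sorted(
            (sp, c) for sp, cs in world.native_ranges.items() for c in cs
        ),
        columns=["species", "country"],
    )
    _write("natives.csv", natives)
    _write("first_records.csv", world.first_records)
    mass = pd.DataFrame(
        [(e, i, y, kg) for (e, i, y), kg in sorted(world.trade_mass.items())],
        columns=["e", "i", "year", "kg"],
    )
    _write("trade_mass.csv", mass)
    money = pd.DataFrame(
        [(e, i, y, v) for (e, i, y), v in sorted(world.trade_money.items())],
        columns=["e", "i", "year", "value"],
    )
    _write("trade_money.csv", money)
    _write("threats.csv", world.threat_table)
    return written


@dataclass
class WorldData:
    """The CSV view of a world, as read back by the pipeline."""

    countries: pd.DataFrame
    distances: pd.DataFrame
    gep: pd.DataFrame
    natives: pd.DataFrame
    first_records: pd.DataFrame
    trade_mass: pd.DataFrame
    trade_money: pd.DataFrame
    threats: pd.DataFrame

    @property
    def natives_by_country(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {
            str(c): set() for c in self.countries["id"].astype(str)
        }
        for row in self.natives.itertuples(index=False):
            out.setdefault(str(row.country), set()).add(str(row.species))
        return out

    @property
    def distance_map(self) -> dict[tuple[str, str], float]:
        return {
            (str(r.e), str(r.i)): float(r.km)
            for r in self.distances.itertuples(index=False)
        }


def read_world_csv(directory: str | Path) -> WorldData:
    """Read a world CSV directory back into DataFrames."""
    directory = Path(directory)
    frames = {}
    for name in CSV_FILES:
        path = directory / name
        if not path.exists():
            raise FileNotFoundError(f"missing input file: {path}")
        frames[name[:-4]] = read_csv(path)
    # empty files lose dtypes; normalise key columns
    fr = frames["first_records"]
    if len(fr):
        frames["first_records"] = fr.astype({"year": int})
    return WorldData(
        countries=frames["countries"],
        distances=frames["distances"],
        gep=frames["gep"],
        natives=frames["natives"],
        first_records=frames["first_records"],
        trade_mass=frames["trade_mass"],
        trade_money=frames["trade_money"],
        threats=frames["threats"].fillna({"dd_predicted_threatened": ""}),
    )
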