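"""End-to-end orchestration over the CSV interfaces.

Each stage reads only the CSV products of earlier stages, so a run can be
staged across invocations (as the CLI does) or executed in one call with
:func:`run_all`; both routes produce identical artifacts because every
intermediate table is serialised with full float precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from ._io import write_csv
from . import fate_factors, nbglmm, species_flows, trade_history
from .characterization import GEPTable, build_cf_table
from .effect_factor import EffectFactor, build_effect_rows, effect_factor
from .synthetic_world import WorldData, read_world_csv

logger = logging.getLogger(__name__)


def run_backcast(
    data: WorldData, year_range: tuple[int, int], out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Back-cast mass from money and cumulate into decades for all pairs."""
    panel, report = trade_history.backcast_all_pairs(
        data.trade_mass, data.trade_money, *year_range
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_csv(panel, out_dir / "decade_panel_trade.csv")
        write_csv(report, out_dir / "backcast_report.csv")
    return panel, report


def run_panel(
    data: WorldData,
    decade_trade: pd.DataFrame,
    year_range: tuple[int, int],
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Build species pools, attribute first records, assemble the panel."""
    pools = species_flows.build_pools(
        data.natives_by_country, data.first_records, year_range
    )
    counts = species_flows.attribute_introductions(data.first_records, pools)
    panel = species_flows.aggregate_panel(
        counts, decade_trade, data.distance_map, pools, year_range
    )
    if out_dir is not None:
        write_csv(panel, Path(out_dir) / "panel.csv")
    return panel


def run_fit(
    panel: pd.DataFrame,
    spec: nbglmm.ModelSpec | None = None,
    include_random: bool = True,
    out_dir: str | Path | None = None,
) -> nbglmm.GLMMFit:
    fit = nbglmm.fit(panel, spec, include_random=include_random)
    if out_dir is not None:
        save_fit(fit, Path(out_dir) / "fit.json")
    return fit


def save_fit(fit: nbglmm.GLMMFit, path: str | Path) -> None:
    payload = {
        "fixed_effects": list(fit.spec.fixed_effects),
        "standardize": list(fit.spec.standardize),
        "random_effects": list(fit.spec.random_effects),
        "beta": fit.beta,
        "beta_se": fit.beta_se,
        "theta": fit.theta,
        "re_sd": fit.re_sd,
        "loglik": fit.loglik,
        "aicc": fit.aicc,
        "n_obs": fit.n_obs,
        "k_params": fit.k_params,
        "scaling": {k: list(v) for k, v in fit.scaling.items()},
        "converged": fit.converged,
        "boundary": fit.boundary,
        "re_modes": fit.re_modes,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_fit(path: str | Path) -> nbglmm.GLMMFit:
    payload = json.loads(Path(path).read_text())
    spec = nbglmm.ModelSpec(
        fixed_effects=tuple(payload["fixed_effects"]),
        standardize=tuple(payload["standardize"]),
        random_effects=tuple(payload["random_effects"]),
    )
    return nbglmm.GLMMFit(
        spec=spec,
        beta=payload["beta"],
        beta_se=payload["beta_se"],
        theta=payload["theta"],
        re_sd=payload["re_sd"],
        loglik=payload["loglik"],
        aicc=payload["aicc"],
        n_obs=payload["n_obs"],
        k_params=payload["k_params"],
        scaling={k: tuple(v) for k, v in payload["scaling"].items()},
        converged=payload["converged"],
        boundary=payload["boundary"],
        re_modes=payload["re_modes"],
    )


def alien_counts(data: WorldData) -> dict[str, int]:
    """Distinct alien species recorded per country by the end of the period."""
    counts: dict[str, int] = {c: 0 for c in data.countries["id"].astype(str)}
    natives = data.natives_by_country
    seen: set[tuple[str, str]] = set()
    for row in data.first_records.itertuples(index=False):
        sp, c = str(row.species), str(row.country)
        if sp in natives.get(c, set()) or (sp, c) in seen:
            continue
        seen.add((sp, c))
        counts[c] = counts.get(c, 0) + 1
    return counts


def run_ff(
    data: WorldData,
    fit: nbglmm.GLMMFit,
    panel: pd.DataFrame,
    include_aliens_in_weighting: bool = True,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    natives_n = {c: len(s) for c, s in data.natives_by_country.items()}
    s_total = fate_factors.species_present(
        natives_n, alien_counts(data), include_aliens=include_aliens_in_weighting
    )
    ff = fate_factors.compute_fate_factors(fit, panel, s_total)
    if out_dir is not None:
        write_csv(ff, Path(out_dir) / "ff.csv")
    return ff


def run_ef(
    data: WorldData,
    n_boot: int = 1000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[EffectFactor]]:
    natives_n = {c: len(s) for c, s in data.natives_by_country.items()}
    area = {
        str(r.id): float(r.area_km2) for r in data.countries.itertuples(index=False)
    }
    rows = build_effect_rows(data.threats, natives_n, alien_counts(data), area)
    efs = effect_factor(rows, n_boot=n_boot, seed=seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_csv(rows, out_dir / "effect_rows.csv")
        (out_dir / "ef.json").write_text(
            json.dumps([asdict(ef) for ef in efs], indent=1)
        )
    return rows, efs


def headline_ef(efs: list[EffectFactor]) -> EffectFactor:
    """The tau=0.05, dd_predicted effect factor."""
    for ef in efs:
        if ef.tau == 0.05 and ef.dd_option == "dd_predicted":
            return ef
    raise ValueError("headline EF (tau=0.05, dd_predicted) not present")


def run_cf(
    data: WorldData,
    ff: pd.DataFrame,
    ef: EffectFactor,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    gep = GEPTable(data.gep)
    cf = build_cf_table(ff, ef, gep)
    if out_dir is not None:
        write_csv(cf, Path(out_dir) / "cf.csv")
    return cf


def run_all(
    world_dir: str | Path,
    year_range: tuple[int, int] = (1870, 2019),
    out_dir: str | Path | None = None,
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Full pipeline from a world CSV directory; returns all artifacts."""
    data = read_world_csv(world_dir)
    decade_trade, backcast_report = run_backcast(data, year_range, out_dir)
    panel = run_panel(data, decade_trade, year_range, out_dir)
    fit = run_fit(panel, out_dir=out_dir)
    ff = run_ff(data, fit, panel, out_dir=out_dir)
    effect_rows, efs = run_ef(data, n_boot=n_boot, seed=seed, out_dir=out_dir)
    ef = headline_ef(efs)
    cf = run_cf(data, ff, ef, out_dir=out_dir)
    return {
        "data": data,
        "decade_trade": decade_trade,
        "backcast_report": backcast_report,
        "panel": panel,
        "fit": fit,
        "ff": ff,
        "effect_rows": effect_rows,
        "efs": efs,
        "ef": ef,
        "cf": cf,
    }
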