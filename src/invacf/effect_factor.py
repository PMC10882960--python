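"""Effect factor: potentially disappeared fraction per unit alien fraction.

The country-level potentially disappeared fraction (PDF) is the share of
comparably assessed native species (amphibians, birds, mammals) that are
extinct or threatened with extinction *and* experience documented declines
caused by invasive alien species.  Because a species can be threatened by
many stressors at once, the observed PDF is only inflated — never deflated —
by confounders, so the stressor-response relationship between a country's
alien species fraction (ASF) and its PDF is fitted through a low quantile
(5th percentile by default) of the PDF distribution rather than the mean.
The regression is a weighted quantile fit (weights log10 of country area,
larger countries being better surveyed) solved exactly as a linear program;
its slope is the effect factor in PDF per ASF.

Data-deficient (DD) Red-List species carry no extinction-risk category and
are handled with three bracketing options: count only those independently
predicted to be threatened (default), none of them, or all of them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .fate_factors import asf

logger = logging.getLogger(__name__)

RED_LIST_CATEGORIES = frozenset({"LC", "NT", "VU", "EN", "CR", "EX", "EW", "DD"})
THREATENED_CATEGORIES = frozenset({"VU", "EN", "CR", "EX", "EW"})
SEVERITIES = frozenset({"slow_significant", "rapid", "very_rapid", "unknown", "none"})
QUALIFYING_SEVERITIES = frozenset({"slow_significant", "rapid", "very_rapid"})
DEFAULT_ALIEN_THREAT_CODES = frozenset({"8.1", "8.1.1", "8.1.2"})
DD_OPTIONS = ("dd_predicted", "dd_not_threatened", "dd_threatened")
DEFAULT_TAUS = (0.05, 0.10, 0.15)


@dataclass
class EffectFactor:
    tau: float
    slope: float  # PDF per ASF
    intercept: float
    ci_lower: float
    ci_upper: float
    dd_option: str
    n: int


def _validate_threats(threats: pd.DataFrame) -> None:
    bad_cat = set(threats["category"].unique()) - RED_LIST_CATEGORIES
    if bad_cat:
        raise ValueError(f"unknown Red-List categories: {sorted(bad_cat)}")
    bad_sev = set(threats["severity"].unique()) - SEVERITIES
    if bad_sev:
        raise ValueError(f"unknown severities: {sorted(bad_sev)}")


def compute_pdf(
    threats: pd.DataFrame,
    country: str,
    dd_option: str = "dd_predicted",
    alien_threat_codes: frozenset[str] = DEFAULT_ALIEN_THREAT_CODES,
) -> tuple[float, int]:
    """PDF and assessed-species denominator for one country.

    Denominator: species with at least one threat row whose severity is not
    "unknown" (assessed at a comparable level of detail).  Numerator:
    species threatened with extinction (per the DD option) that have an
    invasive-alien threat row with a qualifying decline severity.
    """
    if dd_option not in DD_OPTIONS:
        raise ValueError(f"unknown DD option {dd_option!r}")
    sub = threats[threats["country"].astype(str) == str(country)]
    if sub.empty:
        raise KeyError(f"no threat rows for country {country!r}")
    _validate_threats(sub)

    assessed = set(
        sub.loc[sub["severity"] != "unknown", "species"].astype(str)
    )
    if not assessed:
        raise ValueError(f"country {country!r} has no comparably assessed species")

    category = sub.groupby(sub["species"].astype(str))["category"].first()
    if "dd_predicted_threatened" in sub.columns:
        # tolerate booleans, "True"/"False" strings and blanks
        dd_flag = (
            sub.groupby(sub["species"].astype(str))["dd_predicted_threatened"]
            .first()
            .map(lambda v: str(v).strip().lower() == "true")
        )
    else:
        dd_flag = pd.Series(False, index=category.index)

    alien_hit = sub[
        sub["threat_code"].astype(str).isin(alien_threat_codes)
        & sub["severity"].isin(QUALIFYING_SEVERITIES)
    ]["species"].astype(str)
    alien_species = set(alien_hit)

    numerator = 0
    for species in assessed:
        if species not in alien_species:
            continue
        cat = category[species]
        if cat in THREATENED_CATEGORIES:
            numerator += 1
        elif cat == "DD":
            if dd_option == "dd_threatened" or (
                dd_option == "dd_predicted" and bool(dd_flag[species])
            ):
                numerator += 1
    return numerator / len(assessed), len(assessed)


def country_asf(n_native: int, n_alien: int) -> float:
    """Country-level alien species fraction (shared definition with the FF)."""
    return asf(n_alien, n_native)


def build_effect_rows(
    threats: pd.DataFrame,
    natives_count: Mapping[str, int],
    alien_count: Mapping[str, int],
    area_km2: Mapping[str, float],
    alien_threat_codes: frozenset[str] = DEFAULT_ALIEN_THREAT_CODES,
) -> pd.DataFrame:
    """Per-country rows (ASF, PDF per DD option, weight) for the EF fit.

    Only countries present in every input table enter; countries whose
    denominator would be empty are excluded with a log entry.  Weights are
    log10(area) with a floor of 1 for areas below 10 km^2.
    """
    countries = (
        set(threats["country"].astype(str))
        & set(natives_count)
        & set(alien_count)
        & set(area_km2)
    )
    by_country = dict(tuple(threats.groupby(threats["country"].astype(str))))
    rows = []
    for country in sorted(countries):
        sub = by_country[country]
        try:
            pdfs = {
                opt: compute_pdf(sub, country, opt, alien_threat_codes)
                for opt in DD_OPTIONS
            }
        except ValueError:
            logger.warning("excluding %s: no comparably assessed species", country)
            continue
        n_native = int(natives_count[country])
        n_alien = int(alien_count[country])
        if n_native + n_alien == 0:
            logger.warning("excluding %s: no species present", country)
            continue
        weight = max(1.0, math.log10(max(float(area_km2[country]), 1.0)))
        rows.append(
            {
                "country": country,
                "ASF": country_asf(n_native, n_alien),
                "PDF_dd_predicted": pdfs["dd_predicted"][0],
                "PDF_dd_not_threatened": pdfs["dd_not_threatened"][0],
                "PDF_dd_threatened": pdfs["dd_threatened"][0],
                "S_i_assessed": pdfs["dd_predicted"][1],
                "weight": weight,
            }
        )
    return pd.DataFrame(rows)


def weighted_quantile_line(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, tau: float
) -> tuple[float, float]:
    """Intercept and slope minimising the weighted tilted absolute loss.

    Solves min_{a,b} sum_i w_i * rho_tau(y_i - a - b x_i) as the standard
    quantile-regression linear program (residual split into positive and
    negative parts) with the HiGHS solver; exact and deterministic.
    """
    x, y, w = (np.asarray(v, dtype=float) for v in (x, y, w))
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a quantile fit")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly between 0 and 1")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined: all predictor values identical")

    # variables: a+, a-, b+, b-, r+ (n), r- (n)
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], tau * w, (1.0 - tau) * w])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1.0
    A_eq[:, 1] = -1.0
    A_eq[:, 2] = x
    A_eq[:, 3] = -x
    A_eq[np.arange(n), 4 + np.arange(n)] = 1.0
    A_eq[np.arange(n), 4 + n + np.arange(n)] = -1.0
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return float(a), float(b)


def check_loss(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    tau: float,
    intercept: float,
    slope: float,
) -> float:
    """Weighted tilted-absolute-loss value of a candidate line."""
    r = np.asarray(y, float) - intercept - slope * np.asarray(x, float)
    return float(np.sum(np.asarray(w, float) * np.where(r >= 0, tau * r, (tau - 1) * r)))


def weighted_quantile_fit(
    rows: pd.DataFrame,
    tau: float,
    dd_option: str = "dd_predicted",
    n_boot: int = 1000,
    seed: int = 0,
) -> EffectFactor:
    """Fit the EF line through quantile ``tau`` with a bootstrap CI.

    ``rows`` comes from :func:`build_effect_rows`.  The confidence interval
    is a weighted pairs bootstrap: countries are resampled with replacement
    (keeping their weights) ``n_boot`` times and the 2.5/97.5 percentiles of
    the refitted slopes are reported.  Degenerate resamples (all ASF equal)
    are skipped.
    """
    x = rows["ASF"].to_numpy(dtype=float)
    y = rows[f"PDF_{dd_option}"].to_numpy(dtype=float)
    w = rows["weight"].to_numpy(dtype=float)
    a, b = weighted_quantile_line(x, y, w, tau)

    rng = np.random.default_rng(seed)
    slopes = []
    n = len(x)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0:
            continue
        try:
            _, b_star = weighted_quantile_line(x[idx], y[idx], w[idx], tau)
        except RuntimeError:
            continue
        slopes.append(b_star)
    if slopes:
        lo, hi = np.percentile(slopes, [2.5, 97.5])
        lo, hi = float(min(lo, b)), float(max(hi, b))
    else:
        lo = hi = b
    return EffectFactor(
        tau=tau,
        slope=b,
        intercept=a,
        ci_lower=lo,
        ci_upper=hi,
        dd_option=dd_option,
        n=n,
    )


def effect_factor(
    rows: pd.DataFrame,
    taus: Sequence[float] = DEFAULT_TAUS,
    dd_options: Iterable[str] = DD_OPTIONS,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[EffectFactor]:
    """One EffectFactor per (tau, DD option).

    The headline EF is (tau=0.05, dd_predicted) — the first list element
    with the default arguments.
    """
    out = []
    for tau in taus:
        for opt in dd_options:
            out.append(weighted_quantile_fit(rows, tau, opt, n_boot=n_boot, seed=seed))
    return out
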