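"""Assembly of regional and global characterization factors.

A characterization factor (CF) converts an inventory flow — kilograms of
goods shipped from exporter e to importer i — into biodiversity damage,
expressed as a time-integrated potentially disappeared fraction of native
terrestrial species (PDF * year / kg).  The regional CF is the product of
the pair's fate factor (ASF * yr / kg) and the constant effect factor
(PDF / ASF).  Multiplying by the importer's global extinction probability
(GEP, averaged over taxon groups) rescales the regional loss to the share
that would be lost globally.

Distance does not appear at application time: its effect on introduction
success is already inside the fate factor, which distinguishes these CFs
from, e.g., climate-change transport CFs that scale with kg * km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effect_factor import EffectFactor

logger = logging.getLogger(__name__)


@dataclass
class GEPTable:
    """Per-country global extinction probabilities by taxon group."""

    by_group: pd.DataFrame  # columns: country, taxon_group, gep

    def __post_init__(self) -> None:
        gep = self.by_group["gep"].to_numpy(dtype=float)
        if np.any((gep < 0) | (gep > 1)):
            raise ValueError("GEP values must lie in [0, 1]")

    def mean_gep(self, country: str) -> float:
        """Unweighted arithmetic mean GEP across available taxon groups."""
        sub = self.by_group[self.by_group["country"].astype(str) == str(country)]
        if sub.empty:
            raise KeyError(f"no GEP entries for country {country!r}")
        return float(sub["gep"].mean())

    def countries(self) -> set[str]:
        return set(self.by_group["country"].astype(str))


def regional_cf(ff_value: float, ef: EffectFactor | float) -> float:
    """Regional CF = FF * EF slope, in PDF * year / kg."""
    slope = ef.slope if isinstance(ef, EffectFactor) else float(ef)
    return ff_value * slope


def global_cf(regional: float, gep: GEPTable, importer: str) -> float:
    """Global CF = regional CF * importer's mean GEP."""
    return regional * gep.mean_gep(importer)


def build_cf_table(
    ff_table: pd.DataFrame, ef: EffectFactor | float, gep: GEPTable
) -> pd.DataFrame:
    """CF records for every eligible FF row.

    Returns columns (e, i, kind, regional_cf, global_cf); importers missing
    from the GEP table keep their regional CF but get a NaN global CF, with
    a log entry.
    """
    slope = ef.slope if isinstance(ef, EffectFactor) else float(ef)
    known = gep.countries()
    rows = []
    for rec in ff_table.itertuples(index=False):
        if not rec.eligible or not np.isfinite(rec.value):
            continue
        regional = rec.value * slope
        importer = str(rec.i)
        if importer in known:
            glob = regional * gep.mean_gep(importer)
        else:
            glob = np.nan
            logger.warning("no GEP for importer %s; global CF omitted", importer)
        rows.append((str(rec.e), importer, str(rec.kind), regional, glob))
    return pd.DataFrame(rows, columns=["e", "i", "kind", "regional_cf", "global_cf"])


def apply_cf(mass_kg: float, cf_value: float) -> float:
    """Impact (PDF * year) of transporting ``mass_kg`` at the given CF.

    Distance-independent by construction: the fate model already accounts
    for the pair's separation.
    """
    if mass_kg < 0:
        raise ValueError("mass must be nonnegative")
    return mass_kg * cf_value


def compare_with_reference(
    mass_kg: float,
    distance_km: float,
    alien_cf: float,
    reference_cf_per_kgkm: float,
) -> dict[str, float]:
    """Compare the alien-species impact with a distance-scaled reference.

    The reference CF (e.g., a climate-change CF for freight transport) is
    supplied by the user per kg*km; the alien-species CF applies per kg
    irrespective of distance.  Returns both impacts (PDF * year) and their
    ratio (reference / alien; inf when the alien impact is zero).
    """
    if mass_kg < 0 or distance_km < 0 or reference_cf_per_kgkm < 0:
        raise ValueError("mass, distance and reference CF must be nonnegative")
    reference_impact = mass_kg * distance_km * reference_cf_per_kgkm
    alien_impact = apply_cf(mass_kg, alien_cf)
    ratio = reference_impact / alien_impact if alien_impact > 0 else float("inf")
    return {
        "alien_impact_pdf_yr": alien_impact,
        "reference_impact_pdf_yr": reference_impact,
        "ratio_reference_to_alien": ratio,
    }
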