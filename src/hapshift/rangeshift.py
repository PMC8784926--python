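"""Range extent, range change and eDNA-vs-field concordance on a 1-D coastline.

Site positions are kilometres along a transect drawn parallel to the
coast; range extent for a species-year is the distance between its
westernmost and easternmost occupied sites.  Ordinal abundance follows
the rapid-assessment cover bands: absent (0%), scarce (<10%),
common (10-50%), dominant (>50%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

CATEGORY_ORDER = {"absent": 0, "scarce": 1, "common": 2, "dominant": 3}


@dataclass
class RangeResult:
    species: str
    year: int
    west_bound_km: float
    east_bound_km: float
    occupied_site_count: int

    @property
    def extent_km(self) -> float:
        return self.east_bound_km - self.west_bound_km


@dataclass
class RangeChange:
    delta_extent_km: float
    rate_km_per_year: float  # reported to 1 decimal
    west_shift_km: float  # positive = westward expansion
    east_shift_km: float  # positive = eastward expansion
    classification: str  # expansion | contraction | stable


def abundance_rank(cover_percent: float) -> str:
    """Map a substrate-cover percentage onto the ordinal survey category."""
    if not 0 <= cover_percent <= 100:
        raise ValueError("cover must be within [0, 100]")
    if cover_percent == 0:
        return "absent"
    if cover_percent < 10:
        return "scarce"
    if cover_percent <= 50:
        return "common"
    return "dominant"


def range_extent(records: pd.DataFrame, species: str, year: int) -> RangeResult | None:
    """Bounds and extent from occupied sites of one species-year.

    ``records`` needs columns site_id, position_km, year, species,
    category.  Returns None when no site is occupied.
    """
    sub = records[(records["species"] == species) & (records["year"] == year)]
    if sub.empty:
        return None
    missing = sub["position_km"].isna()
    if missing.any():
        raise ValueError(f"positions unknown for sites: {list(sub.loc[missing, 'site_id'])}")
    occ = sub[sub["category"] != "absent"]
    if occ.empty:
        return None
    return RangeResult(
        species=species,
        year=int(year),
        west_bound_km=float(occ["position_km"].min()),
        east_bound_km=float(occ["position_km"].max()),
        occupied_site_count=int(occ["site_id"].nunique()),
    )


def range_change(
    r1: RangeResult | None, r2: RangeResult | None, t1: int, t2: int
) -> RangeChange:
    """Change in extent and bounds between two survey years and the spread rate."""
    if t2 <= t1:
        raise ValueError("t2 must be later than t1")
    if r1 is None or r2 is None:
        raise ValueError("both years must have an occupied range")
    delta = r2.extent_km - r1.extent_km
    # half-up to 1 decimal (reporting convention for spread rates); pre-round
    # to strip float noise so e.g. 21.049999... quantises as 21.05 -> 21.1
    rate = float(
        Decimal(str(round(delta / (t2 - t1), 6))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    if delta > 0:
        classification = "expansion"
    elif delta < 0:
        classification = "contraction"
    else:
        classification = "stable"
    return RangeChange(
        delta_extent_km=delta,
        rate_km_per_year=rate,
        west_shift_km=r1.west_bound_km - r2.west_bound_km,
        east_shift_km=r2.east_bound_km - r1.east_bound_km,
        classification=classification,
    )


def density_concordance(
    edna_rra: np.ndarray | list,
    field_ranks: np.ndarray | list,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation between read abundance and ordinal density.

    Uses only sites with detections in both sources (caller subsets);
    returns (rho, two-sided permutation p).  Fewer than 4 shared sites is
    declared not testable.
    """
    x = np.asarray(edna_rra, dtype=float)
    y = np.asarray(field_ranks, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 4:
        raise ValueError("fewer than 4 shared sites: concordance not testable")
    rng = np.random.default_rng(seed)
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        return float("nan"), float("nan")
    exceed = 0
    for _ in range(n_permutations):
        r = stats.spearmanr(x, rng.permutation(y)).statistic
        if np.isnan(r) or abs(r) >= abs(rho) - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return float(rho), float(p)


def detection_comparison(
    field: pd.DataFrame, edna_incidence: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per species-site confusion classes between field surveys and eDNA markers.

    ``field`` has columns site_id, species, category (one year);
    ``edna_incidence[marker]`` is a species x site table of relative read
    abundance (zero/absent column = not detected).  Returns a long table
    with columns marker, species, site_id, status in
    {both, field_only, edna_only, neither}, plus summary counts obtainable
    by grouping.
    """
    rows = []
    for marker, table in edna_incidence.items():
        sites = sorted(set(field["site_id"]))
        for species in sorted(set(field["species"]) | set(table.index)):
            for site in sites:
                f_sub = field[(field["species"] == species) & (field["site_id"] == site)]
                field_present = bool((f_sub["category"] != "absent").any()) if not f_sub.empty else False
                edna_present = bool(
                    species in table.index
                    and site in table.columns
                    and table.loc[species, site] > 0
                )
                if field_present and edna_present:
                    status = "both"
                elif field_present:
                    status = "field_only"
                elif edna_present:
                    status = "edna_only"
                else:
                    status = "neither"
                rows.append(
                    {"marker": marker, "species": species, "site_id": site, "status": status}
                )
    return pd.DataFrame(rows)
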