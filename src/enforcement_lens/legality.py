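"""Forest Code balance and potentially-illegal-deforestation screening.

A deforestation patch inside a registered landholding is *potentially
illegal* when it falls on a riparian preservation strip (APP) along a
stream, or when its holding carries a Forest Code deficit — native
vegetation below the Legal Reserve requirement (80% of the holding in the
Amazon forest zone).  Patches smaller than the minimum mapping unit
(6.25 ha, the effective resolution of annual wall-to-wall deforestation
mapping) are not assessed.  Notices are attributed to holdings by
point-in-polygon and count as deforestation-related only when issued after
(or in the year of) a clearing in that holding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .grid import GridSpec

__all__ = [
    "RuleConfig",
    "Landholding",
    "ProtectedArea",
    "DeforestationPatch",
    "FCBalance",
    "derive_app_zones",
    "compute_fc_balance",
    "compute_fc_balances",
    "classify_patches",
    "attribute_notices",
    "protected_overlap_flags",
    "land_category_breakdown",
    "illegality_enforcement_series",
]

log = logging.getLogger(__name__)

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds of the legality rules.

    mmu_ha : minimum mapping unit; patches below it are not assessed.
    lr_requirement : Legal Reserve fraction of the holding that must stay
        native (0.80 in the Amazon forest zone).
    overlap_threshold : protected-area overlap fraction above which a
        holding is flagged as potential public-land appropriation.
    app_buffer_m : riparian buffer half-width around streams.
    """

    mmu_ha: float = 6.25
    lr_requirement: float = 0.80
    overlap_threshold: float = 0.25
    app_buffer_m: float = 30.0

    def __post_init__(self) -> None:
        if self.mmu_ha <= 0 or self.app_buffer_m <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0 < self.lr_requirement < 1 or not 0 < self.overlap_threshold < 1:
            raise ValueError("fractions must be in (0, 1)")


@dataclass
class Landholding:
    holding_id: str
    polygon: BaseGeometry
    category: str = "landholding"  # landholding | settlement | traditional_community

    @property
    def area_ha(self) -> float:
        return self.polygon.area / M2_PER_HA


@dataclass
class ProtectedArea:
    pa_id: str
    polygon: BaseGeometry
    pa_class: str  # conservation_unit | indigenous_land


@dataclass
class DeforestationPatch:
    patch_id: str
    polygon: BaseGeometry
    year: int

    @property
    def area_ha(self) -> float:
        return self.polygon.area / M2_PER_HA


@dataclass
class FCBalance:
    """Per-holding Forest Code accounting."""

    holding_id: str
    area_ha: float
    native_fraction: float
    lr_requirement: float
    deficit_ha: float = field(init=False)
    compliant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.deficit_ha = max(0.0, (self.lr_requirement - self.native_fraction)) * self.area_ha
        self.compliant = self.deficit_ha == 0.0


def derive_app_zones(streams, rules: RuleConfig, widths=None) -> BaseGeometry:
    """Union of riparian buffers around the stream polylines.

    ``widths`` optionally gives a per-stream buffer half-width (metres),
    overriding ``rules.app_buffer_m``; flat caps keep strip areas exact for
    straight reaches.
    """
    streams = list(streams)
    if widths is None:
        widths = [rules.app_buffer_m] * len(streams)
    if any(w <= 0 for w in widths):
        raise ValueError("buffer width must be > 0")
    if not streams:
        return shapely.geometry.Polygon()
    return unary_union([s.buffer(w, cap_style="flat") for s, w in zip(streams, widths)])


def compute_fc_balance(
    holding: Landholding, native_map: np.ndarray, grid: GridSpec, rules: RuleConfig
) -> FCBalance:
    """FC balance of one holding from the binary native-vegetation raster.

    native_fraction is the share of raster cells whose centre falls in the
    holding that are native (value 1); cells flagged nodata (255) are
    excluded.
    """
    xs, ys = grid.cell_centers()
    minx, miny, maxx, maxy = holding.polygon.bounds
    cs = grid.cell_size_m
    x0, y0 = grid.origin
    c0 = max(int((minx - x0) // cs), 0)
    c1 = min(int((maxx - x0) // cs) + 1, grid.n_cols)
    r0 = max(int((miny - y0) // cs), 0)
    r1 = min(int((maxy - y0) // cs) + 1, grid.n_rows)
    if c0 >= c1 or r0 >= r1:
        raise ValueError(f"holding {holding.holding_id} lies outside the raster extent")
    sub_x = xs[r0:r1, c0:c1]
    sub_y = ys[r0:r1, c0:c1]
    inside = shapely.contains_xy(holding.polygon, sub_x.ravel(), sub_y.ravel()).reshape(sub_x.shape)
    vals = native_map[r0:r1, c0:c1][inside]
    vals = vals[vals != 255]
    if vals.size == 0:
        raise ValueError(f"holding {holding.holding_id} covers no raster cells")
    native_fraction = float((vals == 1).mean())
    return FCBalance(
        holding_id=holding.holding_id,
        area_ha=holding.area_ha,
        native_fraction=native_fraction,
        lr_requirement=rules.lr_requirement,
    )


def compute_fc_balances(holdings, native_map, grid, rules) -> dict[str, FCBalance]:
    return {h.holding_id: compute_fc_balance(h, native_map, grid, rules) for h in holdings}


def _assign_holding(patch: DeforestationPatch, holdings, tree: STRtree) -> str | None:
    """Largest-overlap assignment with a representative-point fallback."""
    idx = tree.query(patch.polygon, predicate="intersects")
    best, best_area = None, 0.0
    for i in idx:
        a = patch.polygon.intersection(holdings[i].polygon).area
        if a > best_area:
            best, best_area = holdings[i], a
    if best is not None:
        if best_area < patch.polygon.area:
            log.debug("patch %s straddles holdings; assigned to %s", patch.patch_id, best.holding_id)
        return best.holding_id
    pt = patch.polygon.representative_point()
    for i in tree.query(pt, predicate="intersects"):
        return holdings[i].holding_id
    return None


def classify_patches(
    patches,
    holdings,
    balances: dict[str, FCBalance],
    app_zones: BaseGeometry,
    rules: RuleConfig,
) -> pd.DataFrame:
    """Label each in-holding patch.

    Labels: ``below_mmu`` (area under the minimum mapping unit),
    ``potentially_illegal`` with reason ``riparian_app`` (intersects the
    riparian buffer; takes precedence) or ``lr_deficit`` (holding is
    non-compliant), else ``presumed_legal``.  Patches outside every holding
    get a null label (they are screened per land category, not here).
    """
    holdings = list(holdings)
    tree = STRtree([h.polygon for h in holdings])
    rows = []
    for p in patches:
        hid = _assign_holding(p, holdings, tree)
        if hid is None:
            rows.append((p.patch_id, p.year, p.area_ha, None, pd.NA, pd.NA))
            continue
        if p.area_ha < rules.mmu_ha:
            label, reason = "below_mmu", "none"
        elif not app_zones.is_empty and p.polygon.intersects(app_zones):
            label, reason = "potentially_illegal", "riparian_app"
        elif not balances[hid].compliant:
            label, reason = "potentially_illegal", "lr_deficit"
        else:
            label, reason = "presumed_legal", "none"
        rows.append((p.patch_id, p.year, p.area_ha, hid, label, reason))
    return pd.DataFrame(
        rows, columns=["patch_id", "year", "area_ha", "holding_id", "label", "reason"]
    )


def attribute_notices(notices: pd.DataFrame, patches, holdings) -> pd.DataFrame:
    """Link geolocated notices to holdings and flag deforestation relevance.

    A notice links to the holding containing its point; the link is
    deforestation-related when that holding holds at least one patch with
    ``patch.year <= notice year`` — enforcement that follows clearing, at
    year granularity.
    """
    holdings = list(holdings)
    tree = STRtree([h.polygon for h in holdings])
    patch_years: dict[str, list[int]] = {}
    htree_assign = tree  # patches assigned the same way as in classify
    for p in patches:
        hid = _assign_holding(p, holdings, htree_assign)
        if hid is not None:
            patch_years.setdefault(hid, []).append(p.year)
    rows = []
    for rec in notices.itertuples():
        x, y = getattr(rec, "x", np.nan), getattr(rec, "y", np.nan)
        year = pd.Timestamp(rec.date).year
        if pd.isna(x) or pd.isna(y):
            rows.append((rec.record_id, year, None, False))
            continue
        hit = tree.query(shapely.points(x, y), predicate="intersects")
        if len(hit) == 0:
            rows.append((rec.record_id, year, None, False))
            continue
        hid = holdings[hit[0]].holding_id
        related = any(py <= year for py in patch_years.get(hid, []))
        rows.append((rec.record_id, year, hid, related))
    return pd.DataFrame(rows, columns=["record_id", "year", "holding_id", "deforestation_related"])


def protected_overlap_flags(holdings, protected_areas, rules: RuleConfig) -> pd.DataFrame:
    """Per-holding overlap fraction with protected areas and a strict-> flag."""
    pa_union = unary_union([_fix(pa.polygon) for pa in protected_areas]) if protected_areas else shapely.geometry.Polygon()
    rows = []
    for h in holdings:
        poly = _fix(h.polygon)
        frac = 0.0 if pa_union.is_empty else poly.intersection(pa_union).area / poly.area
        rows.append((h.holding_id, frac, frac > rules.overlap_threshold))
    return pd.DataFrame(rows, columns=["holding_id", "overlap_fraction", "flagged"])


def _fix(geom: BaseGeometry) -> BaseGeometry:
    if not geom.is_valid:
        repaired = geom.buffer(0)
        if repaired.is_empty:
            raise ValueError("invalid geometry could not be repaired")
        log.warning("repaired invalid geometry by zero-buffer")
        return repaired
    return geom


_CATEGORY_ORDER = ["indigenous_land", "conservation_unit", "settlement", "landholding", "undesignated"]


def land_category_breakdown(patches, holdings, protected_areas, settlements, region) -> pd.DataFrame:
    """Annual deforested area (ha) per land category.

    Overlapping claims are resolved by precedence indigenous land >
    conservation unit > settlement > private landholding > undesignated, so
    each square metre is counted once and per-year totals conserve total
    patch area.
    """
    layers = {
        "indigenous_land": unary_union(
            [pa.polygon for pa in protected_areas if pa.pa_class == "indigenous_land"] or [shapely.geometry.Polygon()]
        ),
        "conservation_unit": unary_union(
            [pa.polygon for pa in protected_areas if pa.pa_class == "conservation_unit"] or [shapely.geometry.Polygon()]
        ),
        "settlement": unary_union(list(settlements) or [shapely.geometry.Polygon()]),
        "landholding": unary_union([h.polygon for h in holdings] or [shapely.geometry.Polygon()]),
    }
    years = sorted({p.year for p in patches})
    out = pd.DataFrame(0.0, index=years, columns=_CATEGORY_ORDER)
    for p in patches:
        rem = p.polygon.intersection(region)
        for cat in _CATEGORY_ORDER[:-1]:
            if rem.is_empty:
                break
            part = rem.intersection(layers[cat])
            if not part.is_empty:
                out.loc[p.year, cat] += part.area / M2_PER_HA
                rem = rem.difference(layers[cat])
        if not rem.is_empty:
            out.loc[p.year, "undesignated"] += rem.area / M2_PER_HA
    out.index.name = "year"
    return out


def illegality_enforcement_series(
    labels: pd.DataFrame, attribution: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Annual illegality-with-enforcement series plus an overall summary.

    Per year ``y``: the share of potentially-illegal deforested area in
    patches of year ``y`` whose holding received a deforestation-related
    notice in some year >= ``y`` (areal series), and the share of holdings
    with an above-MMU patch in year ``y`` that received a
    deforestation-related notice that year (holding series).  The summary
    reports, over all years, the fraction of deforesting holdings (>=1
    above-MMU patch) ever reached by a deforestation-related notice.
    """
    rel = attribution[attribution["deforestation_related"] & attribution["holding_id"].notna()]
    notice_years: dict[str, list[int]] = rel.groupby("holding_id")["year"].agg(list).to_dict()
    assessed = labels[labels["label"].notna() & (labels["label"] != "below_mmu")]
    illegal = labels[labels["label"] == "potentially_illegal"]

    years = sorted(labels["year"].unique())
    rows = []
    for y in years:
        ill_y = illegal[illegal["year"] == y]
        if len(ill_y) and ill_y["area_ha"].sum() > 0:
            noticed = ill_y["holding_id"].map(
                lambda h, y=y: any(ny >= y for ny in notice_years.get(h, []))
            )
            areal = 100.0 * ill_y.loc[noticed, "area_ha"].sum() / ill_y["area_ha"].sum()
        else:
            areal = np.nan
        deforesting = set(assessed.loc[assessed["year"] == y, "holding_id"])
        if deforesting:
            hit = sum(
                1 for h in deforesting if any(ny == y for ny in notice_years.get(h, []))
            )
            holding_pct = 100.0 * hit / len(deforesting)
        else:
            holding_pct = np.nan
        rows.append((y, areal, holding_pct))
    series = pd.DataFrame(
        rows, columns=["year", "pct_illegal_area_noticed", "pct_holdings_noticed"]
    ).set_index("year")

    all_deforesting = set(assessed["holding_id"])
    ever_noticed = sum(1 for h in all_deforesting if h in notice_years)
    summary = {
        "n_deforesting_holdings": len(all_deforesting),
        "n_noticed_holdings": ever_noticed,
        "pct_deforesting_holdings_noticed": (
            100.0 * ever_noticed / len(all_deforesting) if all_deforesting else np.nan
        ),
    }
    return series, summary
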