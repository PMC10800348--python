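"""Synthetic study region with known ground truth.

Emulates the statistical structure of the real inputs of an Amazon
enforcement analysis — a gapless cadastre of landholdings, protected areas,
streams, yearly deforestation patches with a log-normal size distribution, a
configurable fraction of patches made illegal (riparian placement or Legal
Reserve deficit), enforcement notices spatially coupled to deforestation
with tunable strength, incomplete geolocation, a filed→judged→paid
prosecution funnel and an expenditure series — so every downstream stage can
be tested against exact truth.

All randomness flows from one seed through named sub-streams (holdings,
protected, streams, patches, notices, prosecution, expenditure), so a fixed
seed reproduces the landscape bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, box
from shapely.strtree import STRtree

from .grid import GridSpec
from .legality import (
    DeforestationPatch,
    Landholding,
    ProtectedArea,
    RuleConfig,
    derive_app_zones,
)
from .records import LEGAL_AMAZON_STATES

__all__ = [
    "LandscapeConfig",
    "SyntheticLandscape",
    "EnforcementBundle",
    "generate_landscape",
    "generate_enforcement",
]

log = logging.getLogger(__name__)

M2_PER_HA = 10_000.0

#: Named randomness sub-streams hanging off the single config seed.
_STREAMS = {
    "holdings": 0,
    "protected": 1,
    "streams": 2,
    "patches": 3,
    "native": 4,
    "notices": 5,
    "prosecution": 6,
    "expenditure": 7,
}

def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass(frozen=True)
class LandscapeConfig:
    """Knobs of the synthetic study region.

    Defaults describe a 50 km x 50 km desk-scale region with 60 holdings, a
    mid-study geolocation rate of 60%, a prosecution funnel whose
    filed→paid product is 0.17, and moderately coupled enforcement.
    """

    region_width_m: float = 50_000.0
    region_height_m: float = 50_000.0
    n_holdings: int = 60
    n_protected: int = 3
    protected_area_fraction: float = 0.12
    stream_count: int = 5
    years: tuple[int, int] = (2010, 2019)  # inclusive
    patches_per_year: int = 50
    patch_area_lognormal_params: tuple[float, float] = (math.log(30.0), 0.8)  # log-ha
    illegal_fraction_target: float = 0.5
    app_placement_share: float = 0.5
    coupling_rho: float = 0.7
    jitter_sigma_m: float = 1_000.0
    geolocation_prob: float = 0.6
    notices_per_year: int = 40
    embargo_share: float = 0.35
    confiscation_share: float = 0.20
    flora_theme_share: float = 0.95
    prosecution_transition_probs: tuple[float, float] = (0.5, 0.34)
    raster_cell_m: float = 100.0
    deficit_holding_fraction: float = 0.25
    deficit_native_fraction: float = 0.60
    expenditure_base_brl: float = 100e6
    rules: RuleConfig = field(default_factory=RuleConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "protected_area_fraction": self.protected_area_fraction,
            "illegal_fraction_target": self.illegal_fraction_target,
            "app_placement_share": self.app_placement_share,
            "coupling_rho": self.coupling_rho,
            "geolocation_prob": self.geolocation_prob,
            "embargo_share": self.embargo_share,
            "confiscation_share": self.confiscation_share,
            "flora_theme_share": self.flora_theme_share,
            "deficit_holding_fraction": self.deficit_holding_fraction,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for p in self.prosecution_transition_probs:
            if not 0 <= p <= 1:
                raise ValueError("transition probabilities must be in [0, 1]")
        if min(self.n_holdings, self.n_protected, self.stream_count,
               self.patches_per_year, self.notices_per_year) < 0:
            raise ValueError("counts must be >= 0")
        if self.region_width_m <= 0 or self.region_height_m <= 0:
            raise ValueError("region dimensions must be > 0")
        if self.years[1] < self.years[0]:
            raise ValueError("year range is empty")
        if self.n_holdings < 1:
            raise ValueError("need at least one holding")
        if self.illegal_fraction_target > 0:
            riparian_ok = self.stream_count > 0 and self.app_placement_share > 0
            deficit_ok = self.deficit_holding_fraction > 0 and self.app_placement_share < 1
            if self.stream_count == 0 and self.app_placement_share >= 1:
                raise ValueError(
                    "illegal_fraction_target > 0 but no streams and zero LR-deficit share: "
                    "illegality unachievable"
                )
            if not (riparian_ok or deficit_ok):
                raise ValueError("no route to place illegal patches; adjust config")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class SyntheticLandscape:
    config: LandscapeConfig
    region: Polygon
    holdings: list[Landholding]
    deficit_holding_ids: set[str]
    protected_areas: list[ProtectedArea]
    streams: list[LineString]
    app_zones: shapely.geometry.base.BaseGeometry
    patches: list[DeforestationPatch]
    grid: GridSpec
    native_map: np.ndarray  # uint8: 1 native, 0 cleared, 255 nodata
    ground_truth: pd.DataFrame  # patch_id, year, area_ha, holding_id, true_label, true_reason


@dataclass
class EnforcementBundle:
    records: pd.DataFrame
    prosecutions: pd.DataFrame
    expenditure: pd.DataFrame
    price_index: pd.Series
    notice_truth: pd.DataFrame  # record_id, coupled, target_patch_id, geolocated


# --------------------------------------------------------------------------
# landscape


def _voronoi_holdings(rng: np.random.Generator, cfg: LandscapeConfig, region: Polygon) -> list[Landholding]:
    """Gapless non-overlapping cadastre: Voronoi cells of random seed points.

    Seed points are mirrored across the four region edges so every interior
    cell is finite, then cells are clipped to the region rectangle.
    """
    from scipy.spatial import Voronoi

    W, H = cfg.region_width_m, cfg.region_height_m
    pts = rng.uniform((0, 0), (W, H), size=(cfg.n_holdings, 2))
    mirrored = np.vstack(
        [
            pts,
            pts * [-1, 1],                   # reflect across x=0
            pts * [1, -1],                   # across y=0
            [2 * W, 0] + pts * [-1, 1],      # across x=W
            [0, 2 * H] + pts * [1, -1],      # across y=H
        ]
    )
    if cfg.n_holdings == 1:
        return [Landholding("H000", region)]
    vor = Voronoi(mirrored)
    holdings = []
    for i in range(cfg.n_holdings):
        reg = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[reg]).intersection(region)
        holdings.append(Landholding(f"H{i:03d}", poly))
    return holdings


def _protected_areas(rng: np.random.Generator, cfg: LandscapeConfig) -> list[ProtectedArea]:
    if cfg.n_protected == 0 or cfg.protected_area_fraction == 0:
        return []
    W, H = cfg.region_width_m, cfg.region_height_m
    target = cfg.protected_area_fraction * W * H / cfg.n_protected
    out = []
    for i in range(cfg.n_protected):
        aspect = rng.uniform(0.5, 2.0)
        w = min(math.sqrt(target * aspect), 0.9 * W)
        h = min(target / w, 0.9 * H)
        x = rng.uniform(0, W - w)
        y = rng.uniform(0, H - h)
        cls = "indigenous_land" if i % 2 == 0 else "conservation_unit"
        out.append(ProtectedArea(f"PA{i:02d}", box(x, y, x + w, y + h), cls))
    return out


def _streams(rng: np.random.Generator, cfg: LandscapeConfig) -> list[LineString]:
    W, H = cfg.region_width_m, cfg.region_height_m
    n_vert = 41
    xs = np.linspace(0, W, n_vert)
    out = []
    for _ in range(cfg.stream_count):
        y = np.empty(n_vert)
        y[0] = rng.uniform(0.1 * H, 0.9 * H)
        steps = rng.normal(0, H / 40.0, size=n_vert - 1)
        y[1:] = np.clip(y[0] + np.cumsum(steps), 0.02 * H, 0.98 * H)
        out.append(LineString(np.column_stack([xs, y])))
    return out


def _rect_at(center: tuple[float, float], area_m2: float, rng: np.random.Generator) -> Polygon:
    aspect = rng.uniform(1.0, 3.0)
    w = math.sqrt(area_m2 * aspect)
    h = area_m2 / w
    if rng.random() < 0.5:
        w, h = h, w
    cx, cy = center
    return box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def _clear_to_deficit(
    rng: np.random.Generator, native: np.ndarray, grid: GridSpec, holding: Landholding, target: float
) -> None:
    """Pre-clear a holding's native cells down to the target native fraction."""
    xs, ys = grid.cell_centers()
    inside = shapely.contains_xy(holding.polygon, xs.ravel(), ys.ravel()).reshape(xs.shape)
    rows, cols = np.nonzero(inside)
    n = len(rows)
    n_clear = int(round((1.0 - target) * n))
    pick = rng.choice(n, size=n_clear, replace=False)
    native[rows[pick], cols[pick]] = 0


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Build the full synthetic region; deterministic for a fixed seed."""
    cfg = config
    W, H = cfg.region_width_m, cfg.region_height_m
    region = box(0, 0, W, H)

    rng_h = _rng(cfg.seed, "holdings")
    holdings = _voronoi_holdings(rng_h, cfg, region)
    n_def = int(round(cfg.deficit_holding_fraction * cfg.n_holdings))
    if cfg.illegal_fraction_target > 0 and cfg.app_placement_share < 1:
        n_def = max(n_def, 1)
    deficit_ids = set(
        holdings[i].holding_id for i in rng_h.choice(cfg.n_holdings, size=n_def, replace=False)
    ) if n_def else set()

    protected = _protected_areas(_rng(cfg.seed, "protected"), cfg)
    streams = _streams(_rng(cfg.seed, "streams"), cfg)
    app = derive_app_zones(streams, cfg.rules) if streams else Polygon()

    grid = GridSpec(
        origin=(0.0, 0.0),
        cell_size_m=cfg.raster_cell_m,
        n_cols=int(round(W / cfg.raster_cell_m)),
        n_rows=int(round(H / cfg.raster_cell_m)),
    )
    native = np.ones(grid.shape, dtype=np.uint8)
    rng_nat = _rng(cfg.seed, "native")
    by_id = {h.holding_id: h for h in holdings}
    for hid in sorted(deficit_ids):
        _clear_to_deficit(rng_nat, native, grid, by_id[hid], cfg.deficit_native_fraction)

    patches, truth = _place_patches(cfg, holdings, deficit_ids, app, streams, region)
    return SyntheticLandscape(
        config=cfg,
        region=region,
        holdings=holdings,
        deficit_holding_ids=deficit_ids,
        protected_areas=protected,
        streams=streams,
        app_zones=app,
        patches=patches,
        grid=grid,
        native_map=native,
        ground_truth=truth,
    )


def _place_patches(cfg, holdings, deficit_ids, app, streams, region):
    rng = _rng(cfg.seed, "patches")
    tree = STRtree([h.polygon for h in holdings])
    compliant = [h for h in holdings if h.holding_id not in deficit_ids]
    deficient = [h for h in holdings if h.holding_id in deficit_ids]
    mu, sigma = cfg.patch_area_lognormal_params
    riparian_ok = not app.is_empty and cfg.app_placement_share > 0
    deficit_ok = bool(deficient) and cfg.app_placement_share < 1

    patches: list[DeforestationPatch] = []
    rows = []
    k = 0
    for year in cfg.year_list:
        for _ in range(cfg.patches_per_year):
            area_ha = float(np.exp(rng.normal(mu, sigma)))
            area_m2 = area_ha * M2_PER_HA
            if area_ha < cfg.rules.mmu_ha:
                intent = "below_mmu"
            elif rng.random() < cfg.illegal_fraction_target:
                if riparian_ok and (not deficit_ok or rng.random() < cfg.app_placement_share):
                    intent = "riparian"
                else:
                    intent = "deficit"
            else:
                intent = "legal"
            poly, hid, label, reason = _place_one(
                rng, intent, area_m2, cfg, holdings, tree, compliant, deficient, app, streams, region
            )
            pid = f"D{year}-{k:04d}"
            k += 1
            patches.append(DeforestationPatch(pid, poly, year))
            rows.append((pid, year, poly.area / M2_PER_HA, hid, label, reason))
    truth = pd.DataFrame(
        rows, columns=["patch_id", "year", "area_ha", "holding_id", "true_label", "true_reason"]
    )
    return patches, truth


def _place_one(rng, intent, area_m2, cfg, holdings, tree, compliant, deficient, app, streams, region):
    """Rejection-sample a placement realizing the intended legality.

    If the cap is exhausted, the patch is placed uniformly and the label is
    derived from the realized geometry so the ground truth stays exact.
    """
    max_tries = 60
    poly = None
    for _ in range(max_tries):
        if intent == "riparian":
            pt = _point_on_stream(streams, rng, cfg)
            cand = _rect_at(pt, area_m2, rng)
            # centred on the stream spine so APP intersection is robust
            if cand.within(region) and cand.intersects(app):
                poly = cand
                break
        elif intent == "deficit":
            h = deficient[rng.integers(len(deficient))]
            cand = _rect_in_holding(rng, h, area_m2)
            if cand is not None and not cand.intersects(app):
                poly = cand
                break
        elif intent == "legal":
            h = compliant[rng.integers(len(compliant))] if compliant else None
            if h is None:
                break
            cand = _rect_in_holding(rng, h, area_m2)
            if cand is not None and not cand.intersects(app):
                poly = cand
                break
        else:  # below_mmu: anywhere inside the region
            cx = rng.uniform(0, cfg.region_width_m)
            cy = rng.uniform(0, cfg.region_height_m)
            cand = _rect_at((cx, cy), area_m2, rng)
            if cand.within(region):
                poly = cand
                break
    if poly is None:
        # fallback: uniform placement, label derived from realized geometry
        while True:
            cx = rng.uniform(0, cfg.region_width_m)
            cy = rng.uniform(0, cfg.region_height_m)
            cand = _rect_at((cx, cy), area_m2, rng)
            if cand.within(region):
                poly = cand
                break
    hid = _max_overlap_holding(poly, holdings, tree)
    area_ha = poly.area / M2_PER_HA
    if area_ha < cfg.rules.mmu_ha:
        label, reason = "below_mmu", "none"
    elif not app.is_empty and poly.intersects(app):
        label, reason = "potentially_illegal", "riparian_app"
    elif hid in {h.holding_id for h in deficient}:
        label, reason = "potentially_illegal", "lr_deficit"
    else:
        label, reason = "presumed_legal", "none"
    return poly, hid, label, reason


def _point_on_stream(streams, rng, cfg) -> tuple[float, float]:
    """Random point along a random stream, kept off the region border."""
    W, H = cfg.region_width_m, cfg.region_height_m
    for _ in range(50):
        line = streams[rng.integers(len(streams))]
        pt = shapely.line_interpolate_point(line, rng.random(), normalized=True)
        if 0.02 * W < pt.x < 0.98 * W and 0.02 * H < pt.y < 0.98 * H:
            return (pt.x, pt.y)
    return (W / 2, H / 2)


def _rect_in_holding(rng, holding: Landholding, area_m2: float) -> Polygon | None:
    minx, miny, maxx, maxy = holding.polygon.bounds
    for _ in range(30):
        cx = rng.uniform(minx, maxx)
        cy = rng.uniform(miny, maxy)
        cand = _rect_at((cx, cy), area_m2, rng)
        if cand.within(holding.polygon):
            return cand
    return None


def _max_overlap_holding(poly, holdings, tree) -> str | None:
    idx = tree.query(poly, predicate="intersects")
    best, best_area = None, 0.0
    for i in idx:
        a = poly.intersection(holdings[i].polygon).area
        if a > best_area:
            best, best_area = holdings[i].holding_id, a
    return best


# --------------------------------------------------------------------------
# enforcement records


def generate_enforcement(landscape: SyntheticLandscape, config: LandscapeConfig | None = None) -> EnforcementBundle:
    """Notices coupled to deforestation, sanction spin-offs, funnel, budget."""
    cfg = config or landscape.config
    rng = _rng(cfg.seed, "notices")
    W, H = cfg.region_width_m, cfg.region_height_m
    by_year: dict[int, list[DeforestationPatch]] = {}
    for p in landscape.patches:
        by_year.setdefault(p.year, []).append(p)

    rec_rows = []
    truth_rows = []
    for year in cfg.year_list:
        pool = by_year.get(year, [])
        if cfg.coupling_rho > 0 and not pool:
            log.warning("no patches in %d; coupled notices fall back to uniform", year)
        for i in range(cfg.notices_per_year):
            coupled = rng.random() < cfg.coupling_rho and bool(pool)
            target = None
            if coupled:
                target = pool[rng.integers(len(pool))]
                cx, cy = target.polygon.centroid.x, target.polygon.centroid.y
                x = cx + rng.normal(0, cfg.jitter_sigma_m)
                y = cy + rng.normal(0, cfg.jitter_sigma_m)
            else:
                x = rng.uniform(0, W)
                y = rng.uniform(0, H)
            geolocated = rng.random() < cfg.geolocation_prob
            theme = "flora" if rng.random() < cfg.flora_theme_share else "other"
            state = LEGAL_AMAZON_STATES[rng.integers(len(LEGAL_AMAZON_STATES))]
            day = int(rng.integers(0, 365))
            date = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=day)
            fine = float(np.exp(rng.normal(math.log(50_000.0), 1.0)))
            rid = f"IN-{year}-{i:05d}"
            pid = f"P-{year}-{i:05d}"
            rec_rows.append(
                (rid, pid, date, state, theme, "infraction_notice", fine,
                 x if geolocated else np.nan, y if geolocated else np.nan)
            )
            truth_rows.append((rid, coupled, target.patch_id if target else None, geolocated))
            if rng.random() < cfg.embargo_share:
                rec_rows.append(
                    (f"EM-{year}-{i:05d}", pid, date + pd.Timedelta(days=int(rng.integers(0, 30))),
                     state, theme, "embargo", 0.0,
                     x if geolocated else np.nan, y if geolocated else np.nan)
                )
            if rng.random() < cfg.confiscation_share:
                rec_rows.append(
                    (f"CF-{year}-{i:05d}", pid, date + pd.Timedelta(days=int(rng.integers(0, 30))),
                     state, theme, "confiscation_destruction", 0.0,
                     x if geolocated else np.nan, y if geolocated else np.nan)
                )
    records = pd.DataFrame(
        rec_rows,
        columns=["record_id", "process_id", "date", "state", "theme",
                 "sanction_type", "fine_value_brl", "x", "y"],
    )
    notice_truth = pd.DataFrame(
        truth_rows, columns=["record_id", "coupled", "target_patch_id", "geolocated"]
    )

    prosecutions = _funnel(records, cfg)
    expenditure, price_index = _budget(cfg)
    return EnforcementBundle(records, prosecutions, expenditure, price_index, notice_truth)


def _funnel(records: pd.DataFrame, cfg: LandscapeConfig) -> pd.DataFrame:
    """filed→judged→paid prosecution funnel, one terminal row per process."""
    rng = _rng(cfg.seed, "prosecution")
    p_judge, p_pay = cfg.prosecution_transition_probs
    notices = records[records["sanction_type"] == "infraction_notice"]
    rows = []
    for rec in notices.itertuples():
        filed = rec.date
        stage, stage_date, paid = "filed", filed, 0.0
        if rng.random() < p_judge:
            stage = "judged_first"
            stage_date = filed + pd.Timedelta(days=int(rng.integers(180, 540)))
            if rng.random() < p_pay:
                stage = "paid"
                stage_date = stage_date + pd.Timedelta(days=int(rng.integers(90, 360)))
                paid = rec.fine_value_brl
        rows.append((rec.process_id, filed, stage, stage_date, paid))
    return pd.DataFrame(
        rows, columns=["process_id", "filed_date", "stage", "stage_date", "amount_paid_brl"]
    )


def _budget(cfg: LandscapeConfig) -> tuple[pd.DataFrame, pd.Series]:
    rng = _rng(cfg.seed, "expenditure")
    items = ["2943", "6124", "214N"]
    rows = []
    idx_vals = {}
    y0 = cfg.years[0]
    for year in cfg.year_list:
        total = cfg.expenditure_base_brl * float(rng.lognormal(0.0, 0.15))
        shares = rng.dirichlet(np.ones(len(items)))
        for item, s in zip(items, shares):
            rows.append((year, total * s, "ibama", item))
        idx_vals[year] = 1.04 ** (year - y0)  # steady 4%/yr inflation
    expenditure = pd.DataFrame(rows, columns=["year", "nominal_brl", "agency", "budget_item"])
    price_index = pd.Series(idx_vals, name="index")
    price_index.index.name = "year"
    return expenditure, price_index
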