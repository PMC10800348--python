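"""End-to-end orchestration: simulate → ingest → spatial match → legality →
efficiency → report, driven by one YAML config and one seed.

Exactly one input route must be active: a ``synthetic`` block (landscape
generator parameters) or an ``inputs`` block (paths to previously written
layers and tables).  Every run writes the same set of CSV outputs plus a
JSON manifest carrying the config hash, the seed and per-stage counts, so a
run can be reproduced byte for byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .efficiency import deflate_convert, operational_efficiency
from .io import (
    CSV_FLOAT_FORMAT,
    read_holdings,
    read_native_map,
    read_patches,
    read_protected_areas,
    read_records_csv,
    read_streams,
    write_landscape,
    write_records_csv,
)
from .legality import (
    RuleConfig,
    attribute_notices,
    classify_patches,
    compute_fc_balances,
    derive_app_zones,
    illegality_enforcement_series,
    land_category_breakdown,
    protected_overlap_flags,
)
from .records import FilterConfig, annual_indicators, ingest_records, percent_change, round_percent
from .spatial import SpatialMatchConfig, match_series
from .synthetic import LandscapeConfig, generate_enforcement, generate_landscape

log = logging.getLogger(__name__)

OUTPUT_FILES = (
    "indicators.csv",
    "spatial_match.csv",
    "legality_labels.csv",
    "illegality_series.csv",
    "land_breakdown.csv",
    "efficiency_oe.csv",
)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    synthetic: LandscapeConfig | None = None
    inputs: dict | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    spatial: SpatialMatchConfig = field(default_factory=lambda: SpatialMatchConfig(bandwidth_m=2_000.0))
    rules: RuleConfig = field(default_factory=RuleConfig)
    base_year: int | None = None
    exchange_rate_brl_per_usd: float = 5.0
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'synthetic' and 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        kwargs: dict = {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "rules" in raw:
                syn.setdefault("rules", raw["rules"])
            if "years" in syn:
                syn["years"] = tuple(syn["years"])
            if "rules" in syn and isinstance(syn["rules"], dict):
                syn["rules"] = RuleConfig(**syn["rules"])
            if "seed" in raw:
                syn.setdefault("seed", raw["seed"])
            kwargs["synthetic"] = LandscapeConfig(**syn)
        if "inputs" in raw and raw["inputs"] is not None:
            kwargs["inputs"] = dict(raw["inputs"])
        if "filters" in raw:
            f = dict(raw["filters"])
            if "study_window" in f:
                f["study_window"] = tuple(f["study_window"])
            if "legal_amazon_states" in f:
                f["legal_amazon_states"] = tuple(f["legal_amazon_states"])
            kwargs["filters"] = FilterConfig(**f)
        if "spatial" in raw:
            kwargs["spatial"] = SpatialMatchConfig(**raw["spatial"])
        if "rules" in raw:
            kwargs["rules"] = RuleConfig(**raw["rules"])
        for key in ("base_year", "exchange_rate_brl_per_usd", "out_dir", "seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # run location and verbosity do not affect results
        d.pop("log_level", None)
        blob = json.dumps(d, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(paths: dict):
    base = Path(paths.get("dir", "."))

    def p(name, default):
        return base / paths.get(name, default)

    holdings = read_holdings(p("holdings", "holdings.geojson"))
    protected = read_protected_areas(p("protected_areas", "protected_areas.geojson"))
    streams = read_streams(p("streams", "streams.geojson"))
    patches = read_patches(p("patches", "patches.geojson"))
    grid, native = read_native_map(p("native_map", "native_map.asc"))
    records = read_records_csv(p("records", "records.csv"))
    prosecutions = read_records_csv(p("prosecutions", "prosecutions.csv"))
    expenditure = pd.read_csv(p("expenditure", "expenditure.csv"))
    price_index = pd.read_csv(p("price_index", "price_index.csv")).set_index("year")["index"]
    return holdings, protected, streams, patches, grid, native, records, prosecutions, expenditure, price_index


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the output tables plus the manifest dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "warnings": [],
    }

    stage = "simulate"
    try:
        if config.synthetic is not None:
            land_cfg = dataclasses.replace(config.synthetic, seed=config.seed, rules=config.rules)
            landscape = generate_landscape(land_cfg)
            bundle = generate_enforcement(landscape, land_cfg)
            holdings, protected, streams, patches = (
                landscape.holdings, landscape.protected_areas, landscape.streams, landscape.patches,
            )
            grid, native = landscape.grid, landscape.native_map
            raw_records, prosecutions = bundle.records, bundle.prosecutions
            expenditure, price_index = bundle.expenditure, bundle.price_index
            write_landscape(out_dir / "landscape", landscape)
            write_records_csv(out_dir / "landscape" / "records.csv", raw_records)
            write_records_csv(out_dir / "landscape" / "prosecutions.csv", prosecutions)
            expenditure.to_csv(out_dir / "landscape" / "expenditure.csv", index=False,
                               float_format=CSV_FLOAT_FORMAT)
            price_index.to_frame().to_csv(out_dir / "landscape" / "price_index.csv",
                                          float_format=CSV_FLOAT_FORMAT)
        else:
            (holdings, protected, streams, patches, grid, native,
             raw_records, prosecutions, expenditure, price_index) = _load_inputs(config.inputs)
        manifest["stages"][stage] = {"holdings": len(holdings), "patches": len(patches),
                                     "records": len(raw_records)}

        stage = "ingest"
        records, report = ingest_records(raw_records, config.filters)
        manifest["stages"][stage] = {"retained": len(records), **report}

        stage = "indicators"
        window = config.filters.study_window
        if config.synthetic is not None:
            window = config.synthetic.years
        indicators = annual_indicators(records, prosecutions, window=window)
        manifest["stages"][stage] = {"years": len(indicators)}

        stage = "spatial-match"
        notices = records[records["sanction_type"] == "infraction_notice"]
        geoloc = notices[notices["x"].notna()]
        years_n = pd.to_datetime(geoloc["date"]).dt.year
        annual_fines = {
            int(y): geoloc.loc[years_n == y, ["x", "y"]].to_numpy(float)
            for y in sorted(years_n.unique())
        }
        annual_defor: dict[int, list] = {}
        for p_ in patches:
            annual_defor.setdefault(p_.year, []).append(p_.polygon)
        sm_cfg = dataclasses.replace(config.spatial, cell_size_m=grid.cell_size_m)
        smatch = match_series(annual_fines, annual_defor, sm_cfg, grid)
        manifest["stages"][stage] = {"years": len(smatch)}

        stage = "legality"
        app = derive_app_zones(streams, config.rules)
        balances = compute_fc_balances(holdings, native, grid, config.rules)
        labels = classify_patches(patches, holdings, balances, app, config.rules)
        attribution = attribute_notices(notices, patches, holdings)
        flags = protected_overlap_flags(holdings, protected, config.rules)
        from shapely.geometry import box

        region = box(*grid.extent)
        breakdown = land_category_breakdown(patches, holdings, protected, [], region)
        ill_series, ill_summary = illegality_enforcement_series(labels, attribution)
        manifest["stages"][stage] = {
            "labels": len(labels),
            "flagged_holdings": int(flags["flagged"].sum()),
            **{k: (round(v, 4) if isinstance(v, float) else v) for k, v in ill_summary.items()},
        }

        stage = "efficiency"
        nominal = expenditure.groupby("year")["nominal_brl"].sum()
        base_year = config.base_year if config.base_year is not None else int(nominal.index.max())
        real_usd = deflate_convert(nominal, price_index, base_year, config.exchange_rate_brl_per_usd)
        table = operational_efficiency(real_usd, indicators)
        manifest["stages"][stage] = {"years": len(table.oe), "base_year": base_year}

        stage = "report"
        outputs = {
            "indicators": indicators,
            "spatial_match": smatch,
            "legality_labels": labels,
            "illegality_series": ill_series,
            "land_breakdown": breakdown,
            "efficiency_oe": table.oe,
        }
        for name, df in outputs.items():
            df.to_csv(out_dir / f"{name}.csv", float_format=CSV_FLOAT_FORMAT,
                      index=name != "legality_labels")
        flags.to_csv(out_dir / "protected_overlap_flags.csv", index=False,
                     float_format=CSV_FLOAT_FORMAT)
        summary = report_tables(indicators, window)
        summary.to_csv(out_dir / "summary.csv", float_format=CSV_FLOAT_FORMAT)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except (ConfigError,):
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with the failing stage named
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    outputs["summary"] = summary
    outputs["manifest"] = manifest
    outputs["efficiency_table"] = table
    outputs["illegality_summary"] = ill_summary
    outputs["protected_overlap_flags"] = flags
    return outputs


def report_tables(indicators: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Whole-window totals plus the first-to-last-year percent change.

    Percentages are rounded half-away-from-zero to integers (flagged by the
    ``_pct_rounded`` column name suffix), matching how such series are
    conventionally reported.
    """
    cols = ["notices_count", "embargoes_count", "confiscations_count", "fines_total_brl"]
    rows = {}
    y0, y1 = window
    present = indicators.loc[(indicators.index >= y0) & (indicators.index <= y1)]
    for col in cols:
        total = float(present[col].sum()) if len(present) else 0.0
        first = float(present[col].iloc[0]) if len(present) else np.nan
        last = float(present[col].iloc[-1]) if len(present) else np.nan
        change = (
            round_percent(percent_change(first, last)) if len(present) and first != 0 else np.nan
        )
        rows[col] = {"total": total, "first_year": first, "last_year": last,
                     "change_pct_rounded": change}
    return pd.DataFrame(rows).T
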