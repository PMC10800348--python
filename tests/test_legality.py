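"""Forest Code balance, legality classifier, attribution and overlays."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

from enforcement_lens import (
    DeforestationPatch,
    FCBalance,
    GridSpec,
    Landholding,
    LandscapeConfig,
    ProtectedArea,
    RuleConfig,
    attribute_notices,
    classify_patches,
    compute_fc_balance,
    compute_fc_balances,
    derive_app_zones,
    generate_enforcement,
    generate_landscape,
    illegality_enforcement_series,
    land_category_breakdown,
    protected_overlap_flags,
)

from conftest import binom99, make_records

RULES = RuleConfig()


class TestAppZones:
    def test_straight_strip_area_is_analytic(self):
        stream = LineString([(0, 5000), (10_000, 5000)])  # 10 km reach
        app = derive_app_zones([stream], RULES)  # 30 m half-width
        assert app.area / 1e4 == pytest.approx(60.0, rel=0.01)  # 60 ha strip

    def test_empty_streams_give_empty_geometry(self):
        assert derive_app_zones([], RULES).is_empty

    def test_crossing_streams_union_without_double_count(self):
        a = LineString([(0, 5000), (10_000, 5000)])
        b = LineString([(5000, 0), (5000, 10_000)])
        union = derive_app_zones([a, b], RULES)
        separate = derive_app_zones([a], RULES).area + derive_app_zones([b], RULES).area
        assert union.area < separate
        assert union.area == pytest.approx(separate - 60.0**2, rel=1e-6)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            derive_app_zones([LineString([(0, 0), (1, 1)])], RULES, widths=[0.0])


def square_holding(side_m=1000.0, origin=(0.0, 0.0)):
    x, y = origin
    return Landholding("H1", box(x, y, x + side_m, y + side_m))


def native_raster(grid, fraction, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    native = np.ones(grid.shape, dtype=np.uint8)
    n = grid.n_rows * grid.n_cols
    clear = rng.choice(n, size=int(round((1 - fraction) * n)), replace=False)
    native.ravel()[clear] = 0
    return native


class TestFCBalance:
    grid = GridSpec(origin=(0, 0), cell_size_m=10.0, n_cols=100, n_rows=100)

    def test_above_requirement_is_compliant(self):
        bal = compute_fc_balance(square_holding(), native_raster(self.grid, 0.85), self.grid, RULES)
        assert bal.deficit_ha == 0.0
        assert bal.compliant

    def test_ten_hectare_deficit(self):
        # 100 ha holding with 70 ha native at an 80% requirement -> 10 ha short
        bal = compute_fc_balance(square_holding(), native_raster(self.grid, 0.70), self.grid, RULES)
        assert bal.area_ha == pytest.approx(100.0)
        assert bal.deficit_ha == pytest.approx(10.0, abs=0.01)
        assert not bal.compliant

    def test_fully_native_holding(self):
        bal = compute_fc_balance(square_holding(), np.ones(self.grid.shape, np.uint8), self.grid, RULES)
        assert bal.native_fraction == 1.0
        assert bal.compliant

    def test_holding_outside_raster_raises(self):
        far = Landholding("H2", box(1e6, 1e6, 1e6 + 10, 1e6 + 10))
        with pytest.raises(ValueError, match="outside"):
            compute_fc_balance(far, native_raster(self.grid, 1.0), self.grid, RULES)

    def test_deficit_monotone_in_native_fraction(self):
        deficits = [
            FCBalance("H", 100.0, f, RULES.lr_requirement).deficit_ha
            for f in np.linspace(0, 1, 21)
        ]
        assert all(a >= b for a, b in zip(deficits, deficits[1:]))
        assert deficits[-1] == 0.0


class TestClassifyPatches:
    def setup_method(self):
        self.holdings = [
            Landholding("HA", box(0, 0, 2000, 2000)),
            Landholding("HB", box(2000, 0, 4000, 2000)),
        ]
        self.balances = {
            "HA": FCBalance("HA", 400.0, 0.95, 0.80),  # compliant
            "HB": FCBalance("HB", 400.0, 0.60, 0.80),  # deficient
        }
        self.app = derive_app_zones([LineString([(0, 1900), (4000, 1900)])], RULES)

    def classify(self, patches):
        return classify_patches(patches, self.holdings, self.balances, self.app, RULES)

    def test_small_patch_is_below_mmu_everywhere(self):
        patch = DeforestationPatch("p", box(100, 1850, 350, 2050), 2015)  # 5 ha, on the APP
        out = self.classify([patch])
        assert out.loc[0, "label"] == "below_mmu"
        assert out.loc[0, "reason"] == "none"

    def test_riparian_patch_in_compliant_holding(self):
        patch = DeforestationPatch("p", box(100, 1700, 600, 1950), 2015)  # 12.5 ha crossing APP
        out = self.classify([patch])
        assert out.loc[0, "holding_id"] == "HA"
        assert out.loc[0, "label"] == "potentially_illegal"
        assert out.loc[0, "reason"] == "riparian_app"

    def test_clean_patch_in_compliant_holding_presumed_legal(self):
        patch = DeforestationPatch("p", box(100, 100, 600, 350), 2015)
        out = self.classify([patch])
        assert out.loc[0, "label"] == "presumed_legal"

    def test_deficit_holding_patch(self):
        patch = DeforestationPatch("p", box(2100, 100, 2600, 350), 2015)
        out = self.classify([patch])
        assert out.loc[0, "holding_id"] == "HB"
        assert out.loc[0, "label"] == "potentially_illegal"
        assert out.loc[0, "reason"] == "lr_deficit"

    def test_straddling_patch_assigned_by_largest_overlap(self):
        patch = DeforestationPatch("p", box(1700, 100, 2200, 350), 2015)  # 300 m in HA, 200 m in HB
        out = self.classify([patch])
        assert out.loc[0, "holding_id"] == "HA"

    def test_patch_outside_all_holdings_left_unlabelled(self):
        patch = DeforestationPatch("p", box(9000, 9000, 9500, 9500), 2015)
        out = self.classify([patch])
        assert out.loc[0, "holding_id"] is None
        assert pd.isna(out.loc[0, "label"])


class TestAttributeNotices:
    def setup_method(self):
        self.holdings = [Landholding("HA", box(0, 0, 1000, 1000))]
        self.patches = [DeforestationPatch("p13", box(100, 100, 400, 400), 2013)]

    def notices(self, date, x=500.0, y=500.0):
        return make_records([("N1", "P1", date, "PA", "flora", "infraction_notice", 10.0, x, y)])

    def test_notice_after_patch_is_deforestation_related(self):
        out = attribute_notices(self.notices("2015-06-01"), self.patches, self.holdings)
        assert out.loc[0, "holding_id"] == "HA"
        assert bool(out.loc[0, "deforestation_related"])

    def test_notice_before_patch_is_linked_but_unrelated(self):
        out = attribute_notices(self.notices("2012-06-01"), self.patches, self.holdings)
        assert out.loc[0, "holding_id"] == "HA"
        assert not out.loc[0, "deforestation_related"]

    def test_notice_outside_all_holdings_unlinked(self):
        out = attribute_notices(self.notices("2015-06-01", x=5000.0), self.patches, self.holdings)
        assert out.loc[0, "holding_id"] is None

    def test_ungeolocated_notice_unlinked(self):
        out = attribute_notices(self.notices("2015-06-01", x=np.nan, y=np.nan),
                                self.patches, self.holdings)
        assert out.loc[0, "holding_id"] is None


class TestProtectedOverlap:
    def test_thirty_percent_overlap_flagged(self):
        holding = Landholding("H", box(0, 0, 1000, 1000))
        pa = ProtectedArea("PA", box(0, 0, 300, 1000), "indigenous_land")
        out = protected_overlap_flags([holding], [pa], RULES)
        assert out.loc[0, "overlap_fraction"] == pytest.approx(0.30)
        assert bool(out.loc[0, "flagged"])

    def test_disjoint_not_flagged(self):
        holding = Landholding("H", box(0, 0, 1000, 1000))
        pa = ProtectedArea("PA", box(5000, 0, 6000, 1000), "conservation_unit")
        out = protected_overlap_flags([holding], [pa], RULES)
        assert out.loc[0, "overlap_fraction"] == 0.0
        assert not bool(out.loc[0, "flagged"])

    def test_exact_threshold_not_flagged(self):
        holding = Landholding("H", box(0, 0, 1000, 1000))
        pa = ProtectedArea("PA", box(0, 0, 250, 1000), "indigenous_land")
        out = protected_overlap_flags([holding], [pa], RULES)
        assert out.loc[0, "overlap_fraction"] == pytest.approx(0.25)
        assert not bool(out.loc[0, "flagged"])  # strict inequality


class TestLandCategoryBreakdown:
    region = box(0, 0, 10_000, 10_000)

    def test_all_in_indigenous_land(self):
        pa = [ProtectedArea("IL", box(0, 0, 5000, 5000), "indigenous_land")]
        patches = [DeforestationPatch("p", box(1000, 1000, 2000, 2000), 2015)]
        out = land_category_breakdown(patches, [], pa, [], self.region)
        assert out.loc[2015, "indigenous_land"] == pytest.approx(100.0)
        assert out.loc[2015].drop("indigenous_land").sum() == 0.0

    def test_precedence_on_overlap(self):
        cu = [ProtectedArea("CU", box(0, 0, 1000, 2000), "conservation_unit")]
        holdings = [Landholding("H", box(0, 0, 2000, 2000))]  # overlaps the CU
        patches = [DeforestationPatch("p", box(500, 500, 1500, 1500), 2015)]  # half in CU
        out = land_category_breakdown(patches, holdings, cu, [], self.region)
        assert out.loc[2015, "conservation_unit"] == pytest.approx(50.0)
        assert out.loc[2015, "landholding"] == pytest.approx(50.0)

    def test_per_year_totals_conserve_patch_area(self, small_landscape):
        out = land_category_breakdown(
            small_landscape.patches,
            small_landscape.holdings,
            small_landscape.protected_areas,
            [],
            small_landscape.region,
        )
        per_year = {}
        for p in small_landscape.patches:
            per_year[p.year] = per_year.get(p.year, 0.0) + p.area_ha
        for year, total in per_year.items():
            assert out.loc[year].sum() == pytest.approx(total, rel=5e-3)


class TestEndToEndOracle:
    def test_classifier_recovers_generator_truth(self):
        cfg = LandscapeConfig(seed=17, years=(2010, 2019), patches_per_year=50)
        land = generate_landscape(cfg)
        app = derive_app_zones(land.streams, cfg.rules)
        balances = compute_fc_balances(land.holdings, land.native_map, land.grid, cfg.rules)
        labels = classify_patches(land.patches, land.holdings, balances, app, cfg.rules)
        merged = labels.merge(land.ground_truth, on="patch_id")
        above = merged[merged["true_label"] != "below_mmu"]
        assert len(merged) == 500
        assert (above["label"] == above["true_label"]).all()
        assert (above["reason"] == above["true_reason"]).all()
        below = merged[merged["true_label"] == "below_mmu"]
        assert (below["label"] == "below_mmu").all()

    def test_label_partition_above_mmu(self, small_landscape):
        land = small_landscape
        cfg = land.config
        app = derive_app_zones(land.streams, cfg.rules)
        balances = compute_fc_balances(land.holdings, land.native_map, land.grid, cfg.rules)
        labels = classify_patches(land.patches, land.holdings, balances, app, cfg.rules)
        in_holding = labels[labels["holding_id"].notna()]
        above = in_holding[in_holding["area_ha"] >= cfg.rules.mmu_ha]
        assert above["label"].isin(["potentially_illegal", "presumed_legal"]).all()


class TestIllegalitySeries:
    def build(self, coverage_seed=None, coverage=1.0):
        cfg = LandscapeConfig(seed=29, years=(2012, 2015), patches_per_year=40)
        land = generate_landscape(cfg)
        app = derive_app_zones(land.streams, cfg.rules)
        balances = compute_fc_balances(land.holdings, land.native_map, land.grid, cfg.rules)
        labels = classify_patches(land.patches, land.holdings, balances, app, cfg.rules)
        by_holding = {h.holding_id: h for h in land.holdings}
        rng = np.random.default_rng(coverage_seed if coverage_seed is not None else 0)
        rows = []
        assessed = labels[labels["label"].notna() & (labels["label"] != "below_mmu")]
        patch_by_id = {p.patch_id: p for p in land.patches}
        i = 0
        for hid, grp in assessed.groupby("holding_id"):
            # inclusion decided per holding so the recovered holding coverage
            # is a clean Bernoulli draw; a selected holding is noticed in
            # every year it deforests
            if rng.random() >= coverage:
                continue
            for _, row in grp.groupby("year").first().reset_index().iterrows():
                patch = patch_by_id[row["patch_id"]]
                pt = patch.polygon.intersection(by_holding[hid].polygon).representative_point()
                rows.append((f"N{i}", f"P{i}", f"{int(row['year'])}-07-01", "PA", "flora",
                             "infraction_notice", 10.0, pt.x, pt.y))
                i += 1
        notices = make_records(rows)
        attribution = attribute_notices(notices, land.patches, land.holdings)
        return labels, attribution

    def test_full_coverage_gives_one_hundred_percent(self):
        labels, attribution = self.build(coverage=1.0)
        series, summary = illegality_enforcement_series(labels, attribution)
        assert summary["pct_deforesting_holdings_noticed"] == pytest.approx(100.0)
        assert (series["pct_illegal_area_noticed"].dropna() == 100.0).all()

    def test_no_notices_give_zero_percent(self):
        labels, _ = self.build(coverage=1.0)
        empty = attribute_notices(make_records([]), [], [])
        series, summary = illegality_enforcement_series(labels, empty)
        assert summary["pct_deforesting_holdings_noticed"] == 0.0
        assert (series["pct_illegal_area_noticed"].dropna() == 0.0).all()

    def test_partial_coverage_recovered_within_binomial_interval(self):
        labels, attribution = self.build(coverage_seed=101, coverage=0.10)
        _, summary = illegality_enforcement_series(labels, attribution)
        n = summary["n_deforesting_holdings"]
        lo, hi = binom99(n, 0.10)
        assert 100 * lo <= summary["pct_deforesting_holdings_noticed"] <= 100 * hi
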