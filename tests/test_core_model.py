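"""Domain types, bundle I/O round-trips, and report formatting."""

from __future__ import annotations

import json

import pandas as pd
import pytest
from pydantic import ValidationError

import oshburden as ob
from oshburden.bands import NONFATAL_BAND_IDS, SeverityBand

from .conftest import make_profile


class TestSeverityBands:
    def test_required_bands_present(self):
        assert set(NONFATAL_BAND_IDS["injury"]) == {
            "0-3", "4-14", "15-90", "91-180", "181-365", "never_return",
        }
        assert set(NONFATAL_BAND_IDS["disease"]) == {
            "lt3", "4-30", "31-90", "gt90", "never_return",
        }
        assert ob.get_band("injury", "fatal").fatal
        assert ob.get_band("disease", "fatal").fatal

    def test_fatal_and_permanent_mutually_exclusive(self):
        with pytest.raises(ValueError):
            SeverityBand("injury", "bad", 0, 10, permanent=True, fatal=True)

    def test_inverted_day_range_rejected(self):
        with pytest.raises(ValueError):
            SeverityBand("injury", "bad", 10, 5)

    def test_midpoint_lost_days(self):
        assert ob.get_band("injury", "4-14").expected_lost_days == 9.0
        assert ob.get_band("disease", "gt90").expected_lost_days == 228.0
        assert ob.get_band("injury", "never_return").expected_lost_days == float("inf")

    @pytest.mark.parametrize(
        "kind,band_id,cls",
        [
            ("injury", "0-3", "minor"),
            ("injury", "15-90", "temporary"),
            ("injury", "181-365", "permanent"),
            ("injury", "never_return", "permanent"),
            ("injury", "fatal", "fatal"),
            ("disease", "gt90", "temporary"),
            ("disease", "never_return", "permanent"),
        ],
    )
    def test_severity_classes(self, kind, band_id, cls):
        assert ob.get_band(kind, band_id).severity_class == cls

    def test_unknown_band_raises(self):
        with pytest.raises(KeyError, match="unknown severity band"):
            ob.get_band("injury", "5-200")


class TestBundleIO:
    def test_round_trip_identity(self, tmp_path, synth_bundle, default_params):
        _, profile, cohorts = synth_bundle
        ob.write_country_bundle(profile, cohorts, default_params, tmp_path)
        p2, c2, m2 = ob.load_bundle_dir(tmp_path)
        assert p2 == profile
        assert m2 == default_params
        assert c2 == cohorts

    def test_finland_like_totals_conserved_through_io(
        self, tmp_path, synth_bundle, default_params
    ):
        spec, profile, cohorts = synth_bundle
        ob.write_country_bundle(profile, cohorts, default_params, tmp_path)
        _, c2, _ = ob.load_bundle_dir(tmp_path)
        n_injury = sum(c.count for c in c2 if c.kind == "injury")
        assert n_injury == spec.n_injury_cases == 63_407

    def test_missing_earnings_stratum_names_the_stratum(
        self, tmp_path, default_params
    ):
        profile = make_profile()  # earnings cover ages 15-64 only
        cohorts = [
            ob.CaseCohort(
                kind="injury", condition_group="injury", band_id="4-14",
                age_low=65, age_high=74, sex="M", count=5,
            )
        ]
        paths = ob.write_country_bundle(profile, cohorts, default_params, tmp_path)
        with pytest.raises(ob.StratumError, match="age 65-74"):
            ob.load_country_bundle(
                paths["profile"], paths["incidence"], paths["params"]
            )

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ob.CaseCohort(
                kind="injury", condition_group="injury", band_id="4-14",
                age_low=25, age_high=34, sex="M", count=-1,
            )

    def test_unknown_band_in_incidence_file(self, tmp_path, default_params):
        profile = make_profile()
        paths = ob.write_country_bundle(profile, [], default_params, tmp_path)
        pd.DataFrame(
            [
                {
                    "kind": "injury", "condition_group": "injury",
                    "band_id": "5-200", "age_low": 25, "age_high": 34,
                    "sex": "M", "count": 1,
                }
            ]
        ).to_csv(paths["incidence"], index=False)
        with pytest.raises((KeyError, ValidationError)):
            ob.load_country_bundle(
                paths["profile"], paths["incidence"], paths["params"]
            )


class TestBurdenReport:
    @staticmethod
    def _germany_like_summary():
        return ob.summary_from_category_totals(
            direct=10_914e6,
            indirect=70_658e6,
            intangible=25_557e6,
            case_total=2_262_031,
            gdp=3_043_438e6,
            employed_persons=40_210_444,
            stakeholder_totals={
                "worker_family": 64_813e6,
                "employer": 21_534e6,
                "system_public": 20_782e6,
            },
        )

    def test_category_share_formatting(self, tmp_path):
        summary = self._germany_like_summary()
        bd = ob.CostBreakdown(n_cases=summary.case_total)
        bd.add("formal_healthcare", "system_public", 10_914e6)
        bd.add("earnings_loss", "worker_family", 70_658e6)
        bd.add("qaly_loss", "worker_family", 25_557e6)
        paths = ob.write_burden_report(summary, bd, tmp_path)
        table2 = pd.read_csv(paths["categories"], index_col="category")
        assert table2.loc["direct", "formatted"] == "M€10,914 (10%)"
        assert table2.loc["indirect", "formatted"] == "M€70,658 (66%)"
        assert table2.loc["intangible", "formatted"] == "M€25,557 (24%)"
        assert table2.loc["total", "cost_meur"] == 107_129

    def test_report_numbers_roundtrip_to_the_euro(self, tmp_path):
        summary = self._germany_like_summary()
        bd = ob.CostBreakdown(n_cases=summary.case_total)
        bd.add("formal_healthcare", "system_public", 10_914e6)
        bd.add("earnings_loss", "worker_family", 70_658e6)
        bd.add("qaly_loss", "worker_family", 25_557e6)
        paths = ob.write_burden_report(summary, bd, tmp_path)
        table2 = pd.read_csv(paths["categories"], index_col="category")
        for cat in ("direct", "indirect", "intangible"):
            assert abs(table2.loc[cat, "cost_eur"] - summary.by_category[cat]) < 1.0

    def test_empty_breakdown_writes_zero_rows(self, tmp_path):
        summary = ob.BurdenSummary(
            total_cost=0.0,
            by_category={"direct": 0.0, "indirect": 0.0, "intangible": 0.0},
            pct_gdp=0.0, per_case=0.0, per_employed=0.0,
            stakeholder_shares={s: 0.0 for s in ob.types.STAKEHOLDERS},
            case_total=0.0,
        )
        paths = ob.write_burden_report(summary, ob.CostBreakdown(), tmp_path)
        table2 = pd.read_csv(paths["categories"])
        assert (table2["cost_eur"] == 0).all()
        assert (table2["share_pct"] == 0).all()
        table3 = pd.read_csv(paths["stakeholders"])
        assert (table3["share_pct"] == 0).all()


class TestParameterConfig:
    def test_shipped_config_covers_every_parameter_field(self):
        from importlib import resources

        raw = json.loads(
            resources.files("oshburden.data")
            .joinpath("default_parameters.json")
            .read_text()
        )
        missing = set(ob.ModelParameters.model_fields) - set(raw)
        assert not missing, f"config lacks defaults for {missing}"

    def test_shipped_config_loads_and_matches_defaults(self):
        params = ob.load_default_parameters()
        assert params.qaly_value_eur == pytest.approx(41_100.0)
        assert params.impairment_output_loss == 0.35
        assert params.caregiving_cap_days == {"injury": 183.0, "disease": 183.0}

    def test_episode_years_capped_for_injuries(self, default_params):
        long_params = default_params.model_copy(
            update={"treatment_episode_years": {"injury": 2.0, "cancer": 2.0}}
        )
        with pytest.raises(ValidationError):
            ob.ModelParameters(treatment_episode_years={"cancer": 2.5})
        assert long_params.episode_years("injury", "injury") == 1.0
        assert long_params.episode_years("disease", "cancer") == 2.0
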