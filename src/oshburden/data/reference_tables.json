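{
  "_description": "Published national estimates of the economic burden of work injuries and diseases for five EU countries, reference year 2015. Incidence counts carry rates per 100,000 employed persons; burden components are in millions of 2015 euros; gdp_meur_implied is GDP backed out of the printed baseline burden-to-GDP ratio (two-decimal precision).",
  "qaly_value_gbp": {"baseline": 30000, "low": 20000, "high": 45000},
  "countries": {
    "FI": {
      "name": "Finland",
      "incidence": {
        "injury_nonfatal": 63407, "injury_nonfatal_per_100k": 2602,
        "injury_fatal": 35, "injury_fatal_per_100k": 1.4,
        "disease_nonfatal": 67795, "disease_nonfatal_per_100k": 2782,
        "disease_fatal": 628, "disease_fatal_per_100k": 25.8
      },
      "burden": {
        "cases": 131867,
        "direct_meur": 484, "indirect_meur": 4362, "intangible_meur": 1196,
        "total_meur": 6042, "pct_gdp": 2.9,
        "per_case_eur": 45816, "per_employed_eur": 2479
      },
      "category_shares_pct": {"direct": 8, "indirect": 72, "intangible": 20},
      "stakeholders_meur": {"worker_family": 3800, "employer": 1325, "system_public": 916},
      "stakeholder_shares_pct": {"worker_family": 63, "employer": 22, "system_public": 15},
      "qaly_change_pct": {"low": -6.60, "high": 9.90},
      "gdp_meur_implied": 209792,
      "disease_incidence_bounds": {"nonfatal_low": 1776, "nonfatal_high": 67797}
    },
    "DE": {
      "name": "Germany",
      "incidence": {
        "injury_nonfatal": 1158865, "injury_nonfatal_per_100k": 2882,
        "injury_fatal": 450, "injury_fatal_per_100k": 1.1,
        "disease_nonfatal": 1088793, "disease_nonfatal_per_100k": 2708,
        "disease_fatal": 13924, "disease_fatal_per_100k": 34.6
      },
      "burden": {
        "cases": 2262031,
        "direct_meur": 10914, "indirect_meur": 70658, "intangible_meur": 25557,
        "total_meur": 107129, "pct_gdp": 3.5,
        "per_case_eur": 47360, "per_employed_eur": 2664
      },
      "category_shares_pct": {"direct": 10, "indirect": 66, "intangible": 24},
      "stakeholders_meur": {"worker_family": 64813, "employer": 21534, "system_public": 20782},
      "stakeholder_shares_pct": {"worker_family": 61, "employer": 20, "system_public": 19},
      "qaly_change_pct": {"low": -7.95, "high": 11.93},
      "gdp_meur_implied": 3043438,
      "disease_incidence_bounds": {"nonfatal_low": 36202, "nonfatal_high": 1088793}
    },
    "NL": {
      "name": "The Netherlands",
      "incidence": {
        "injury_nonfatal": 99880, "injury_nonfatal_per_100k": 1201,
        "injury_fatal": 35, "injury_fatal_per_100k": 0.4,
        "disease_nonfatal": 220368, "disease_nonfatal_per_100k": 2649,
        "disease_fatal": 3262, "disease_fatal_per_100k": 39.2
      },
      "burden": {
        "cases": 323544,
        "direct_meur": 2137, "indirect_meur": 16468, "intangible_meur": 5147,
        "total_meur": 23751, "pct_gdp": 3.5,
        "per_case_eur": 73410, "per_employed_eur": 2855
      },
      "category_shares_pct": {"direct": 9, "indirect": 69, "intangible": 22},
      "stakeholders_meur": {"worker_family": 17235, "employer": 3484, "system_public": 3032},
      "stakeholder_shares_pct": {"worker_family": 73, "employer": 15, "system_public": 13},
      "qaly_change_pct": {"low": -7.22, "high": 10.84},
      "gdp_meur_implied": 682500,
      "disease_incidence_bounds": {"nonfatal_low": 8073, "nonfatal_high": 220368}
    },
    "IT": {
      "name": "Italy",
      "incidence": {
        "injury_nonfatal": 1257987, "injury_nonfatal_per_100k": 5600,
        "injury_fatal": 543, "injury_fatal_per_100k": 2.4,
        "disease_nonfatal": 638448, "disease_nonfatal_per_100k": 2842,
        "disease_fatal": 10524, "disease_fatal_per_100k": 46.8
      },
      "burden": {
        "cases": 1907504,
        "direct_meur": 8491, "indirect_meur": 58961, "intangible_meur": 37392,
        "total_meur": 104844, "pct_gdp": 6.3,
        "per_case_eur": 54964, "per_employed_eur": 4667
      },
      "category_shares_pct": {"direct": 8, "indirect": 56, "intangible": 36},
      "stakeholders_meur": {"worker_family": 70391, "employer": 20632, "system_public": 13821},
      "stakeholder_shares_pct": {"worker_family": 67, "employer": 20, "system_public": 13},
      "qaly_change_pct": {"low": -11.89, "high": 17.83},
      "gdp_meur_implied": 1653691,
      "disease_incidence_bounds": {"nonfatal_low": 19314, "nonfatal_high": 638448},
      "injury_adjustment_ratio_bounds": {"low": 2.9, "high": 4.5}
    },
    "PL": {
      "name": "Poland",
      "incidence": {
        "injury_nonfatal": 697337, "injury_nonfatal_per_100k": 4336,
        "injury_fatal": 301, "injury_fatal_per_100k": 1.9,
        "disease_nonfatal": 454090, "disease_nonfatal_per_100k": 2823,
        "disease_fatal": 4663, "disease_fatal_per_100k": 29.0
      },
      "burden": {
        "cases": 1156394,
        "direct_meur": 1882, "indirect_meur": 19588, "intangible_meur": 22311,
        "total_meur": 43781, "pct_gdp": 10.2,
        "per_case_eur": 37860, "per_employed_eur": 2722
      },
      "category_shares_pct": {"direct": 4, "indirect": 45, "intangible": 51},
      "stakeholders_meur": {"worker_family": 34421, "employer": 5007, "system_public": 4353},
      "stakeholder_shares_pct": {"worker_family": 79, "employer": 11, "system_public": 10},
      "qaly_change_pct": {"low": -16.99, "high": 25.48},
      "gdp_meur_implied": 430069,
      "disease_incidence_bounds": {"nonfatal_low": 2351, "nonfatal_high": 454090},
      "injury_adjustment_ratio_bounds": {"low": 6.2, "high": 9.6},
      "injury_adjusted_count_bounds": {"low": 545300, "high": 848783}
    }
  }
}
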