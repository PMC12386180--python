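"""Published monitoring records of the Columbia Basin pygmy rabbit
recovery program (2012–2020), bundled as analysis inputs.

These are the program's published per-period demographic and genetic
summaries for the Sagebrush Flat/CRP (SBF), Beezley Hills (BH) and Chester
Butte (CHB) recovery areas, the per-cohort release table, and the pooled
release/detection counts behind the apparent-survival rates.  They let the
summary and survival stages run on the real study's inputs; all other
stages run on synthetic data.
"""

from __future__ import annotations

import pandas as pd

#: Potential-habitat areas (hectares) per recovery area.
HABITAT_HA = {"SBF": 1780.0, "BH": 83.0, "CHB": 893.0}

_SBF_PERIODS = [
    # period, minimum count, males, females, rabbits/active burrow,
    # mean CB %, % individuals with CB ancestry, % wild-born with CB,
    # Ne point, Ne lo, Ne hi, Ho, He, AR
    ("winter_2012_13", 45, 18, 27, 0.87, 19.69, 48.89, 100.0, 15.4, 13.7, 17.3, 0.76, 0.80, 5.22),
    ("winter_2013_14", 44, 22, 22, 0.75, 19.72, 88.64, 100.0, 29.6, 25.3, 34.9, 0.81, 0.79, 5.15),
    ("winter_2014_15", 91, 44, 47, 0.63, 19.10, 71.43, 33.33, 30.4, 27.7, 33.5, 0.81, 0.80, 5.13),
    ("winter_2015_16", 18, 7, 11, 1.00, 21.06, 100.0, 100.0, 19.3, 14.7, 27.0, 0.75, 0.80, 5.29),
    ("winter_2016_17", 60, 32, 28, 0.92, 21.89, 100.0, 100.0, 40.7, 35.0, 47.9, 0.70, 0.80, 5.16),
    ("winter_2017_18", 158, 101, 57, 0.96, 15.31, 100.0, 100.0, 44.3, 40.6, 48.5, 0.84, 0.82, 5.35),
    ("summer_2018", 54, 19, 35, 0.56, 18.48, 100.0, 100.0, 36.9, 23.7, 30.8, 0.76, 0.79, 5.00),
    ("winter_2018_19", 138, 91, 47, 0.65, 17.97, 100.0, 100.0, 27.6, 25.5, 29.9, 0.62, 0.79, 4.95),
    ("winter_2019_20", 8, 4, 4, 0.33, 16.10, 100.0, 100.0, 12.3, 7.0, 26.8, 0.64, 0.72, 4.67),
]

_SBF_DENSITY_PRINTED = [0.03, 0.02, 0.05, 0.01, 0.03, 0.09, 0.03, 0.08, 0.004]

_BH_CHB_PERIODS = [
    # site, period, minimum count, males, females, rabbits/burrow,
    # mean CB %, Ho, He, AR
    ("BH", "winter_2017_18", 5, 2, 3, 0.42, 23.98, 0.78, 0.71, 5.41),
    ("CHB", "winter_2018_19", 5, 3, 2, 0.45, 14.85, 0.77, 0.71, 4.65),
    ("BH", "winter_2018_19", 3, 1, 2, 0.43, 23.97, 0.75, None, None),
    ("CHB", "summer_2019", 5, 2, 3, 0.50, 20.89, 0.73, 0.66, 4.59),
    ("BH", "summer_2019", 7, 6, 1, 0.70, 22.87, 0.80, 0.66, 3.82),
    ("CHB", "winter_2019_20", 10, 4, 6, 0.35, 19.04, 0.74, 0.64, 3.69),
    ("BH", "winter_2019_20", 5, 2, 3, 0.50, 27.46, 0.59, 0.64, 3.71),
]

_SBF_RELEASES = [
    # breeding season, juveniles released, adults released
    (2012, 104, 0),
    (2013, 265, 7),
    (2014, 717, 113),
    (2015, 149, 4),
    (2016, 119, 1),
]

#: Pooled release/detection counts behind the published apparent-survival
#: rates.  Per-period detection rows of the monitoring table pool adults
#: and juveniles, so the age-class split exists only pooled.
SURVIVAL_COHORTS = [
    # cohort, n at risk, n detected
    ("released_juveniles_first_winter", 1354, 141),
    ("released_adults_first_winter", 125, 25),
    ("wild_born_second_winter", 420, 20),
    ("released_juveniles_second_winter", 141, 5),
]


def sbf_period_summaries() -> pd.DataFrame:
    """Per-period demographic/genetic summary of the SBF/CRP area."""
    df = pd.DataFrame(
        _SBF_PERIODS,
        columns=[
            "period_id", "minimum_count", "males", "females",
            "rabbits_per_burrow", "mean_cb_pct", "pct_containing_cb",
            "pct_wild_born_containing_cb", "ne", "ne_lo", "ne_hi",
            "ho", "he", "ar",
        ],
    )
    df["site"] = "SBF"
    df["habitat_ha"] = HABITAT_HA["SBF"]
    df["density_printed"] = _SBF_DENSITY_PRINTED
    return df


def bh_chb_period_summaries() -> pd.DataFrame:
    """Per-period summary of the BH and CHB recovery areas."""
    df = pd.DataFrame(
        _BH_CHB_PERIODS,
        columns=[
            "site", "period_id", "minimum_count", "males", "females",
            "rabbits_per_burrow", "mean_cb_pct", "ho", "he", "ar",
        ],
    )
    df["habitat_ha"] = df["site"].map(HABITAT_HA)
    return df


def sbf_release_cohorts() -> pd.DataFrame:
    """Juveniles/adults released into SBF per breeding season."""
    return pd.DataFrame(
        _SBF_RELEASES,
        columns=["breeding_season", "juveniles_released", "adults_released"],
    )


def survival_cohorts() -> pd.DataFrame:
    """Pooled release/detection counts for apparent-survival rates."""
    return pd.DataFrame(
        SURVIVAL_COHORTS, columns=["cohort", "n_at_risk", "n_detected"]
    )
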