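"""Published stratum summaries from the ENSIN 2005 adult zinc analysis.

The raw microdata of Colombia's 2005 National Nutritional Situation
Survey (ENSIN 2005) are restricted, but the published stratum-level
summaries — median (Q1, Q3) of each nutrient intake per sex × age band,
stratum sizes, and the corresponding absorbed-zinc summaries — are
public. They serve two roles here:

* calibration targets for the synthetic cohort generator
  (:mod:`zincabs.synthetic`), which emulates the survey's marginal
  intake distributions; and
* inputs for the worked requirement-derivation example: applying the
  EAR_M/RDA_M equations to a stratum's published median fractional
  absorption reproduces that stratum's published model-based
  requirement, because the transform is monotone.

Quantities: intakes in mg/day (protein g/day), ``pz`` dimensionless,
``taz`` mg/day, ``faz`` percent.
"""

from __future__ import annotations

from .intake import AgeBand, Sex, StratumKey

#: (median, Q1, Q3) per nutrient and stratum size, adults 19–70 y.
INTAKE_TARGETS: dict[StratumKey, dict] = {
    StratumKey(Sex.MALE, AgeBand.Y19_30): {
        "n": 2754,
        "zinc_mg": (8.1, 5.5, 11.4),
        "phytate_mg": (590.6, 320.4, 1040.1),
        "protein_g": (59.9, 42.4, 80.5),
        "calcium_mg": (317.3, 176.7, 555.6),
        "pz": (7.5, 4.2, 12.9),
    },
    StratumKey(Sex.MALE, AgeBand.Y31_50): {
        "n": 2431,
        "zinc_mg": (7.5, 5.1, 10.5),
        "phytate_mg": (570.9, 298.9, 976.4),
        "protein_g": (54.7, 40.0, 75.5),
        "calcium_mg": (304.1, 159.3, 513.9),
        "pz": (7.8, 4.2, 13.1),
    },
    StratumKey(Sex.MALE, AgeBand.Y51_70): {
        "n": 867,
        "zinc_mg": (6.6, 4.6, 9.6),
        "phytate_mg": (535.1, 287.7, 945.3),
        "protein_g": (48.4, 34.3, 65.9),
        "calcium_mg": (278.5, 134.8, 488.9),
        "pz": (8.4, 4.4, 15.4),
    },
    StratumKey(Sex.FEMALE, AgeBand.Y19_30): {
        "n": 3057,
        "zinc_mg": (6.2, 4.2, 8.9),
        "phytate_mg": (458.5, 250.9, 773.2),
        "protein_g": (45.8, 32.4, 62.1),
        "calcium_mg": (285.0, 144.0, 500.6),
        "pz": (7.5, 4.1, 13.0),
    },
    StratumKey(Sex.FEMALE, AgeBand.Y31_50): {
        "n": 2795,
        "zinc_mg": (5.5, 3.7, 7.7),
        "phytate_mg": (409.5, 214.6, 713.5),
        "protein_g": (40.2, 28.7, 54.0),
        "calcium_mg": (255.1, 125.3, 461.3),
        "pz": (7.7, 4.2, 13.4),
    },
    StratumKey(Sex.FEMALE, AgeBand.Y51_70): {
        "n": 1083,
        "zinc_mg": (4.7, 3.1, 6.8),
        "phytate_mg": (410.2, 217.1, 701.8),
        "protein_g": (35.2, 23.8, 47.2),
        "calcium_mg": (230.6, 113.1, 436.2),
        "pz": (8.8, 4.6, 15.0),
    },
}

#: Published absorbed-zinc summaries per stratum: TAZ mg/day and FAZ %
#: as (median, Q1, Q3); ``all`` rows are the per-sex totals.
ABSORPTION_SUMMARIES: dict[StratumKey, dict] = {
    StratumKey(Sex.MALE, AgeBand.Y19_30): {
        "taz_mg": (2.5, 1.9, 3.2),
        "faz_pct": (31.0, 25.0, 38.2),
        "faz_mean": 32.0, "faz_sd": 9.6, "faz_min": 9.8, "faz_max": 69.1,
    },
    StratumKey(Sex.MALE, AgeBand.Y31_50): {
        "taz_mg": (2.4, 1.7, 3.1),
        "faz_pct": (31.6, 25.6, 39.3),
        "faz_mean": 32.8, "faz_sd": 10.1, "faz_min": 11.2, "faz_max": 84.8,
    },
    StratumKey(Sex.MALE, AgeBand.Y51_70): {
        "taz_mg": (2.1, 1.5, 2.9),
        "faz_pct": (32.9, 25.9, 39.8),
        "faz_mean": 33.4, "faz_sd": 9.9, "faz_min": 11.8, "faz_max": 73.4,
    },
    StratumKey(Sex.MALE, AgeBand.ALL): {
        "taz_mg": (2.4, 1.7, 3.1),
        "faz_pct": (31.4, 25.4, 38.8),
        "faz_mean": 32.5, "faz_sd": 9.9, "faz_min": 9.8, "faz_max": 84.8,
    },
    StratumKey(Sex.FEMALE, AgeBand.Y19_30): {
        "taz_mg": (2.2, 1.5, 2.9),
        "faz_pct": (34.6, 28.8, 41.6),
        "faz_mean": 35.4, "faz_sd": 9.3, "faz_min": 9.7, "faz_max": 71.3,
    },
    StratumKey(Sex.FEMALE, AgeBand.Y31_50): {
        "taz_mg": (2.0, 1.4, 2.6),
        "faz_pct": (36.4, 29.8, 43.4),
        "faz_mean": 36.8, "faz_sd": 9.5, "faz_min": 8.9, "faz_max": 71.0,
    },
    StratumKey(Sex.FEMALE, AgeBand.Y51_70): {
        "taz_mg": (1.7, 1.1, 2.4),
        "faz_pct": (37.0, 30.5, 43.7),
        "faz_mean": 37.4, "faz_sd": 9.5, "faz_min": 14.6, "faz_max": 63.5,
    },
    StratumKey(Sex.FEMALE, AgeBand.ALL): {
        "taz_mg": (2.0, 1.4, 2.7),
        "faz_pct": (35.7, 29.5, 42.7),
        "faz_mean": 36.2, "faz_sd": 9.4, "faz_min": 8.9, "faz_max": 71.3,
    },
}

#: Default per-stratum sizes of the survey (sums to 12 987 adults).
STRATUM_SIZES = {key: targets["n"] for key, targets in INTAKE_TARGETS.items()}
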