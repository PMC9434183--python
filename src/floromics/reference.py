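"""Published reference measurements bundled as analysis inputs.

Two small summary tables from the Arabidopsis flower-anthesis feeding
experiments are shipped with the package so that the flux arithmetic and
the significance-letter machinery can be exercised against real printed
numbers without any download:

* the ¹⁴C-glucose whole-inflorescence partitioning summary (label totals,
  per-class redistribution percentages, and the published absolute fluxes;
  means ± sd over n = 5 replicate samples), and
* the ¹³C accumulation of primary metabolites in florets at preanthesis,
  anthesis and postanthesis (ng·mg⁻¹ FW; mean ± se, n = 3), with the
  published significance letters (P < 0.05) and bold flags (P < 0.01).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "C14_TOTALS",
    "C14_REDISTRIBUTION_PCT",
    "C14_PUBLISHED_FLUXES",
    "C14_FEEDING_SA",
    "C14_FEEDING_HOURS",
    "C14_N_REPLICATES",
    "c13_accumulation",
]

#: Label totals (Bq per g fresh weight) and fractionation recovery: mean, sd.
C14_TOTALS = {
    "total uptake": (1.36e7, 3.89e6),
    "metabolized radioactivity": (1.29e7, 3.72e6),
    "recovery": (0.58, 0.04),
}

#: Redistribution of metabolized label over compound classes (%): mean, sd.
C14_REDISTRIBUTION_PCT = {
    "CO2": (0.10, 0.03),
    "amino acids": (0.39, 0.06),
    "organic acids": (35.29, 3.79),
    "hexoses-P": (53.24, 5.12),
    "Suc": (6.42, 0.95),
    "Fru": (1.59, 1.19),
    "protein": (0.57, 0.14),
    "starch": (0.17, 0.03),
    "cellulose": (2.23, 0.32),
}

#: Published absolute fluxes (nmol hexose equivalents gFW^-1 h^-1): mean, sd.
#: These were derived with per-replicate hexose-phosphate-pool specific
#: activities that are not public; recomputation from the feeding-solution
#: specific activity lands within ~20% (lower-bound bias: pool dilution).
C14_PUBLISHED_FLUXES = {
    "Suc": (2.57e4, 1.28e4),
    "starch": (745.17, 499.09),
    "cellulose": (9167.26, 5049.41),
    "protein": (2466.28, 1725.3),
}

#: Feeding-solution specific activity, Bq per nmol of total glucose
#: (7 MBq per mmol), feeding duration, and replicate count.
C14_FEEDING_SA = 7.0
C14_FEEDING_HOURS = 5.0
C14_N_REPLICATES = 5

_C13_ROWS = [
    # metabolite, group, (pre mean, se), (anth mean, se), (post mean, se), letters, bold
    ("Ala", "amino acid", 328.92, 47.59, 466.36, 45.78, 414.00, 30.45, ("a", "b", "b"), False),
    ("Asn", "amino acid", 155.95, 20.95, 125.28, 22.20, 50.20, 6.60, ("a", "a", "b"), False),
    ("Asp", "amino acid", 326.42, 41.04, 152.66, 14.77, 77.69, 3.83, ("a", "b", "c"), False),
    ("GABA", "amino acid", 46.58, 6.64, 37.20, 5.02, 26.46, 6.11, ("a", "a", "b"), False),
    ("Glu", "amino acid", 2670.82, 297.74, 1714.00, 172.21, 799.73, 85.65, ("a", "b", "c"), False),
    ("Glycine", "amino acid", 101.92, 6.08, 83.07, 1.08, 49.86, 5.64, ("a", "b", "c"), True),
    ("Ile", "amino acid", 3.02, 0.13, 2.93, 0.71, 2.17, 0.14, ("a", "ab", "b"), False),
    ("Leu", "amino acid", 1.52, 0.20, 1.08, 0.30, 0.59, 0.13, ("a", "ab", "b"), False),
    ("Ornithine", "amino acid", 4.43, 0.71, 3.15, 0.42, 2.85, 0.33, ("a", "b", "b"), False),
    ("Pro", "amino acid", 333.88, 53.28, 274.55, 13.97, 121.66, 8.61, ("a", "a", "b"), False),
    ("Ser", "amino acid", 210.43, 28.11, 141.64, 14.54, 79.35, 8.83, ("a", "b", "c"), False),
    ("Thr", "amino acid", 51.85, 7.17, 60.39, 5.89, 45.45, 6.14, ("a", "a", "a"), False),
    ("Val", "amino acid", 178.44, 15.81, 139.77, 3.70, 58.98, 6.36, ("a", "b", "c"), True),
    ("Fru", "carbohydrate", 437.16, 103.16, 2378.80, 25.09, 2418.67, 212.58, ("a", "b", "b"), True),
    ("Glc", "carbohydrate", 1.71e5, 1.47e4, 4.84e5, 1.71e4, 3.74e5, 4.62e4, ("a", "b", "c"), True),
    ("Myoinositol", "carbohydrate", 627.30, 95.75, 570.21, 6.39, 364.14, 21.13, ("a", "a", "b"), True),
    ("Suc", "carbohydrate", 10576.81, 1571.98, 12052.37, 421.79, 6878.57, 391.95, ("a", "a", "b"), False),
    ("Trehalose", "carbohydrate", 17.92, 1.57, 13.29, 4.38, 26.59, 0.78, ("a", "a", "b"), False),
    ("Citrate", "organic acid", 588.81, 87.27, 276.14, 0.04, 436.99, 8.60, ("a", "b", "c"), True),
    ("Fumarate", "organic acid", 69.86, 6.24, 316.96, 33.09, 220.42, 9.16, ("a", "b", "c"), True),
    ("Glycerate", "organic acid", 11.27, 4.60, 23.93, 4.09, 15.18, 5.73, ("a", "b", "ab"), False),
    ("Malate", "organic acid", 498.35, 48.09, 654.58, 31.01, 364.05, 26.89, ("a", "b", "c"), False),
    ("Succinate", "organic acid", 137.83, 14.18, 431.74, 27.73, 155.27, 6.66, ("a", "b", "a"), False),
]


def c13_accumulation() -> pd.DataFrame:
    """The ¹³C accumulation reference table (one row per metabolite).

    Columns: group, mean/se per phase (preanthesis, anthesis, postanthesis;
    ng·mg⁻¹ FW, n = 3), the published significance letters, and the bold
    (P < 0.01) flag.
    """
    return pd.DataFrame(
        [
            {
                "metabolite": m,
                "group": g,
                "preanthesis_mean": m1,
                "preanthesis_se": s1,
                "anthesis_mean": m2,
                "anthesis_se": s2,
                "postanthesis_mean": m3,
                "postanthesis_se": s3,
                "letters": letters,
                "bold": bold,
            }
            for m, g, m1, s1, m2, s2, m3, s3, letters, bold in _C13_ROWS
        ]
    ).set_index("metabolite")
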