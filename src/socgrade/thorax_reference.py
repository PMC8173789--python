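"""Bundled benchmark summaries for 13 thoracic organs at risk.

These are cohort-level summaries from a published clinical evaluation
of atlas-based auto-segmentation against manual contours on thoracic
planning CT (20 test patients, 3 mm slices), covering all thoracic
organs at risk of the RTOG delineation guidelines. They serve as a
worked example and as ground truth for the grading schemes: applying
the built-in thresholds to the published per-organ index means must
reproduce the published level assignments.

Only summary statistics are bundled; the underlying per-patient data
were not released, so per-case analyses (e.g. standard derivation) run
on synthetic cohorts instead.
"""

from __future__ import annotations

from .geometry_metrics import MetricSet
from .grading import SubjectiveRecord

#: The 13 thoracic organs at risk, ordered by decreasing mean DSC.
OARS = (
    "R Lung", "L Lung", "Skin", "Heart", "SC", "AOR", "CW",
    "Trachea", "PA", "SVC", "ESO", "IVC", "PV",
)

#: Published per-organ means of the five indexes
#: (DSC, ΔCMD cm, ΔV %, MHD cm, AHD cm).
INDEX_MEANS: dict[str, MetricSet] = {
    oar: MetricSet(*vals)
    for oar, vals in {
        "R Lung":  (0.96, 0.13, 7.0, 2.18, 0.11),
        "L Lung":  (0.94, 0.28, 10.0, 3.45, 0.17),
        "Skin":    (0.93, 2.06, 11.0, 8.85, 0.58),
        "Heart":   (0.90, 0.40, 7.0, 1.85, 0.24),
        "SC":      (0.88, 1.34, 9.0, 2.74, 0.13),
        "AOR":     (0.79, 0.92, 24.0, 2.72, 0.28),
        "CW":      (0.77, 1.29, 39.0, 6.51, 0.46),
        "Trachea": (0.75, 0.53, 34.0, 4.27, 0.25),
        "PA":      (0.73, 0.71, 16.0, 2.12, 0.28),
        "SVC":     (0.62, 1.17, 29.0, 1.87, 0.33),
        "ESO":     (0.57, 0.89, 33.0, 2.10, 0.29),
        "IVC":     (0.56, 0.91, 30.0, 2.17, 0.43),
        "PV":      (0.53, 1.00, 35.0, 2.65, 0.44),
    }.items()
}

#: Published level assignments per organ. Keys are (index, scheme);
#: schemes only appear for indexes they define.
PUBLISHED_LEVELS: dict[str, dict[tuple[str, str], int]] = {}

_LEVEL_ROWS = {
    # digits: DSC(our, velker, ciardo), CMD(our, ciardo), DV(our),
    #         MHD(our), AHD(our, ciardo)
    "R Lung":  "333333233",
    "L Lung":  "333323132",
    "Skin":    "333112111",
    "Heart":   "333323222",
    "SC":      "333113133",
    "AOR":     "222211122",
    "CW":      "222111111",
    "Trachea": "222211122",
    "PA":      "222212222",
    "SVC":     "122111222",
    "ESO":     "111211222",
    "IVC":     "111211211",
    "PV":      "111211111",
}

_LEVEL_COLUMNS = (
    ("dsc", "our_center"), ("dsc", "velker"), ("dsc", "ciardo"),
    ("cmd", "our_center"), ("cmd", "ciardo"),
    ("dv", "our_center"),
    ("mhd", "our_center"),
    ("ahd", "our_center"), ("ahd", "ciardo"),
)

for _oar, _digits in _LEVEL_ROWS.items():
    PUBLISHED_LEVELS[_oar] = {
        col: int(d) for col, d in zip(_LEVEL_COLUMNS, _digits)
    }

#: Published subjective slice-review summaries: average standard slice
#: number, average slices to modify, average percentage to modify (an
#: average of per-patient percentages, hence not exactly
#: modified/total), and the published subjective score. The shortest
#: organ (PV, ~9 slices) was scored on counts and has no percentage.
SUBJECTIVE_RECORDS: dict[str, SubjectiveRecord] = {
    "R Lung":  SubjectiveRecord("R Lung", 71, 5, 6.0),
    "L Lung":  SubjectiveRecord("L Lung", 71, 7, 10.0),
    "Skin":    SubjectiveRecord("Skin", 125, 19, 14.0),
    "Heart":   SubjectiveRecord("Heart", 31, 6, 17.0),
    "SC":      SubjectiveRecord("SC", 124, 11, 8.0),
    "AOR":     SubjectiveRecord("AOR", 62, 27, 41.0),
    "CW":      SubjectiveRecord("CW", 71, 29, 42.0),
    "Trachea": SubjectiveRecord("Trachea", 47, 15, 31.0),
    "PA":      SubjectiveRecord("PA", 12, 7, 58.0),
    "SVC":     SubjectiveRecord("SVC", 22, 13, 57.0),
    "ESO":     SubjectiveRecord("ESO", 72, 54, 74.0),
    "IVC":     SubjectiveRecord("IVC", 13, 10, 75.0),
    "PV":      SubjectiveRecord("PV", 9, 7, None),
}

#: Published subjective scores per organ.
SUBJECTIVE_SCORES: dict[str, int] = {
    "R Lung": 3, "L Lung": 3, "Skin": 2, "Heart": 2, "SC": 3,
    "AOR": 1, "CW": 1, "Trachea": 1, "PA": 1, "SVC": 1,
    "ESO": 1, "IVC": 1, "PV": 1,
}
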