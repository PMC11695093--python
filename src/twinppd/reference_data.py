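"""Published headline counts from a nationwide Danish register study of
postpartum depression in twin vs singleton parents (births 1997-2019).

These printed table values serve as worked-example inputs: the package's
arithmetic (percentages, crude cumulative risk ratios) can be checked
against the corresponding published cells without access to the
confidential individual-level register data.
"""

from __future__ import annotations

__all__ = [
    "COHORT_SIZES",
    "TWIN_CHILDBIRTH_COUNTS",
    "TWIN_CHILDBIRTH_PERCENTAGES",
    "SINGLETON_CHILDBIRTH_COUNTS",
    "MOTHER_LANDMARK_CASES",
    "PUBLISHED_UNADJUSTED_RR_MOTHERS",
]

#: study-population sizes by role and plurality
COHORT_SIZES = {
    ("mother", "twin"): 25_611,
    ("mother", "singleton"): 1_257_947,
    ("father", "twin"): 25_457,
    ("father", "singleton"): 1_271_646,
    ("childbirth", "twin"): 27_095,
    ("childbirth", "singleton"): 1_350_046,
}

#: childbirth-level characteristic counts among the 27,095 twin childbirths.
#: The preterm row is excluded: 12,669 childbirths have missing preterm
#: information, so its printed percentage does not recompute from the full
#: childbirth denominator.
TWIN_CHILDBIRTH_COUNTS = {
    "art": 9_110,
    "csection": 14_096,
    "preeclampsia": 2_672,
    "gestational_diabetes": 1_030,
    "hemorrhage": 3_196,
    "nicu": 11_695,
}

#: printed percentages for the same rows (one decimal)
TWIN_CHILDBIRTH_PERCENTAGES = {
    "art": 33.6,
    "csection": 52.0,
    "preeclampsia": 9.9,
    "gestational_diabetes": 3.8,
    "hemorrhage": 11.8,
    "nicu": 43.2,
}

#: childbirth-level counts among the 1,350,046 singleton childbirths
SINGLETON_CHILDBIRTH_COUNTS = {
    "art": 59_733,
    "csection": 244_290,
    "preeclampsia": 45_176,
    "gestational_diabetes": 33_638,
    "hemorrhage": 81_048,
    "nicu": 109_218,
}

#: cumulative postpartum-depression case counts among mothers by landmark
#: (days; 30-day months, 12 months = 365-day horizon): (twin, singleton)
MOTHER_LANDMARK_CASES = {
    90: (117, 4_823),
    180: (258, 10_131),
    270: (374, 15_708),
    365: (505, 21_960),
}

#: printed unadjusted cumulative risk ratios for mothers at the landmarks
#: (model-smoothed, so crude count ratios need not match at 3-9 months)
PUBLISHED_UNADJUSTED_RR_MOTHERS = {90: 1.26, 180: 1.24, 270: 1.18, 365: 1.13}
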