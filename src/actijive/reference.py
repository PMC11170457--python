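"""Published reference statistics used for calibration and cross-checks.

These are descriptive statistics of accelerometry-derived features reported
for wave 2 of the CoLaus|PsyCoLaus study, a Swiss population-based cohort of
adults aged 35-75, stratified by major depressive disorder (MDD) status.
The raw cohort is not publicly deposited, so this package uses the printed
group-level summaries in two ways:

* as calibration targets for the default synthetic-cohort plans
  (:mod:`actijive.simulate`), so that simulated cohorts live on a realistic
  scale; and
* as inputs for recomputing whole-cohort summaries (overall percentages and
  wear-time-weighted means) from the per-group values, which exercises the
  pooling arithmetic in :mod:`actijive.association`.

All values are per-subject means (SD) over valid wear days, or counts for
categorical rows.  ``GROUP_N`` keys are the diagnostic groups used
throughout the package: ``none`` (no lifetime MDD), ``current`` and
``remitted``; ``lifetime`` is the union of the latter two.
"""

from __future__ import annotations

GROUPS = ("none", "current", "remitted")

#: Subjects per diagnostic group.
GROUP_N = {"none": 1164, "current": 185, "remitted": 968}

#: Female subjects per group (sex is the one chi-square row).
FEMALE_N = {"none": 502, "current": 131, "remitted": 628}

#: Self-reported White ethnicity per group.
WHITE_N = {"none": 1086, "current": 167, "remitted": 893}

#: Current comorbid anxiety disorder, count per group.
ANXIETY_N = {"none": 33, "current": 21, "remitted": 57}

#: Current substance use disorder, count per group (2 missing in remitted).
SUD_N = {"none": 5, "current": 3, "remitted": 5}

#: Current antidepressant or benzodiazepine use, count per group.
MEDICATION_N = {"none": 32, "current": 64, "remitted": 128}

AGE_MEAN = {"none": 63.39, "current": 58.66, "remitted": 60.47}
AGE_SD = {"none": 10.32, "current": 8.76, "remitted": 9.42}
BMI_MEAN = {"none": 26.30, "current": 26.75, "remitted": 26.34}
BMI_SD = {"none": 4.64, "current": 5.36, "remitted": 4.77}

#: Mean (SD) of each accelerometry feature in the no-MDD group.  Used as the
#: physical scale for feature-tier simulation (z-scores are mapped onto these
#: means/SDs) and as loose calibration targets for the epoch-tier generator.
FEATURE_REFERENCE = {
    # sleep
    "Onset": (23.44, 1.16),
    "Wakeup": (7.18, 1.11),
    "Duration": (6.69, 1.01),
    "Midpoint": (3.31, 1.01),
    "Efficiency": (0.87, 0.06),
    "NWB": (2.08, 1.64),
    "NSB": (13.97, 3.63),
    # physical activity
    "TAC": (42588.0, 13655.0),
    "TLAC": (6733.0, 368.4),
    "TST": (1160.0, 109.7),
    "LiPA": (183.2, 61.27),
    "MVPA": (97.14, 65.65),
    "SATP": (0.07, 0.02),
    "ASTP": (0.25, 0.08),
    # circadian rhythms
    "fPC1": (-0.22, 10.49),
    "fPC2": (0.54, 8.15),
    "fPC3": (0.00, 5.89),
    "fPC4": (-0.21, 3.92),
    "RA": (0.82, 0.07),
    "IV": (0.66, 0.13),
    "IS": (0.36, 0.10),
    "Mesor": (29.57, 9.48),
    "Amp": (24.48, 10.16),
    "Acro": (-3.65, 0.32),
    "L5": (4.29, 1.30),
    "M10": (50.26, 17.38),
    "L5Time": (-0.15, 0.94),
    "M10Time": (-0.12, 1.23),
}

#: Joint / individual / residual variance-explained fractions per block
#: reported for the reference cohort; the default feature-tier plan targets
#: these partitions.
VAREXP_REFERENCE = {
    "SL": (0.585, 0.344, 0.071),
    "PA": (0.795, 0.176, 0.029),
    "CR": (0.545, 0.255, 0.200),
}

#: JIVE ranks selected on the reference cohort (joint, SL, PA, CR).
RANKS_REFERENCE = (3, 1, 2, 3)

#: Per-1-SD odds ratios for lifetime MDD on the nine JIVE scores reported
#: for the reference cohort; the default outcome model plants the log of
#: these as coefficients.
LIFETIME_OR_REFERENCE = {
    "Joint-1": 0.86,
    "Joint-2": 1.12,
    "Joint-3": 0.97,
    "SL-1": 0.97,
    "PA-1": 0.94,
    "PA-2": 0.84,
    "CR-1": 0.86,
    "CR-2": 1.11,
    "CR-3": 0.99,
}
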