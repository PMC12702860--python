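"""Reference values from the published budget-impact analysis this package
re-implements.

These printed per-category figures are *inputs* for exact-arithmetic checks
(per-member-per-month division, column additivity); the model fixture is
calibrated against a subset of them but never reads them at run time.
All values are 2024 USD for a 100-infant cohort.
"""

# payer perspective, 5-year horizon, by care setting: category -> (pfos, soc)
PAYER_TABLE = {
    "NICU": (19_867_218, 22_182_414),
    "Lower acuity ward": (89_129, 97_219),
    "Infection (in hospital)": (15_101, 17_541),
    "Discharged with NGT": (24_696, 22_885),
    "Infection (at home)": (43_995, 45_078),
    "Rehospitalizations": (1_673_794, 1_698_105),
}
PAYER_TOTALS = {"pfos": 21_713_932, "soc": 24_063_242}

# hospital perspective, 1-year horizon, by FOF achievement
HOSPITAL_TABLE = {
    "FOF group: Pre NNS training NICU": (3_092_177, 3_331_773),
    "FOF group: NNS training and follow up": (4_938_498, 5_652_845),
    "FOF group: Staff time for training": (66_431, 78_728),
    "Non-FOF group: Pre NNS training NICU": (212_208, 210_428),
    "Non-FOF group: NNS training and follow up": (430_194, 455_529),
    "Non-FOF group: Staff time for training": (6_649, 6_906),
}
HOSPITAL_TOTALS = {"pfos": 8_746_157, "soc": 9_736_209}

# gestational-age subgroup totals (pooled cohort of 100)
SUBGROUP_TABLE = {
    "GAB 25-28": (13_824_084, 14_009_788),
    "GAB 29-30": (8_092_140, 9_714_029),
}
SUBGROUP_TOTALS = {"pfos": 21_916_224, "soc": 23_723_817}

COVERED_LIVES = 982_791
PAYER_MONTHS = 60
PMPM_EXPECTED = {"pfos": 0.37, "soc": 0.41, "saving": 0.04}

# per-arm mean NICU length-of-stay model inputs (days)
MEAN_NICU_LOS = {"soc": 65.8, "pfos": 59.8}
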