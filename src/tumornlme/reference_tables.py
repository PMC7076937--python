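"""Published information-criterion summaries for the mouse cisplatin study
that the synthetic cohorts emulate.

The underlying animal data were never deposited, so the absolute -2LL values
are not recomputable here; they serve as fixed inputs from which the derived
columns (AIC reconstruction, evidence weights) are recomputed at run time by
``tumornlme reproduce-tables`` and the test suite.  Columns per row:
(-2LL, AIC, AICc, BIC) as printed, to two decimals.

Parameter counts implied by the printed AIC - (-2LL) gaps are recorded in
``IMPLIED_K``; note the published table's own counts are not fully internally
consistent (the AICc and BIC gaps imply different k for some rows), which is
why weights are always recomputed from the printed IC values themselves.
"""

# untreated cohort: four candidate growth laws, 21 subjects, 386 observations
CONTROL_TABLE = {
    "generalized_logistic": {"minus2LL": 5159.69, "AIC": 5179.69, "AICc": 5180.07, "BIC": 5190.13},
    "gompertz": {"minus2LL": 5182.79, "AIC": 5198.79, "AICc": 5199.01, "BIC": 5207.15},
    "von_bertalanffy": {"minus2LL": 5189.97, "AIC": 5209.97, "AICc": 5210.35, "BIC": 5226.42},
    "simeoni": {"minus2LL": 5148.52, "AIC": 5168.52, "AICc": 5168.90, "BIC": 5179.01},
}

# treated cohort: transit-chain variants vs the explicit-delay model,
# 19 subjects, 545 observations
TREATED_TABLE = {
    "simeoni-1": {"minus2LL": 6786.12, "AIC": 6818.12, "AICc": 6818.91, "BIC": 6833.23},
    "simeoni-2": {"minus2LL": 6780.10, "AIC": 6812.10, "AICc": 6812.89, "BIC": 6827.21},
    "simeoni-3": {"minus2LL": 6780.32, "AIC": 6812.32, "AICc": 6813.11, "BIC": 6827.44},
    "delay": {"minus2LL": 6775.61, "AIC": 6811.61, "AICc": 6812.64, "BIC": 6828.61},
}

#: k implied by AIC - (-2LL) = 2k in the printed rows
IMPLIED_K = {
    "control": {"generalized_logistic": 10, "gompertz": 8, "von_bertalanffy": 10, "simeoni": 10},
    "treated": {"simeoni-1": 16, "simeoni-2": 16, "simeoni-3": 16, "delay": 18},
}

CONTROL_N_OBS = 386
CONTROL_N_SUBJECTS = 21
TREATED_N_OBS = 545
TREATED_N_SUBJECTS = 19
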