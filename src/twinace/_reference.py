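"""Reference values from a published population twin study of autistic
traits and four receptive-language measures (same-sex pairs, age 12).

These constants serve two purposes: the printed model-fit table is used to
validate the package's model-comparison arithmetic (likelihood-ratio
differences, AIC), and the published group sizes and standardized
variance-component estimates parameterize the study-like simulation
preset.  They are inputs, not outputs, of this package.
"""

from __future__ import annotations

PHENOTYPES = ("traits", "figurative", "pragmatics", "syntax", "vocabulary")

#: same-sex pair counts per zygosity-sex group
GROUP_N_PAIRS = {"MZM": 1113, "DZM": 1102, "MZF": 1293, "DZF": 1188}

#: standardized variance proportions (ACE, quantitative sex limitation)
VARIANCE_COMPONENTS = {
    "M": {
        "A": (0.73, 0.39, 0.18, 0.25, 0.27),
        "C": (0.04, 0.12, 0.15, 0.18, 0.19),
    },
    "F": {
        "A": (0.52, 0.39, 0.25, 0.22, 0.33),
        "C": (0.25, 0.12, 0.12, 0.21, 0.12),
    },
}

#: published fit-comparison table: model -> (-2LL, df, n_parameters) and the
#: printed contrasts vs the saturated model / best-fitting full model.
#: Some printed AE/CE AIC entries are internally inconsistent with the
#: chi2 - 2*df formula; they are kept exactly as printed.
FIT_TABLE = {
    "equated": {
        "saturated": {"minus2LL": 76817.71, "df": 29654, "parameters": 130},
        "ACE": {
            "minus2LL": 76944.08,
            "df": 29725,
            "parameters": 50,
            "vs_saturated": {"delta_chi2": 126.37, "delta_df": 80, "aic": -33.63},
        },
        "ADE": {
            "minus2LL": 76995.10,
            "df": 29725,
            "parameters": 50,
            "vs_saturated": {"delta_chi2": 177.39, "delta_df": 80, "aic": 17.39},
        },
    },
    "quantitative": {
        "saturated": {"minus2LL": 76672.36, "df": 29515, "parameters": 260},
        "ACE": {
            "minus2LL": 76888.36,
            "df": 29675,
            "parameters": 100,
            "vs_saturated": {"delta_chi2": 216.02, "delta_df": 160, "aic": -103.98},
        },
        "ADE": {
            "minus2LL": 76950.33,
            "df": 29675,
            "parameters": 100,
            "vs_saturated": {"delta_chi2": 277.97, "delta_df": 160, "aic": -42.03},
        },
        "AE": {
            "minus2LL": 76962.25,
            "df": 29705,
            "parameters": 70,
            "vs_saturated": {"delta_chi2": 289.89, "delta_df": 190, "aic": -70.11},
            "vs_best_full": {"delta_chi2": 77.86, "delta_df": 30, "aic": 13.86},
        },
        "CE": {
            "minus2LL": 77423.37,
            "df": 29705,
            "parameters": 70,
            "vs_saturated": {"delta_chi2": 751.01, "delta_df": 190, "aic": 391.01},
            "vs_best_full": {"delta_chi2": 534.98, "delta_df": 30, "aic": 474.98},
        },
        "E": {
            "minus2LL": 80402.56,
            "df": 29735,
            "parameters": 40,
            "vs_saturated": {"delta_chi2": 3730.20, "delta_df": 220, "aic": 3290.20},
            "vs_best_full": {"delta_chi2": 3514.17, "delta_df": 60, "aic": 3394.17},
        },
    },
}
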