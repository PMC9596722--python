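"""Published summary statistics for the two harmonized GSE75010 cohorts.

These constants are the printed per-gene descriptive statistics (log2
means and SDs per group, two-sample t-test p-values and BH FDR values) for
the 17 core circadian clock genes in the two cohorts GSE75010-157
(77 non-PE vs 80 PE) and GSE75010-173 (96 non-PE vs 77 PE), the term-only
subgroup of GSE75010-157 (42 non-PE vs 31 PE after removing preterm
births), and the 2x2 risk-score contingency tables.

They serve two purposes: they parameterize the synthetic cohort generator
(group means/SDs are the study conditions being emulated) and they are the
verification surface for the arithmetic stages (BH adjustment, percent
change, significance filtering, Firth odds ratios) that are exactly
recomputable from printed numbers.

p-values printed as "< 0.0001" are stored as 0.0001.
"""

from __future__ import annotations

CIRCADIAN_GENES: tuple[str, ...] = (
    "ARNTL", "ARNTL2", "CLOCK", "CRY1", "CRY2", "NPAS1", "NPAS2", "NPAS3",
    "NR1D1", "NR1D2", "PER1", "PER2", "PER3", "RORA", "RORB", "RORC",
    "TIMELESS",
)

#: cohort -> (n_control, n_case)
GROUP_SIZES: dict[str, tuple[int, int]] = {
    "157": (77, 80),
    "173": (96, 77),
    "157-term": (42, 31),
}

#: cohort -> gene -> (mu_control, sd_control, mu_case, sd_case), log2 units
GENE_STATS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "157": {
        "ARNTL":    (7.36, 0.38, 7.38, 0.42),
        "ARNTL2":   (7.95, 0.40, 8.09, 0.42),
        "CLOCK":    (8.88, 0.50, 8.73, 0.53),
        "CRY1":     (8.39, 0.41, 8.53, 0.39),
        "CRY2":     (8.39, 0.27, 8.38, 0.28),
        "NPAS1":    (6.56, 0.36, 6.76, 0.39),
        "NPAS2":    (9.06, 0.37, 8.96, 0.32),
        "NPAS3":    (6.55, 0.42, 6.45, 0.37),
        "NR1D1":    (7.23, 0.40, 7.32, 0.34),
        "NR1D2":    (8.80, 0.48, 8.45, 0.51),
        "PER1":     (7.40, 0.37, 7.41, 0.47),
        "PER2":     (7.93, 0.38, 8.08, 0.32),
        "PER3":     (7.30, 0.32, 7.04, 0.30),
        "RORA":     (8.54, 0.43, 8.52, 0.40),
        "RORB":     (6.64, 0.67, 7.00, 0.93),
        "RORC":     (6.56, 0.35, 6.64, 0.35),
        "TIMELESS": (7.92, 0.40, 7.73, 0.32),
    },
    "173": {
        "ARNTL":    (7.38, 0.39, 7.35, 0.32),
        "ARNTL2":   (8.01, 0.41, 8.01, 0.43),
        "CLOCK":    (8.88, 0.53, 8.71, 0.40),
        "CRY1":     (8.40, 0.40, 8.53, 0.36),
        "CRY2":     (8.40, 0.29, 8.38, 0.26),
        "NPAS1":    (6.68, 0.44, 6.61, 0.45),
        "NPAS2":    (8.99, 0.38, 9.03, 0.32),
        "NPAS3":    (6.51, 0.40, 6.48, 0.39),
        "NR1D1":    (7.28, 0.36, 7.22, 0.41),
        "NR1D2":    (8.70, 0.51, 8.49, 0.41),
        "PER1":     (7.37, 0.44, 7.43, 0.39),
        "PER2":     (8.05, 0.33, 7.95, 0.36),
        "PER3":     (7.25, 0.30, 7.03, 0.27),
        "RORA":     (8.59, 0.42, 8.45, 0.36),
        "RORB":     (6.79, 0.67, 6.87, 0.82),
        "RORC":     (6.55, 0.39, 6.62, 0.38),
        "TIMELESS": (7.82, 0.37, 7.83, 0.36),
    },
    "157-term": {
        "ARNTL":    (7.22, 0.33, 7.39, 0.41),
        "ARNTL2":   (8.03, 0.37, 7.96, 0.39),
        "CLOCK":    (9.06, 0.33, 8.73, 0.69),
        "CRY1":     (8.55, 0.34, 8.52, 0.51),
        "CRY2":     (8.44, 0.24, 8.34, 0.30),
        "NPAS1":    (6.57, 0.37, 6.77, 0.46),
        "NPAS2":    (9.07, 0.29, 8.93, 0.34),
        "NPAS3":    (6.58, 0.44, 6.49, 0.41),
        "NR1D1":    (7.33, 0.34, 7.36, 0.33),
        "NR1D2":    (8.92, 0.40, 8.61, 0.56),
        "PER1":     (7.35, 0.26, 7.31, 0.38),
        "PER2":     (8.05, 0.32, 7.99, 0.29),
        "PER3":     (7.34, 0.30, 7.16, 0.30),
        "RORA":     (8.77, 0.32, 8.58, 0.41),
        "RORB":     (6.55, 0.58, 6.84, 0.97),
        "RORC":     (6.61, 0.35, 6.59, 0.36),
        "TIMELESS": (7.78, 0.35, 7.72, 0.40),
    },
}

#: cohort -> gene -> printed two-sided t-test p-value ("<0.0001" -> 0.0001)
PRINTED_P: dict[str, dict[str, float]] = {
    "157": {
        "ARNTL": 0.7006, "ARNTL2": 0.0346, "CLOCK": 0.0766, "CRY1": 0.0250,
        "CRY2": 0.9098, "NPAS1": 0.0008, "NPAS2": 0.0759, "NPAS3": 0.1226,
        "NR1D1": 0.1262, "NR1D2": 0.0001, "PER1": 0.8812, "PER2": 0.0096,
        "PER3": 0.0001, "RORA": 0.7598, "RORB": 0.0063, "RORC": 0.1711,
        "TIMELESS": 0.0015,
    },
    "173": {
        "ARNTL": 0.5509, "ARNTL2": 0.9995, "CLOCK": 0.0181, "CRY1": 0.0209,
        "CRY2": 0.6289, "NPAS1": 0.2943, "NPAS2": 0.4382, "NPAS3": 0.6276,
        "NR1D1": 0.2638, "NR1D2": 0.0030, "PER1": 0.3200, "PER2": 0.0737,
        "PER3": 0.0001, "RORA": 0.0204, "RORB": 0.4664, "RORC": 0.2341,
        "TIMELESS": 0.9138,
    },
    "157-term": {
        "ARNTL": 0.0619, "ARNTL2": 0.3919, "CLOCK": 0.0168, "CRY1": 0.7561,
        "CRY2": 0.0943, "NPAS1": 0.0449, "NPAS2": 0.0724, "NPAS3": 0.3971,
        "NR1D1": 0.6501, "NR1D2": 0.0120, "PER1": 0.6164, "PER2": 0.3812,
        "PER3": 0.0137, "RORA": 0.0308, "RORB": 0.1535, "RORC": 0.8158,
        "TIMELESS": 0.5378,
    },
}

#: cohort -> gene -> printed BH FDR value
PRINTED_FDR: dict[str, dict[str, float]] = {
    "157": {
        "ARNTL": 0.8507, "ARNTL2": 0.0735, "CLOCK": 0.1302, "CRY1": 0.0607,
        "CRY2": 0.9098, "NPAS1": 0.0045, "NPAS2": 0.1302, "NPAS3": 0.1788,
        "NR1D1": 0.1778, "NR1D2": 0.0008, "PER1": 0.9098, "PER2": 0.0272,
        "PER3": 0.0008, "RORA": 0.8611, "RORB": 0.0214, "RORC": 0.2237,
        "TIMELESS": 0.0064,
    },
    "173": {
        "ARNTL": 0.7128, "ARNTL2": 0.9995, "CLOCK": 0.0711, "CRY1": 0.0711,
        "CRY2": 0.7128, "NPAS1": 0.5440, "NPAS2": 0.6607, "NPAS3": 0.7128,
        "NR1D1": 0.5440, "NR1D2": 0.0255, "PER1": 0.5440, "PER2": 0.2088,
        "PER3": 0.0017, "RORA": 0.0711, "RORB": 0.6607, "RORC": 0.5440,
        "TIMELESS": 0.9709,
    },
    "157-term": {
        "ARNTL": 0.1754, "ARNTL2": 0.5626, "CLOCK": 0.0952, "CRY1": 0.8034,
        "CRY2": 0.2004, "NPAS1": 0.1527, "NPAS2": 0.1758, "NPAS3": 0.5626,
        "NR1D1": 0.7368, "NR1D2": 0.0952, "PER1": 0.7368, "PER2": 0.5626,
        "PER3": 0.0952, "RORA": 0.1309, "RORB": 0.2899, "RORC": 0.8158,
        "TIMELESS": 0.7033,
    },
}

#: The single printed FDR cell that BH on the printed p-values does not
#: reproduce (prints 0.1778; BH gives 0.1788 — presumably a transcription
#: slip in the source table).
FDR_TYPO_CELLS: tuple[tuple[str, str], ...] = (("157", "NR1D1"),)

#: Risk-score 2x2 tables: cohort -> {"low"/"high": (n_non_pe, n_pe)}.
#: "low" is the score <= median row, "high" the score > median row.
RISK_TABLE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "157": {"low": (54, 24), "high": (23, 56)},
    "173": {"low": (65, 21), "high": (31, 56)},
}

#: Published Firth odds ratios (95% CI) for score > median vs <= median.
PRINTED_OR: dict[str, tuple[float, float, float]] = {
    "157": (5.35, 2.70, 10.57),
    "173": (5.46, 2.83, 10.54),
}

#: Integer offsets of the published risk scores.
OVERALL_SCORE_OFFSETS: dict[str, int] = {"NR1D2": 11, "PER3": 9}
OVERALL_SCORE_UP: tuple[str, ...] = ("CRY1",)
TERM_SCORE_OFFSETS: dict[str, int] = {"CLOCK": 10, "NR1D2": 11, "PER3": 9}
TERM_SCORE_UP: tuple[str, ...] = ()
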