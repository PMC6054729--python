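"""Published reference values from the motivating CD-vs-UC cohort study.

The original patient-level data were never deposited, but the study's
reported per-variable raw permutation p-values (B = 10,000) are themselves a
complete input to the multiplicity stage, and its adjusted p-values and
nine-variable significant set serve as reference outputs.  One known
internal inconsistency in the published report: the step-down table prints a
raw p of 0.0567 for follow-up time while the descriptive table and the
adjusted value 0.5770 (= 10 × 0.0577) both imply 0.0577.
``cd_uc_raw_pvalues(self_consistent=True)`` substitutes the self-consistent
value.
"""

from __future__ import annotations

# variable -> raw p as printed in the published step-down table
_RAW_P = {
    "Diagnosis age": 0.0281,
    "Gender": 0.0019,
    "Smoking habit": 0.0001,
    "Immunosuppressive therapy": 0.0002,
    "Duration of immunosuppr. therapy": 0.0032,
    "Biological drugs": 0.0004,
    "Duration of biological treatment": 0.0053,
    "Re-hospitalization": 0.0008,
    "Adverse events": 0.0007,
    "Infections": 0.6274,
    "Cancers": 0.2755,
    "Diabetes": 0.0006,
    "Hypertension": 0.7376,
    "Heart failure": 0.9852,
    "Kidney failure": 0.5074,
    "Pulmonary failure": 0.1553,
    "Neuropathy": 0.8858,
    "Liver disease": 0.6075,
    "Charlson score": 0.0316,
    "Surgery": 0.0003,
    "Final exitus": 0.6643,
    "Follow-up time": 0.0567,
}

# variable -> (rank i in the ascending sort, adjusted p) as printed
_ADJUSTED = {
    "Diagnosis age": (11, 0.3372),
    "Gender": (8, 0.0285),
    "Smoking habit": (1, 0.0022),
    "Immunosuppressive therapy": (2, 0.0042),
    "Duration of immunosuppr. therapy": (9, 0.0448),
    "Biological drugs": (4, 0.0076),
    "Duration of biological treatment": (10, 0.0689),
    "Re-hospitalization": (7, 0.0128),
    "Adverse events": (6, 0.0119),
    "Infections": (18, 0.9999),
    "Cancers": (15, 0.9999),
    "Diabetes": (5, 0.0108),
    "Hypertension": (20, 0.9999),
    "Heart failure": (22, 0.9999),
    "Kidney failure": (16, 0.9999),
    "Pulmonary failure": (14, 0.9999),
    "Neuropathy": (21, 0.9999),
    "Liver disease": (17, 0.9999),
    "Charlson score": (12, 0.3476),
    "Surgery": (3, 0.0060),
    "Final exitus": (19, 0.9999),
    "Follow-up time": (13, 0.5770),
}

# the nine variables the published step-down analysis declares significant
HOLM_SIGNIFICANT_SET = frozenset(
    {
        "Smoking habit",
        "Immunosuppressive therapy",
        "Surgery",
        "Biological drugs",
        "Diabetes",
        "Adverse events",
        "Re-hospitalization",
        "Gender",
        "Duration of immunosuppr. therapy",
    }
)

INCONSISTENT_VARIABLE = "Follow-up time"


def cd_uc_raw_pvalues(self_consistent: bool = False) -> dict[str, float]:
    """The 22 published raw permutation p-values, in table order."""
    out = dict(_RAW_P)
    if self_consistent:
        out[INCONSISTENT_VARIABLE] = 0.0577
    return out


def cd_uc_adjusted_pvalues() -> dict[str, tuple[int, float]]:
    """The published (rank i, adjusted p) per variable, in table order."""
    return dict(_ADJUSTED)
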