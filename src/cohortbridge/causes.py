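"""Cause-of-death labels, ICD-10-style codes and coding-policy constants.

The cause list is deliberately small: two sex-specific cancers, a residual
cancer group, cardiovascular disease, suicide and a residual group. These
are the groups the downstream rate and trend analyses distinguish; the
pre-1995 priority-coding rules operate on them.
"""

from __future__ import annotations

# Canonical cause labels, in a fixed order used throughout the package.
CAUSES: tuple[str, ...] = (
    "breast",
    "prostate",
    "other_cancer",
    "cardiovascular",
    "suicide",
    "other",
)

# ICD-10-style code for each label (ranges abbreviated to their anchor code).
ICD10_CODES: dict[str, str] = {
    "breast": "C50",
    "prostate": "C61",
    "other_cancer": "C00-C97",
    "cardiovascular": "I00-I52",
    "suicide": "X60-X84",
    "other": "R99",
}

# Reverse lookup so rules can be queried with either a label or a code.
_CODE_TO_LABEL: dict[str, str] = {v: k for k, v in ICD10_CODES.items()}

CANCER_CAUSES: frozenset[str] = frozenset({"breast", "prostate", "other_cancer"})

# Sex-specific causes: the only sex for which the cause is possible.
SEX_RESTRICTED: dict[str, str] = {"breast": "female", "prostate": "male"}

# Pre-1995 coder priority, highest first: external causes (here suicide),
# influenza (kept as a slot even though the default cause list has no
# influenza label), then cancers. When several mentioned causes share the
# list, the earliest entry wins.
DEFAULT_PRIORITY_CAUSES: tuple[str, ...] = (
    "suicide",
    "influenza",
    "breast",
    "prostate",
    "other_cancer",
)


def normalize_cause(cause: str) -> str:
    """Return the canonical label for a cause given as label or ICD code."""
    if cause in _CODE_TO_LABEL:
        return _CODE_TO_LABEL[cause]
    return cause
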