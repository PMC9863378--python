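"""Published reference data: clearance-index summary, final models, split sets.

These are the printed results of the source study (15 bisphenols perfused on
five placentae; three final multilinear models) kept as fixtures so the
pipeline's replay and validation machinery can be exercised against them.
"""

from __future__ import annotations

from .io import (
    CISummary,
    PublishedModel,
    build_chrom_schema,
    build_molecular_schema,
)

import pandas as pd

LIMITED = "limited"
ANTIPYRINE_LIKE = "antipyrine-like"

# (compound, mean CI, SD, transfer class); CI is dimensionless, n = 5 placentae.
_TABLE1 = [
    ("BPFL", 0.064, 0.021, LIMITED),
    ("BPS", 0.082, 0.016, LIMITED),
    ("BPBP", 0.256, 0.046, LIMITED),
    ("BPZ", 0.318, 0.090, LIMITED),
    ("BPC", 0.392, 0.076, LIMITED),
    ("BPM", 0.442, 0.149, LIMITED),
    ("BPP", 0.452, 0.048, LIMITED),
    ("BPAF", 0.524, 0.071, LIMITED),
    ("BPAP", 0.570, 0.062, ANTIPYRINE_LIKE),
    ("BP44", 0.662, 0.135, ANTIPYRINE_LIKE),
    ("BPE", 0.686, 0.158, ANTIPYRINE_LIKE),
    ("BPF", 0.696, 0.142, ANTIPYRINE_LIKE),
    ("3-3BPA", 0.722, 0.070, ANTIPYRINE_LIKE),
    ("BPA", 0.812, 0.065, ANTIPYRINE_LIKE),
    ("BPB", 0.842, 0.080, ANTIPYRINE_LIKE),
]

BISPHENOLS = tuple(row[0] for row in _TABLE1)


def table1_fixture() -> CISummary:
    """Mean +/- SD clearance indices of the 15 bisphenols (5 placentae each)."""
    df = pd.DataFrame(
        {
            "compound_id": [r[0] for r in _TABLE1],
            "mean_ci": [r[1] for r in _TABLE1],
            "sd_ci": [r[2] for r in _TABLE1],
            "n_replicates": [5] * len(_TABLE1),
            "transfer_class": [r[3] for r in _TABLE1],
        }
    )
    return CISummary(df)


_MODELS = {
    # CI = 0.46 + 0.23 LP2 - 0.08 MT5 - 0.30 DE1 + 0.41 DE2 (weighting 1/Y)
    "molecular": PublishedModel(
        name="molecular",
        intercept=0.46,
        coefficients=(("LP2", 0.23), ("MT5", -0.08), ("DE1", -0.30), ("DE2", 0.41)),
    ),
    # CI = 0.48 - 0.03 CPS3 - 0.23 MT2 + 0.33 DE9 - 0.25 C8A2 + 0.37 RCBA8
    #      - 0.27 PFPM2 + 0.23 PFPM7
    "combined": PublishedModel(
        name="combined",
        intercept=0.48,
        coefficients=(
            ("CPS3", -0.03),
            ("MT2", -0.23),
            ("DE9", 0.33),
            ("C8A2", -0.25),
            ("RCBA8", 0.37),
            ("PFPM2", -0.27),
            ("PFPM7", 0.23),
        ),
    ),
    # CI = 0.48 - 0.66 T3A2 - 0.05 PFPA7 + 0.07 CC18A7 - 0.50 C8M7
    #      - 0.14 PFPM7 + 0.38 CNM8
    "chromatographic": PublishedModel(
        name="chromatographic",
        intercept=0.48,
        coefficients=(
            ("T3A2", -0.66),
            ("PFPA7", -0.05),
            ("CC18A7", 0.07),
            ("C8M7", -0.50),
            ("PFPM7", -0.14),
            ("CNM8", 0.38),
        ),
    ),
}


def published_model(name: str) -> PublishedModel:
    """One of the three final models: molecular, combined, chromatographic."""
    try:
        model = _MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(_MODELS)}") from None
    # sanity: codes resolve in the canonical schemas
    mol = build_molecular_schema()
    chrom = build_chrom_schema()
    for code in model.codes:
        assert code in mol or code in chrom, code
    return model


# Test-set allocations of the three leave-many-out data sets.  High-leverage
# compounds are pinned to every training set: BPS and BPFL always, plus BPAF
# (molecular-only model) or BP44 (models using chromatographic descriptors).
_TEST_SETS_MOLECULAR = (
    ("BP44", "BPB", "3-3BPA", "BPZ"),
    ("BPP", "BPM", "BPAP", "BPBP"),
    ("BPE", "BPA", "BPF", "BPC"),
)
_TEST_SETS_CHROM = (
    ("BPAF", "BPB", "3-3BPA", "BPZ"),
    ("BPP", "BPM", "BPAP", "BPBP"),
    ("BPE", "BPA", "BPF", "BPC"),
)


def split_plan_fixture(kind: str = "chromatographic"):
    """The published train/test allocation for the given descriptor mode."""
    from .validation import SplitPlan

    if kind == "molecular":
        tests, pinned = _TEST_SETS_MOLECULAR, ("BPS", "BPFL", "BPAF")
    elif kind in ("chromatographic", "combined"):
        tests, pinned = _TEST_SETS_CHROM, ("BPS", "BPFL", "BP44")
    else:
        raise KeyError(f"unknown split fixture {kind!r}")
    sets = []
    for test in tests:
        train = tuple(c for c in BISPHENOLS if c not in test)
        sets.append((train, test))
    return SplitPlan(sets=tuple(sets), pinned=pinned)
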