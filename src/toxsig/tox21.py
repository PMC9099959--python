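"""Published Tox21 Data Challenge per-assay summaries.

Per-assay active/inactive counts for the pre-processed training and test
partitions of the twelve qHTS assays, together with the imbalance ratio
(IR = inactive/active) and held-out model performance reported for the
interaction-signature pipeline on this benchmark.  These summaries are
small published statistics, not raw data; they serve as inputs for
arithmetic validation: the IR column can be recomputed from the counts,
and the confusion-derived metric columns can be recomputed from the test
partition counts plus the reported recall and specificity via
:func:`toxsig.metrics.reconstruct_confusion`.

Note the published IR column mixes rounding conventions: most entries
are the ratio rounded to 2 decimals, but a few (e.g. 6521/211 = 30.9052
shown as 30.90) are truncated.  ``ir_matches_printed`` accepts either.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "assay_counts",
    "reported_metrics",
    "ir_matches_printed",
    "ASSAYS",
]

ASSAYS = [
    "NR-AhR", "NR-ER-LBD", "NR-ER", "NR-Aromatase", "NR-PPAR-gamma",
    "NR-AR", "NR-AR-LBD", "SR-MMP", "SR-ARE", "SR-ATAD5", "SR-p53", "SR-HSE",
]

# assay: (train_inactive, train_active, train_IR, test_inactive, test_active, test_IR)
_COUNTS = {
    "NR-AhR":        (5777, 734, 7.87, 521, 71, 7.34),
    "NR-ER-LBD":     (6643, 282, 23.56, 564, 20, 28.20),
    "NR-ER":         (5474, 651, 8.41, 456, 49, 9.31),
    "NR-Aromatase":  (5496, 274, 20.06, 479, 37, 12.94),
    "NR-PPAR-gamma": (6283, 167, 37.62, 559, 30, 18.63),
    "NR-AR":         (6958, 252, 27.61, 561, 12, 46.75),
    "NR-AR-LBD":     (6521, 211, 30.90, 558, 8, 69.75),
    "SR-MMP":        (4899, 888, 5.52, 474, 55, 8.62),
    "SR-ARE":        (4919, 881, 5.58, 450, 89, 5.06),
    "SR-ATAD5":      (6787, 256, 26.51, 569, 34, 16.73),
    "SR-p53":        (6351, 409, 15.53, 560, 38, 14.74),
    "SR-HSE":        (6144, 305, 20.14, 574, 17, 33.76),
}

# assay: f1, precision, recall, auc_roc, auc_pr, ba, mcc, specificity, accuracy
_METRICS = {
    "NR-AhR":        (0.471, 0.318, 0.901, 0.896, 0.560, 0.819, 0.438, 0.737, 0.757),
    "NR-ER-LBD":     (0.342, 0.333, 0.350, 0.810, 0.272, 0.663, 0.318, 0.975, 0.954),
    "NR-ER":         (0.420, 0.301, 0.694, 0.806, 0.414, 0.760, 0.370, 0.827, 0.814),
    "NR-Aromatase":  (0.317, 0.250, 0.432, 0.795, 0.282, 0.666, 0.260, 0.900, 0.866),
    "NR-PPAR-gamma": (0.286, 0.308, 0.267, 0.745, 0.241, 0.617, 0.251, 0.968, 0.932),
    "NR-AR":         (0.261, 0.273, 0.250, 0.706, 0.196, 0.618, 0.178, 0.988, 0.970),
    "NR-AR-LBD":     (0.000, 0.000, 0.000, 0.618, 0.036, 0.493, -0.014, 0.986, 0.972),
    "SR-MMP":        (0.488, 0.331, 0.927, 0.916, 0.597, 0.855, 0.478, 0.783, 0.798),
    "SR-ARE":        (0.425, 0.305, 0.697, 0.757, 0.403, 0.692, 0.294, 0.687, 0.688),
    "SR-ATAD5":      (0.325, 0.283, 0.382, 0.744, 0.230, 0.662, 0.282, 0.942, 0.910),
    "SR-p53":        (0.235, 0.159, 0.447, 0.830, 0.198, 0.643, 0.182, 0.839, 0.814),
    "SR-HSE":        (0.286, 0.308, 0.267, 0.759, 0.240, 0.617, 0.251, 0.968, 0.932),
}

_METRIC_COLS = [
    "f1", "precision", "recall", "auc_roc", "auc_pr",
    "balanced_accuracy", "mcc", "specificity", "accuracy",
]


def assay_counts() -> pd.DataFrame:
    """Published per-assay class counts and imbalance ratios."""
    df = pd.DataFrame.from_dict(
        _COUNTS,
        orient="index",
        columns=[
            "train_inactive", "train_active", "train_ir",
            "test_inactive", "test_active", "test_ir",
        ],
    ).loc[ASSAYS]
    df.index.name = "assay"
    return df


def reported_metrics() -> pd.DataFrame:
    """Published held-out performance per assay."""
    df = pd.DataFrame.from_dict(_METRICS, orient="index", columns=_METRIC_COLS).loc[ASSAYS]
    df.index.name = "assay"
    return df


def ir_matches_printed(inactive: int, active: int, printed: float) -> bool:
    """Does inactive/active reproduce the printed 2-decimal IR?

    Accepts both round-half and truncation at the second decimal, since
    the published table mixes the two.
    """
    ratio = inactive / active
    return (
        round(ratio, 2) == round(printed, 2)
        or math.floor(ratio * 100) / 100 == round(printed, 2)
    )
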