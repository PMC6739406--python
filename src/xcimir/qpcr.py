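"""Validation-arm arithmetic: 2^-ddCt relative quantification and MFI ratios.

Relative quantification follows the standard comparative-Ct scheme with
dual reference normalization:

    Ct(sample, assay)   = mean of replicate Cts
    Ct_ref(sample)      = arithmetic mean over the reference assays
                          (equivalent to the geometric mean of the
                          reference quantities)
    dCt(sample)         = Ct(target) - Ct_ref
    dCt(group)          = mean of sample dCts
    ddCt                = dCt(test group) - dCt(calibrator group)
    fold                = 2 ** (-ddCt)

A fold change is significant when its magnitude reaches the threshold in
either direction: max(fold, 1/fold) >= fold_threshold (default 1.5,
boundary inclusive).
"""

from __future__ import annotations

import math
from typing import Sequence

from .models import DataError, FoldChangeResult, MfiRatio, QpcrSample

DEFAULT_REFERENCES = ("RNU6B", "RNU44")


def _delta_cts(
    samples: Sequence[QpcrSample],
    target_assay: str,
    reference_assays: Sequence[str],
    group: str,
) -> dict[str, float]:
    """Per-sample dCt = target Ct - mean reference Ct for one group."""
    by_sample: dict[str, dict[str, QpcrSample]] = {}
    for s in samples:
        if s.group == group:
            by_sample.setdefault(s.sample_id, {})[s.assay] = s
    if not by_sample:
        raise DataError(f"group {group!r} has no samples")
    dcts: dict[str, float] = {}
    for sample_id, assays in sorted(by_sample.items()):
        if target_assay not in assays:
            raise DataError(f"sample {sample_id!r} lacks target assay {target_assay!r}")
        missing = [r for r in reference_assays if r not in assays]
        if missing:
            raise DataError(f"sample {sample_id!r} lacks reference assay(s) {missing}")
        ref_ct = sum(assays[r].mean_ct for r in reference_assays) / len(reference_assays)
        dcts[sample_id] = assays[target_assay].mean_ct - ref_ct
    return dcts


def delta_delta_ct(
    samples: Sequence[QpcrSample],
    target_assay: str,
    reference_assays: Sequence[str] = DEFAULT_REFERENCES,
    group_test: str = "XX",
    group_calibrator: str = "XY",
    fold_threshold: float = 1.5,
    per_sample: bool = False,
) -> FoldChangeResult:
    """Group-vs-group fold change of a target assay by the 2^-ddCt method.

    With ``per_sample`` the result also carries each test-group sample's
    individual fold against the calibrator-group mean dCt.
    """
    if not reference_assays:
        raise DataError("at least one reference assay is required")
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    dct_test = _delta_cts(samples, target_assay, reference_assays, group_test)
    dct_cal = _delta_cts(samples, target_assay, reference_assays, group_calibrator)
    mean_test = sum(dct_test.values()) / len(dct_test)
    mean_cal = sum(dct_cal.values()) / len(dct_cal)
    ddct = mean_test - mean_cal
    fold = 2.0 ** (-ddct)
    magnitude = max(fold, 1.0 / fold)
    # boundary-inclusive up to float round-off in the Ct arithmetic
    significant = (
        magnitude >= fold_threshold
        or math.isclose(magnitude, fold_threshold, rel_tol=1e-9)
    )
    per_sample_folds = None
    if per_sample:
        per_sample_folds = {
            sid: 2.0 ** (-(d - mean_cal)) for sid, d in dct_test.items()
        }
    return FoldChangeResult(
        assay=target_assay,
        group_test=group_test,
        group_calibrator=group_calibrator,
        delta_ct_test=mean_test,
        delta_ct_cal=mean_cal,
        ddct=ddct,
        fold=fold,
        significant=significant,
        per_sample_folds=per_sample_folds,
    )


def mfi_ratio(
    numerator: float,
    denominator: float,
    numerator_label: str = "Bax",
    denominator_label: str = "Bcl-2",
) -> MfiRatio:
    """Ratio of two median fluorescence intensities (both must be > 0)."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("MFI values must be > 0")
    return MfiRatio(
        numerator_label=numerator_label,
        denominator_label=denominator_label,
        numerator=numerator,
        denominator=denominator,
        ratio=numerator / denominator,
    )
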