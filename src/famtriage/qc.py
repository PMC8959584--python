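"""Site-level quality filtering and coverage summaries.

Raw SNV/indel calls are retained only when read depth, RMS mapping quality
and variant quality all lie strictly above their thresholds (defaults
depth > 4, MQ > 30, QUAL > 20). Depth and MQ are site-level metrics (VCF
INFO DP/MQ), not per-sample values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AnnotatedVariant


@dataclass(frozen=True)
class QcThresholds:
    """Exclusive lower bounds for site QC metrics."""

    min_depth_exclusive: float = 4
    min_mq_exclusive: float = 30
    min_qual_exclusive: float = 20

    def __post_init__(self) -> None:
        for name in ("min_depth_exclusive", "min_mq_exclusive", "min_qual_exclusive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class QcRejection:
    variant_key: str
    reason: str  # depth / mq / qual / missing_metric
    value: float | None


def site_qc_filter(
    variants: list[AnnotatedVariant], thresholds: QcThresholds = QcThresholds()
) -> tuple[list[AnnotatedVariant], list[QcRejection]]:
    """Keep variants passing all three QC criteria; log the first failure otherwise.

    Criteria are tested in the order depth, MQ, QUAL, all as strict
    inequalities. A variant missing any metric is rejected with reason
    ``missing_metric`` (conservative: unknown quality is not trusted).
    """
    t = thresholds
    kept: list[AnnotatedVariant] = []
    rejected: list[QcRejection] = []
    for v in variants:
        if v.depth is None or v.mq is None or v.qual is None:
            rejected.append(QcRejection(v.key, "missing_metric", None))
        elif not v.depth > t.min_depth_exclusive:
            rejected.append(QcRejection(v.key, "depth", v.depth))
        elif not v.mq > t.min_mq_exclusive:
            rejected.append(QcRejection(v.key, "mq", v.mq))
        elif not v.qual > t.min_qual_exclusive:
            rejected.append(QcRejection(v.key, "qual", v.qual))
        else:
            kept.append(v)
    return kept, rejected


def coverage_summary(depth_profile, cutoffs=(10,)) -> dict:
    """Mean depth and fraction of positions covered at >= each cutoff.

    ``depth_profile`` is a per-position depth array (any 1-D sequence).
    """
    depths = np.asarray(depth_profile, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth profile")
    fractions = {float(c): float(np.mean(depths >= c)) for c in cutoffs}
    return {
        "mean_depth": float(depths.mean()),
        "n_positions": int(depths.size),
        "fraction_at_least": fractions,
    }
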