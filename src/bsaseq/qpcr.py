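"""Relative qPCR quantification by the comparative CT (delta-delta-Ct) method.

Each sample's target Ct is first normalized to a constitutive reference
transcript (delta Ct = Ct_target - Ct_reference), then expressed relative
to a calibrator sample:

    ddCt        = dCt_sample - dCt_calibrator
    fold change = 2 ** (-ddCt)

assuming perfect amplification efficiency (doubling per cycle), the
standard assumption of the comparative CT method.  Replicates are
aggregated by averaging Ct values (not fold changes); uncertainty is
propagated to the fold-change scale with the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

_LN2 = math.log(2.0)


@dataclass
class QPCRRecord:
    """One well: target and reference Ct for a sample replicate."""

    sample_id: str
    target_ct: float
    reference_ct: float
    replicate: int = 1

    def __post_init__(self):
        for v in (self.target_ct, self.reference_ct):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"Ct values must be positive and finite, got {v!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass
class RelativeExpression:
    sample_id: str
    calibrator_id: str
    delta_delta_ct: float
    fold_change: float
    fold_change_se: float = 0.0
    n_replicates: int = 1


def delta_delta_ct(
    target_ct_sample: float,
    ref_ct_sample: float,
    target_ct_cal: float,
    ref_ct_cal: float,
    sample_id: str = "sample",
    calibrator_id: str = "calibrator",
) -> RelativeExpression:
    """Single-measurement comparative CT.

    ddCt = (target - reference)_sample - (target - reference)_calibrator,
    fold change = 2^-ddCt.  Raises on non-finite Ct.
    """
    for v in (target_ct_sample, ref_ct_sample, target_ct_cal, ref_ct_cal):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (target_ct_sample - ref_ct_sample) - (target_ct_cal - ref_ct_cal)
    return RelativeExpression(
        sample_id=sample_id,
        calibrator_id=calibrator_id,
        delta_delta_ct=ddct,
        fold_change=2.0 ** (-ddct),
    )


def summarize_replicates(records: list[QPCRRecord], calibrator_id: str) -> list[RelativeExpression]:
    """Per-sample relative expression from replicated measurements.

    Delta Ct is averaged across a sample's replicates before the ddCt
    step.  The fold-change standard error uses the delta method:
    SE(2^-ddCt) = ln(2) * fold * SE(ddCt), where SE(ddCt) combines the
    standard errors of the sample and calibrator mean delta Ct in
    quadrature.  Single-replicate samples get SE 0.

    Raises
    ------
    ValueError
        If the calibrator sample has no records.
    """
    if not records:
        raise ValueError("no qPCR records")
    by_sample: dict[str, list[float]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec.delta_ct)
    if calibrator_id not in by_sample:
        raise ValueError(f"calibrator sample {calibrator_id!r} not present")

    def mean_se(values: list[float]) -> tuple[float, float]:
        n = len(values)
        mean = sum(values) / n
        if n < 2:
            return mean, 0.0
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        return mean, math.sqrt(var / n)

    cal_mean, cal_se = mean_se(by_sample[calibrator_id])
    out = []
    for sid in sorted(by_sample):
        mean, se = mean_se(by_sample[sid])
        ddct = mean - cal_mean
        fold = 2.0 ** (-ddct)
        se_ddct = math.sqrt(se**2 + cal_se**2) if sid != calibrator_id else se
        out.append(
            RelativeExpression(
                sample_id=sid,
                calibrator_id=calibrator_id,
                delta_delta_ct=ddct,
                fold_change=fold,
                fold_change_se=_LN2 * fold * se_ddct,
                n_replicates=len(by_sample[sid]),
            )
        )
    return out


def records_from_tsv(path) -> list[QPCRRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        QPCRRecord(
            sample_id=str(r.sample_id),
            target_ct=float(r.target_ct),
            reference_ct=float(r.reference_ct),
            replicate=int(getattr(r, "replicate", 1)),
        )
        for r in df.itertuples(index=False)
    ]


def expression_to_tsv(results: list[RelativeExpression], path, header_comments=()) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "calibrator_id": [r.calibrator_id for r in results],
            "delta_delta_ct": [r.delta_delta_ct for r in results],
            "fold_change": [r.fold_change for r in results],
            "fold_change_se": [r.fold_change_se for r in results],
            "n_replicates": [r.n_replicates for r in results],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
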