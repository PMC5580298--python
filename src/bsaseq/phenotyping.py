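"""Volatile phenotyping: peak normalization and producer calling.

GC/MS methyl anthranilate (MA) peak areas (single-ion monitoring, ion 119)
are normalized to the peak area of a spiked internal standard
(3-hexanone), giving a dimensionless relative abundance that is comparable
across samples.  A genotype is called an MA *producer* when its normalized
area exceeds a detection threshold in at least ``min_harvests`` harvests;
the default (any-harvest detection) reflects strong harvest-to-harvest
variability of the trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: numeric floor applied to the detection threshold so that exact zeros are
#: never "detected" even at threshold 0
DETECTION_EPS = 1e-12


@dataclass
class PhenotypeRecord:
    """One genotype x harvest volatile measurement.

    Either pass the raw MA and internal-standard peak areas (the
    normalized area is computed), or pass ``ma_norm_area`` directly for
    pre-normalized data.
    """

    genotype_id: str
    harvest_id: str
    ma_peak_area: float | None = None
    internal_standard_area: float | None = None
    ma_norm_area: float | None = None

    def __post_init__(self):
        if self.ma_norm_area is None:
            if self.ma_peak_area is None or self.internal_standard_area is None:
                raise ValueError("need raw peak areas or ma_norm_area")
            self.ma_norm_area = normalize_peak(self.ma_peak_area, self.internal_standard_area)
        if self.ma_norm_area < 0:
            raise ValueError("normalized area must be non-negative")


@dataclass
class ProducerCall:
    genotype_id: str
    is_producer: bool
    n_detected: int
    n_harvests: int
    max_norm_area: float


@dataclass
class ProducerFraction:
    """Producer fraction of a population, raw and as rounded percent."""

    n_producers: int
    n_total: int
    percent: float
    percent_rounded: int


def normalize_peak(ma_peak_area: float, internal_standard_area: float) -> float:
    """Ratio of the MA ion-119 peak area to the internal-standard area.

    Raises
    ------
    ValueError
        If the standard area is zero or negative (corrupt record) or the
        MA area is negative.
    """
    if not internal_standard_area > 0:
        raise ValueError(f"internal standard area must be positive, got {internal_standard_area!r}")
    if ma_peak_area < 0:
        raise ValueError("peak area must be non-negative")
    return ma_peak_area / internal_standard_area


def call_producers(
    records: list[PhenotypeRecord],
    detection_threshold: float = 0.0,
    min_harvests: int = 1,
) -> list[ProducerCall]:
    """Call each genotype's producer status from multi-harvest records.

    A harvest counts as detected when the normalized area strictly exceeds
    ``max(detection_threshold, DETECTION_EPS)``.  A genotype is a producer
    when it is detected in at least ``min_harvests`` harvests.  One call
    per genotype, ordered by genotype id.

    Raises
    ------
    ValueError
        On duplicate (genotype, harvest) pairs, empty input, or
        ``min_harvests < 1``.
    """
    if not records:
        raise ValueError("no phenotype records")
    if min_harvests < 1:
        raise ValueError("min_harvests must be >= 1")
    seen: set[tuple[str, str]] = set()
    by_genotype: dict[str, list[float]] = {}
    for rec in records:
        key = (rec.genotype_id, rec.harvest_id)
        if key in seen:
            raise ValueError(f"duplicate record for genotype {key[0]!r}, harvest {key[1]!r}")
        seen.add(key)
        by_genotype.setdefault(rec.genotype_id, []).append(rec.ma_norm_area)
    floor = max(detection_threshold, DETECTION_EPS)
    calls = []
    for gid in sorted(by_genotype):
        areas = by_genotype[gid]
        n_det = sum(1 for a in areas if a > floor)
        calls.append(
            ProducerCall(
                genotype_id=gid,
                is_producer=n_det >= min_harvests,
                n_detected=n_det,
                n_harvests=len(areas),
                max_norm_area=max(areas),
            )
        )
    return calls


def producer_fraction(calls: list[ProducerCall]) -> ProducerFraction:
    """Percentage of producers among the called genotypes."""
    if not calls:
        raise ValueError("no producer calls")
    k = sum(c.is_producer for c in calls)
    return fraction_percent(k, len(calls))


def fraction_percent(n_producers: int, n_total: int) -> ProducerFraction:
    """Producer percentage from raw counts, e.g. 37/114 -> 32.46 (32).

    Rounding is half-away-from-zero to the nearest integer percent, the
    convention for reporting segregation ratios.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_producers <= n_total:
        raise ValueError("n_producers out of range")
    pct = 100.0 * n_producers / n_total
    return ProducerFraction(
        n_producers=n_producers,
        n_total=n_total,
        percent=pct,
        percent_rounded=int(math.floor(pct + 0.5)),
    )


# ---------------------------------------------------------------------------
# TSV IO (dialect shared with the simulator)

def records_from_tsv(path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        PhenotypeRecord(genotype_id=str(r.genotype_id), harvest_id=str(r.harvest_id), ma_norm_area=float(r.ma_norm_area))
        for r in df.itertuples(index=False)
    ]


def records_to_tsv(records: list[PhenotypeRecord], path, header_comments=()) -> None:
    df = pd.DataFrame(
        {
            "genotype_id": [r.genotype_id for r in records],
            "harvest_id": [r.harvest_id for r in records],
            "ma_norm_area": [r.ma_norm_area for r in records],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def calls_to_tsv(calls: list[ProducerCall], path, header_comments=()) -> None:
    df = pd.DataFrame(
        {
            "genotype_id": [c.genotype_id for c in calls],
            "is_producer": [int(c.is_producer) for c in calls],
            "n_detected": [c.n_detected for c in calls],
            "n_harvests": [c.n_harvests for c in calls],
            "max_norm_area": [c.max_norm_area for c in calls],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def calls_from_tsv(path) -> list[ProducerCall]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ProducerCall(
            genotype_id=str(r.genotype_id),
            is_producer=bool(r.is_producer),
            n_detected=int(r.n_detected),
            n_harvests=int(r.n_harvests),
            max_norm_area=float(r.max_norm_area),
        )
        for r in df.itertuples(index=False)
    ]
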