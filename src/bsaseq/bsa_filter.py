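"""In-silico bulked-segregant candidate filtering of transcript expression.

Given per-genotype RPKM values, producer/non-producer bulk assignments
and (optionally) a cross-assembly match table, a cascade of filters
narrows the transcriptome to contigs whose detection pattern tracks the
producer phenotype:

* **filter 1** — detection at thresholds: the contig is informative, i.e.
  called present (RPKM > ``present_min``) in at least one genotype and
  absent (RPKM < ``absent_max``) in at least one.
* **filter 2** — segregating detection: absent in at least
  ``min_absent_genotypes`` genotypes (the non-producer parent required
  among them by default) and present in at least
  ``min_present_genotypes`` genotypes.  Ambiguous calls count as neither.
* **filter 3** — dual-assembly confirmation: the contig has a qualifying
  k-mer containment match in the second, independently built assembly.
* **strict co-segregation** — present in every producer-bulk genotype
  and absent in the non-producer parent.

A contig is a candidate iff every enabled check passes.  Every contig
keeps its per-filter flags, so exclusions are fully attributable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import pandas as pd

from .assembly_match import MatchTable
from .phenotyping import ProducerCall
from .quantification import (
    ABSENT_MAX_DEFAULT,
    PRESENT_MIN_DEFAULT,
    PresenceMatrix,
    RPKMMatrix,
    classify_presence,
)


@dataclass
class FilterParams:
    present_min: float = PRESENT_MIN_DEFAULT
    absent_max: float = ABSENT_MAX_DEFAULT
    min_absent_genotypes: int = 3
    require_nonproducer_parent_absent: bool = True
    min_present_genotypes: int = 6
    require_dual_assembly: bool = True
    strict_coseg: bool = True

    def __post_init__(self):
        if self.min_absent_genotypes < 1 or self.min_present_genotypes < 1:
            raise ValueError("min genotype counts must be >= 1")
        if self.absent_max > self.present_min:
            raise ValueError("absent_max must be <= present_min")

    @classmethod
    def from_json(cls, path) -> "FilterParams":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Bulks:
    """Disjoint producer / non-producer genotype sets, with the parents
    identified when known (the non-producer parent anchors filter 2 and
    the strict check; the producer parent orders the report)."""

    producer_set: set[str]
    nonproducer_set: set[str]
    producer_parent: str | None = None
    nonproducer_parent: str | None = None

    def __post_init__(self):
        if self.producer_set & self.nonproducer_set:
            raise ValueError("bulks overlap")
        if self.producer_parent is not None and self.producer_parent not in self.producer_set:
            raise ValueError("producer parent not in producer set")
        if self.nonproducer_parent is not None and self.nonproducer_parent not in self.nonproducer_set:
            raise ValueError("non-producer parent not in non-producer set")

    @property
    def all_genotypes(self) -> set[str]:
        return self.producer_set | self.nonproducer_set


@dataclass
class CandidateReport:
    """Per-contig filter provenance plus the final candidate list.

    ``rows`` holds one record per input contig: its RPKM values
    (``rpkm_<genotype>``), trinary calls (``call_<genotype>``), the four
    pass flags and ``is_candidate``.  Rows are ordered by descending RPKM
    in the producer parent (mean over the producer bulk when no parent is
    identified), ties broken by contig id.
    """

    rows: pd.DataFrame
    params: FilterParams
    bulks: Bulks

    @property
    def candidate_ids(self) -> list[str]:
        return list(self.rows.loc[self.rows["is_candidate"], "contig_id"])

    def summary(self) -> dict:
        r = self.rows
        return {
            "n_contigs": int(len(r)),
            "n_pass_filter1": int(r["passed_filter1"].sum()),
            "n_pass_filter2": int(r["passed_filter2"].sum()),
            "n_pass_filter3": int(r["passed_filter3"].sum()),
            "n_pass_strict": int(r["passed_strict"].sum()),
            "n_candidates": int(r["is_candidate"].sum()),
            "candidates": self.candidate_ids,
            "producer_set": sorted(self.bulks.producer_set),
            "nonproducer_set": sorted(self.bulks.nonproducer_set),
            "params": self.params.to_dict(),
        }

    def to_tsv(self, path, header_comments=()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.rows.to_csv(fh, sep="\t", index=False)


def assign_bulks(
    calls: list[ProducerCall],
    genotype_ids: list[str],
    producer_parent: str | None = None,
    nonproducer_parent: str | None = None,
) -> Bulks:
    """Partition the RNA-seq genotypes into producer and non-producer
    bulks from their phenotype calls.

    Raises
    ------
    ValueError
        If any genotype in ``genotype_ids`` lacks a producer call, or a
        named parent falls in the wrong bulk.
    """
    by_id = {c.genotype_id: c for c in calls}
    missing = [g for g in genotype_ids if g not in by_id]
    if missing:
        raise ValueError(f"no producer call for genotype(s): {missing}")
    producers = {g for g in genotype_ids if by_id[g].is_producer}
    nonproducers = set(genotype_ids) - producers
    if not nonproducers:
        warnings.warn("all genotypes are producers; downstream filters are degenerate", stacklevel=2)
    if not producers:
        warnings.warn("no producer genotypes; downstream filters are degenerate", stacklevel=2)
    return Bulks(
        producer_set=producers,
        nonproducer_set=nonproducers,
        producer_parent=producer_parent,
        nonproducer_parent=nonproducer_parent,
    )


def run_candidate_filter(
    rpkm: RPKMMatrix,
    bulks: Bulks,
    match_table: MatchTable | None,
    params: FilterParams | None = None,
) -> CandidateReport:
    """Apply the three-filter cascade plus the strict producer-specificity
    check; see the module docstring for the filter definitions."""
    params = params or FilterParams()
    genotypes = list(rpkm.genotype_ids)
    unknown = bulks.all_genotypes - set(genotypes)
    if unknown:
        raise ValueError(f"bulk genotypes missing from RPKM matrix: {sorted(unknown)}")
    if set(genotypes) - bulks.all_genotypes:
        raise ValueError(
            f"RPKM genotypes missing a bulk assignment: {sorted(set(genotypes) - bulks.all_genotypes)}"
        )
    n_genotypes = len(genotypes)
    if params.min_absent_genotypes > n_genotypes or params.min_present_genotypes > n_genotypes:
        raise ValueError("min genotype counts exceed the number of genotypes")
    if params.require_dual_assembly and match_table is None:
        raise ValueError("require_dual_assembly is set but no match table was given")

    presence: PresenceMatrix = classify_presence(rpkm, params.present_min, params.absent_max)
    present = presence.present()
    absent = presence.absent()

    n_present = present.sum(axis=1)
    n_absent = absent.sum(axis=1)

    f1 = (n_present >= 1) & (n_absent >= 1)

    f2 = (n_absent >= params.min_absent_genotypes) & (n_present >= params.min_present_genotypes)
    if params.require_nonproducer_parent_absent:
        if bulks.nonproducer_parent is None:
            raise ValueError("require_nonproducer_parent_absent is set but no non-producer parent is identified")
        f2 &= absent[bulks.nonproducer_parent]

    if params.require_dual_assembly:
        matched = match_table.matched_a_ids
        f3 = pd.Series([cid in matched for cid in rpkm.contig_ids], index=present.index)
    else:
        f3 = pd.Series(True, index=present.index)

    # strict co-segregation anchors on the non-producer parent when known
    producer_cols = sorted(bulks.producer_set)
    strict = present[producer_cols].all(axis=1) if producer_cols else pd.Series(False, index=present.index)
    if bulks.nonproducer_parent is not None:
        strict &= absent[bulks.nonproducer_parent]

    enabled = [f1, f2, f3] if not params.strict_coseg else [f1, f2, f3, strict]
    is_candidate = enabled[0].copy()
    for flag in enabled[1:]:
        is_candidate &= flag

    # report ordering: producer-parent RPKM descending, ties by contig id
    if bulks.producer_parent is not None:
        order_key = rpkm.values[bulks.producer_parent]
    elif producer_cols:
        order_key = rpkm.values[producer_cols].mean(axis=1)
    else:
        order_key = pd.Series(0.0, index=rpkm.values.index)

    rows = pd.DataFrame({"contig_id": rpkm.contig_ids}, index=rpkm.values.index)
    for g in genotypes:
        rows[f"rpkm_{g}"] = rpkm.values[g]
    for g in genotypes:
        rows[f"call_{g}"] = presence.calls[g]
    rows["passed_filter1"] = f1
    rows["passed_filter2"] = f2
    rows["passed_filter3"] = f3
    rows["passed_strict"] = strict
    rows["is_candidate"] = is_candidate
    rows["_key"] = order_key
    rows.index.name = None
    rows = (
        rows.sort_values(["_key", "contig_id"], ascending=[False, True], kind="stable")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return CandidateReport(rows=rows, params=params, bulks=bulks)
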