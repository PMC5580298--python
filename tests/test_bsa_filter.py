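"""The candidate filter cascade and bulk assignment."""

import numpy as np
import pandas as pd
import pytest

from bsaseq import FilterParams, analyze_study, assign_bulks, run_candidate_filter
from bsaseq.bsa_filter import Bulks
from bsaseq.fixtures import TABLE1_NONPRODUCER_PARENT, TABLE1_PRODUCERS, load_table1
from bsaseq.phenotyping import ProducerCall
from bsaseq.quantification import RPKMMatrix


def table1_bulks():
    return Bulks(
        producer_set=set(TABLE1_PRODUCERS),
        nonproducer_set={TABLE1_NONPRODUCER_PARENT},
        producer_parent="Mara",
        nonproducer_parent="Elyana",
    )


def table1_params(**kw):
    """Only four genotypes are available in the worked example, so the
    count-based second filter and the dual-assembly filter are disabled."""
    base = dict(min_absent_genotypes=1, min_present_genotypes=1, require_dual_assembly=False)
    base.update(kw)
    return FilterParams(**base)


def _mk_calls(status: dict[str, bool]):
    return [ProducerCall(g, s, int(s), 3, 1.0 if s else 0.0) for g, s in status.items()]


def test_assign_bulks_partitions_sixteen_genotypes():
    gids = ["Mara", "Elyana", "P098", "P103"] + [f"P{i:03d}" for i in range(1, 13)]
    status = {g: g in ("Mara", "P098", "P103") for g in gids}
    bulks = assign_bulks(_mk_calls(status), gids, producer_parent="Mara", nonproducer_parent="Elyana")
    assert bulks.producer_set == {"Mara", "P098", "P103"}
    assert len(bulks.nonproducer_set) == 13


def test_assign_bulks_requires_calls_for_all():
    with pytest.raises(ValueError, match="no producer call"):
        assign_bulks(_mk_calls({"a": True}), ["a", "b"])


def test_assign_bulks_warns_when_degenerate():
    with pytest.warns(UserWarning, match="degenerate"):
        assign_bulks(_mk_calls({"a": True, "b": True}), ["a", "b"])


def test_table1_replay_keeps_all_five_candidates(table1):
    report = run_candidate_filter(table1, table1_bulks(), None, table1_params())
    assert len(report.candidate_ids) == 5
    assert set(report.candidate_ids) == set(table1.contig_ids)
    # report ordered by producer-parent abundance
    assert report.rows.contig_id.iloc[0] == "contig_1885"


def test_decoy_present_everywhere_is_excluded(table1):
    values = table1.values.copy()
    values.loc["decoy"] = 50.0
    lengths = pd.concat([table1.lengths_bp, pd.Series([1000], index=["decoy"])])
    rpkm = RPKMMatrix(values=values, lengths_bp=lengths)
    report = run_candidate_filter(rpkm, table1_bulks(), None, table1_params())
    assert "decoy" not in report.candidate_ids
    row = report.rows.set_index("contig_id").loc["decoy"]
    assert not row.passed_strict  # present in the non-producer parent


def test_unknown_genotypes_rejected(table1):
    bulks = Bulks(producer_set={"Mara", "ghost"}, nonproducer_set={"Elyana"})
    with pytest.raises(ValueError):
        run_candidate_filter(table1, bulks, None, table1_params())


def test_min_counts_exceeding_genotypes_rejected(table1):
    with pytest.raises(ValueError):
        run_candidate_filter(table1, table1_bulks(), None, table1_params(min_present_genotypes=10))


def test_dual_assembly_requires_match_table(table1):
    with pytest.raises(ValueError, match="match table"):
        run_candidate_filter(table1, table1_bulks(), None, table1_params(require_dual_assembly=True))


def test_filter_anti_monotonicity(small_study):
    """Any stricter parameterization yields a candidate subset of the
    looser run's candidates."""
    loose = analyze_study(small_study, FilterParams(min_absent_genotypes=1, min_present_genotypes=1))
    stricter_variants = [
        FilterParams(min_absent_genotypes=3, min_present_genotypes=1),
        FilterParams(min_absent_genotypes=1, min_present_genotypes=4),
        FilterParams(min_absent_genotypes=1, min_present_genotypes=1, present_min=60, absent_max=1),
    ]
    for params in stricter_variants:
        strict = analyze_study(small_study, params)
        assert set(strict.candidate_ids) <= set(loose.candidate_ids), params


def test_provenance_completeness(small_study):
    """Every excluded contig carries at least one failed-filter flag."""
    analysis = analyze_study(small_study)
    rows = analysis.report.rows
    excluded = rows[~rows.is_candidate]
    flags = excluded[["passed_filter1", "passed_filter2", "passed_filter3", "passed_strict"]]
    assert (~flags).any(axis=1).all()


def test_pipeline_recovers_planted_truth(small_study):
    analysis = analyze_study(small_study)
    assert sorted(analysis.candidate_ids) == sorted(small_study.truth["causal_contigs"]["A"])


def test_permuted_labels_on_signal_free_study_yield_nothing():
    from bsaseq import SimConfig, simulate_cross

    cfg = SimConfig(n_progeny=30, n_background_contigs=100, n_causal_contigs=0,
                    contig_length_range=(150, 400), n_rnaseq_progeny=8,
                    n_subset_producers=2, n_subset_low=2, seed=31)
    study = simulate_cross(cfg)
    assert analyze_study(study).candidate_ids == []
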