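"""The synthetic-study generator: segregation, counts, dual assemblies."""

import numpy as np
import pandas as pd
import pytest

from bsaseq import SimConfig, compute_rpkm, simulate_counts, simulate_cross
from bsaseq.assembly_match import ContigSet
from bsaseq.simdata import derive_second_assembly, random_dna, simulate_ct_table
from tests.test_assembly_match import substring_match_oracle


def _cheap(**kw):
    base = dict(n_background_contigs=10, n_causal_contigs=2, contig_length_range=(150, 300), n_progeny=30,
                n_rnaseq_progeny=8, n_subset_producers=2, n_subset_low=2, seed=5)
    base.update(kw)
    return SimConfig(**base)


@pytest.mark.parametrize(
    "model, expected",
    [("one_locus", 0.5), ("two_locus", 0.25)],
)
def test_true_producer_fraction_matches_model(model, expected):
    cfg = _cheap(genetic_model=model, n_progeny=10000, penetrance=1.0, seed=3)
    study = simulate_cross(cfg)
    progeny = [g for g in study.genotypes if g.role == "progeny"]
    frac = np.mean([study.truth["true_producers"][g.id] for g in progeny])
    se = np.sqrt(expected * (1 - expected) / len(progeny))
    assert abs(frac - expected) <= 3 * se


def test_zero_penetrance_means_no_detectable_phenotype():
    cfg = _cheap(penetrance=0.0, seed=9)
    study = simulate_cross(cfg)
    thr = cfg.ma_detection_threshold
    assert all(r.ma_norm_area <= thr for r in study.phenotypes)


def test_detection_fraction_converges_with_partial_penetrance():
    """Any-harvest producer fraction tends to model_fraction *
    (1 - (1 - penetrance)^n_harvests)."""
    pen, h = 0.6, 3
    cfg = _cheap(n_progeny=10000, penetrance=pen, n_harvests=h, seed=13)
    study = simulate_cross(cfg)
    thr = cfg.ma_detection_threshold
    detected = {r.genotype_id for r in study.phenotypes if r.ma_norm_area > thr}
    progeny = [g.id for g in study.genotypes if g.role == "progeny"]
    frac = np.mean([g in detected for g in progeny])
    expected = 0.5 * (1 - (1 - pen) ** h)
    se = np.sqrt(expected * (1 - expected) / len(progeny))
    # a handful of subset low-producers are forced sub-threshold
    assert abs(frac - expected) <= 3 * se + len(study.truth["low_producer_ids"]) / len(progeny)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(genetic_model="three_locus")
    with pytest.raises(ValueError):
        SimConfig(n_progeny=0)
    with pytest.raises(ValueError):
        SimConfig(mean_expression_present=8.0)  # must exceed presence threshold
    with pytest.raises(ValueError):
        SimConfig(penetrance=1.5)


def test_carrier_rpkm_recovers_target_mean():
    """Realized RPKM of causal contigs in carriers, averaged over ~200
    carrier draws, lands within 10% of the configured present mean
    (oracle: the RPKM formula applied to the simulated counts)."""
    values = []
    seed = 0
    while len(values) < 200:
        cfg = _cheap(seed=seed, n_causal_contigs=3)
        study = simulate_cross(cfg)
        rpkm = compute_rpkm(study.expression["A"])
        carriers = [g for g in study.subset_ids if study.truth["carriers"][g]]
        vals = rpkm.values.loc[study.truth["causal_contigs"]["A"], carriers]
        values.extend(np.asarray(vals).ravel().tolist())
        seed += 1
    mean = float(np.mean(values[:200]))
    assert mean == pytest.approx(cfg.mean_expression_present, rel=0.10)


def test_zero_mean_zero_dispersion_counts_are_zero():
    cfg = _cheap(nb_dispersion=0.0, mean_expression_absent=0.0, seed=2)
    study = simulate_cross(cfg)
    counts = study.expression["A"].counts
    noncarriers = [g for g in study.subset_ids if not study.truth["carriers"][g]]
    causal = study.truth["causal_contigs"]["A"]
    assert (counts.loc[causal, noncarriers].to_numpy() == 0).all()


def test_counts_deterministic_given_seed():
    cfg = _cheap(seed=21)
    s1, s2 = simulate_cross(cfg), simulate_cross(cfg)
    pd.testing.assert_frame_equal(s1.expression["A"].counts, s2.expression["A"].counts)
    pd.testing.assert_frame_equal(s1.expression["B"].counts, s2.expression["B"].counts)
    again = simulate_counts(s1, cfg, "A")
    pd.testing.assert_frame_equal(again.counts, s1.expression["A"].counts)


def test_study_outputs_byte_identical(tmp_path):
    cfg = _cheap(seed=4)
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    simulate_cross(cfg).write(d1)
    simulate_cross(cfg).write(d2)
    for f in sorted(d1.iterdir()):
        assert (d2 / f.name).read_bytes() == f.read_bytes(), f.name


# ---------------------------------------------------------------------------
# second-assembly derivation


def test_full_overlap_copy_mode_renames_assembly(rng):
    cfg = _cheap(assembly_overlap_fraction=1.0)
    a = ContigSet("A", [(f"a{i}", random_dna(rng, 200)) for i in range(8)])
    b, mapping = derive_second_assembly(a, cfg, mode_probs=(1.0, 0.0, 0.0))
    assert len(b.contigs) == len(a.contigs)
    by_id = dict(b.contigs)
    for (aid, seq) in a.contigs:
        (bid,) = mapping[aid]
        assert by_id[bid] == seq


def test_zero_overlap_shares_nothing(rng):
    cfg = _cheap(assembly_overlap_fraction=0.0, contig_length_range=(150, 200))
    a = ContigSet("A", [(f"a{i}", random_dna(rng, 180)) for i in range(5)])
    b, mapping = derive_second_assembly(a, cfg)
    assert mapping == {}
    for _, bseq in b.contigs:
        for _, aseq in a.contigs:
            assert not substring_match_oracle(aseq, bseq)


def test_split_conserves_sequence(rng):
    cfg = _cheap(assembly_overlap_fraction=1.0)
    a = ContigSet("A", [("a1", random_dna(rng, 1000))])
    b, mapping = derive_second_assembly(a, cfg, mode_probs=(0.0, 0.0, 1.0))
    b1, b2 = mapping["a1"]
    by_id = dict(b.contigs)
    assert by_id[b1] + by_id[b2] == dict(a.contigs)["a1"]


def test_short_contig_copied_untruncated(rng):
    cfg = _cheap(assembly_overlap_fraction=1.0, contig_length_range=(50, 80))
    a = ContigSet("A", [("a1", random_dna(rng, 60))])
    b, mapping = derive_second_assembly(a, cfg, mode_probs=(0.0, 1.0, 0.0))
    (bid,) = mapping["a1"]
    assert dict(b.contigs)[bid] == dict(a.contigs)["a1"]


def test_overlap_fraction_governs_matched_share():
    """The share of A contigs with a B counterpart tracks the configured
    overlap fraction (simulation truth as the oracle)."""
    f = 0.6
    cfg = _cheap(assembly_overlap_fraction=f, n_background_contigs=100, n_causal_contigs=0, seed=17)
    study = simulate_cross(cfg)
    mapped = len(study.truth["a_to_b"])
    total = len(study.assemblies["A"].contigs)
    assert mapped / total == pytest.approx(f, abs=0.01)


def test_causal_contigs_always_present_in_both_assemblies():
    cfg = _cheap(assembly_overlap_fraction=0.5, seed=23)
    study = simulate_cross(cfg)
    for cid in study.truth["causal_contigs"]["A"]:
        assert study.truth["a_to_b"].get(cid), cid


def test_ct_table_shape_and_contrast():
    cfg = _cheap(seed=29)
    study = simulate_cross(cfg)
    df = simulate_ct_table(study, cfg)
    assert set(df.columns) == {"sample_id", "target_ct", "reference_ct", "replicate"}
    carriers = [g for g in study.subset_ids if study.truth["carriers"][g]]
    noncar = [g for g in study.subset_ids if not study.truth["carriers"][g]]
    assert df[df.sample_id.isin(carriers)].target_ct.mean() < df[df.sample_id.isin(noncar)].target_ct.mean()
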