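"""Synthetic study generator for the bulked-segregant transcriptome pipeline.

Emulates an F1 strawberry cross between a methyl-anthranilate (MA)
producing parent and a non-producer, segregating a dominant producer
allele under a one-locus (50% expected producers) or two-locus (25%)
model with per-harvest penetrance.  The generator produces every input
the analysis consumes:

* progeny genotypes with per-locus dominant-allele carriage,
* multi-harvest normalized volatile phenotypes,
* an RNA-seq subset (both parents + ``n_rnaseq_progeny`` progeny,
  default 16 genotypes) with negative-binomial read counts over planted
  causal contigs and homogeneous background contigs,
* two partially overlapping de novo assemblies (copy / truncation /
  split derivation of the second from the first),
* a DNA marker band table linked to the causal locus,
* ground truth (planted contigs, carriage, assembly mapping).

The RNA-seq subset mirrors the study design being emulated: a few strong
producers (the producer parent plus two progeny), several progeny that
carry — and express — the causal transcript but show sub-threshold
volatile levels (the transcript is necessary but not sufficient for the
phenotype), and transcript-negative progeny.  All randomness flows
through substreams of a single seed, so identical config implies
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .assembly_match import ContigSet
from .phenotyping import PhenotypeRecord, records_to_tsv
from .quantification import ExpressionMatrix

PRODUCER_PARENT_ID = "Mara_des_Bois"
NONPRODUCER_PARENT_ID = "Elyana"
TRANSCRIPT_LOCUS = "locus_1"

#: minimum bases a truncated/split fragment must keep (2x the default
#: matching k so fragments stay matchable)
MIN_FRAGMENT_BP = 42

# normalized-peak-area generative constants (dimensionless, relative to
# the internal standard): detected producers draw lognormal signal,
# non-producers draw sub-threshold noise
_SIGNAL_LOG_MU = 0.0
_SIGNAL_LOG_SIGMA = 0.5
_NOISE_FRACTION = 0.2      # noise ceiling as a fraction of the threshold
_LOW_FRACTION = (0.1, 0.8)  # low-producer band as fractions of the threshold

_STREAMS = {name: i for i, name in enumerate(
    ["alleles", "phenotype", "subset", "sequences", "assembly_b", "library", "counts_A", "counts_B", "marker", "ct"]
)}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimConfig:
    """Study-design constants for the simulated cross.

    Defaults follow the emulated study: ~114 progeny phenotyped over 3
    harvests, an RNA-seq subset of 14 progeny plus both parents, 5
    causal transcripts against a 2000-contig background, and RPKM-scale
    expression targets that make planted signals cleanly classifiable
    (absent mean < 5 < 10 < present mean).
    """

    genetic_model: str = "one_locus"
    n_progeny: int = 114
    n_harvests: int = 3
    penetrance: float = 1.0
    n_causal_contigs: int = 5
    n_background_contigs: int = 2000
    mean_expression_present: float = 100.0
    mean_expression_absent: float = 0.5
    mean_expression_background: float = 250.0
    nb_dispersion: float = 0.1
    library_size_log_mean: float = float(np.log(5e6))
    library_size_log_sd: float = 0.2
    contig_length_range: tuple[int, int] = (300, 3000)
    assembly_overlap_fraction: float = 0.9
    ma_detection_threshold: float = 0.05
    n_rnaseq_progeny: int = 14
    n_subset_producers: int = 2
    n_subset_low: int = 5
    marker_discordance_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.genetic_model not in ("one_locus", "two_locus"):
            raise ValueError(f"unknown genetic_model {self.genetic_model!r}")
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if self.n_harvests < 1:
            raise ValueError("n_harvests must be >= 1")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        if self.n_causal_contigs < 0 or self.n_background_contigs < 0:
            raise ValueError("contig counts must be non-negative")
        if not (self.mean_expression_absent < 5.0 < 10.0 < self.mean_expression_present):
            raise ValueError("need mean_expression_absent < 5 < 10 < mean_expression_present (RPKM scale)")
        lo, hi = self.contig_length_range
        if lo < MIN_FRAGMENT_BP or hi < lo:
            raise ValueError(f"contig lengths must be >= {MIN_FRAGMENT_BP} bp and the range ordered")
        if not 0.0 <= self.assembly_overlap_fraction <= 1.0:
            raise ValueError("assembly_overlap_fraction must be in [0, 1]")
        if self.ma_detection_threshold < 0:
            raise ValueError("ma_detection_threshold must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.n_subset_producers + self.n_subset_low > self.n_rnaseq_progeny:
            raise ValueError("subset class sizes exceed n_rnaseq_progeny")
        if self.n_rnaseq_progeny > self.n_progeny:
            raise ValueError("n_rnaseq_progeny exceeds n_progeny")
        if not 0.0 <= self.marker_discordance_rate <= 1.0:
            raise ValueError("marker_discordance_rate must be in [0, 1]")

    @property
    def loci(self) -> list[str]:
        n = 1 if self.genetic_model == "one_locus" else 2
        return [f"locus_{i + 1}" for i in range(n)]

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if "contig_length_range" in data:
            data["contig_length_range"] = tuple(data["contig_length_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contig_length_range"] = list(self.contig_length_range)
        return d


@dataclass
class Genotype:
    id: str
    role: str  # producer_parent | nonproducer_parent | progeny
    alleles: dict[str, int]  # locus -> dominant-allele count in {0, 1}

    def carries(self, locus: str) -> bool:
        return self.alleles.get(locus, 0) > 0

    def carries_all(self, loci) -> bool:
        return all(self.carries(l) for l in loci)


@dataclass
class SimulatedStudy:
    config: SimConfig
    genotypes: list[Genotype]
    phenotypes: list[PhenotypeRecord]
    subset_ids: list[str]
    assemblies: dict[str, ContigSet]
    expression: dict[str, ExpressionMatrix]
    marker_table: pd.DataFrame
    library_sizes: pd.Series
    truth: dict

    def genotype(self, gid: str) -> Genotype:
        return next(g for g in self.genotypes if g.id == gid)

    def subset_phenotypes(self) -> list[PhenotypeRecord]:
        wanted = set(self.subset_ids)
        return [r for r in self.phenotypes if r.genotype_id in wanted]

    def write(self, outdir, header_comments=()) -> None:
        """Write all study files: FASTA per assembly, counts TSVs,
        phenotype TSV, marker TSV and the truth JSON."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for label, contigs in self.assemblies.items():
            contigs.to_fasta(out / f"assembly_{label}.fasta")
        for label, em in self.expression.items():
            em.to_tsv(out / f"counts_{label}.tsv", header_comments)
        records_to_tsv(self.phenotypes, out / "phenotypes.tsv", header_comments)
        with open(out / "marker.tsv", "w", encoding="utf-8") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.marker_table.to_csv(fh, sep="\t", index=False)
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def random_dna(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length)
    return np.frombuffer(np.array([65, 67, 71, 84], dtype=np.uint8)[codes].tobytes(), dtype="S1").tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# cross + phenotypes


def _simulate_genotypes(config: SimConfig) -> list[Genotype]:
    loci = config.loci
    rng = _rng(config.seed, "alleles")
    parents = [
        Genotype(PRODUCER_PARENT_ID, "producer_parent", {l: 1 for l in loci}),
        Genotype(NONPRODUCER_PARENT_ID, "nonproducer_parent", {l: 0 for l in loci}),
    ]
    width = max(3, len(str(config.n_progeny)))
    progeny = []
    carriage = rng.integers(0, 2, size=(config.n_progeny, len(loci)))
    for i in range(config.n_progeny):
        alleles = {l: int(carriage[i, j]) for j, l in enumerate(loci)}
        progeny.append(Genotype(f"P{i + 1:0{width}d}", "progeny", alleles))
    return parents + progeny


def _simulate_phenotypes(config: SimConfig, genotypes: list[Genotype]) -> list[PhenotypeRecord]:
    rng = _rng(config.seed, "phenotype")
    loci = config.loci
    thr = config.ma_detection_threshold
    records = []
    for g in genotypes:
        is_producer = g.carries_all(loci)
        for h in range(1, config.n_harvests + 1):
            if is_producer and rng.random() < config.penetrance:
                area = float(rng.lognormal(_SIGNAL_LOG_MU, _SIGNAL_LOG_SIGMA))
            else:
                area = float(rng.uniform(0.0, _NOISE_FRACTION * thr))
            records.append(PhenotypeRecord(genotype_id=g.id, harvest_id=f"H{h}", ma_norm_area=area))
    return records


def _detected_ids(config: SimConfig, records: list[PhenotypeRecord]) -> set[str]:
    thr = max(config.ma_detection_threshold, 1e-12)
    return {r.genotype_id for r in records if r.ma_norm_area > thr}


def _select_subset(
    config: SimConfig, genotypes: list[Genotype], records: list[PhenotypeRecord]
) -> tuple[list[str], list[str], list[str]]:
    """Choose the RNA-seq progeny: strong producers, transcript-carrying
    low producers (phenotype forced sub-threshold if needed), negatives.

    Returns (subset_progeny_ids, strong_ids, low_ids).  Low producers
    that were phenotypic producers in the raw draw get their phenotype
    records overwritten in place with sub-threshold values.
    """
    rng = _rng(config.seed, "subset")
    loci = config.loci
    progeny = [g for g in genotypes if g.role == "progeny"]
    detected = _detected_ids(config, records)
    producers = [g.id for g in progeny if g.carries_all(loci) and g.id in detected]
    carriers = [g.id for g in progeny if g.carries(TRANSCRIPT_LOCUS)]

    strong = producers[: config.n_subset_producers]
    low_natural = [gid for gid in carriers if gid not in detected]
    low = low_natural[: config.n_subset_low]
    forced = []
    if len(low) < config.n_subset_low:
        pool = [gid for gid in carriers if gid not in strong and gid not in low]
        forced = pool[: config.n_subset_low - len(low)]
        low = low + forced
    negatives = [g.id for g in progeny if not g.carries(TRANSCRIPT_LOCUS)]
    n_neg = config.n_rnaseq_progeny - len(strong) - len(low)
    chosen_neg = list(negatives[:n_neg])
    subset = strong + low + chosen_neg
    if len(subset) < config.n_rnaseq_progeny:  # top up from whatever remains
        rest = [g.id for g in progeny if g.id not in subset]
        subset += rest[: config.n_rnaseq_progeny - len(subset)]
    # force the phenotype of converted low producers below threshold
    if forced:
        thr = config.ma_detection_threshold
        forced_set = set(forced)
        for r in records:
            if r.genotype_id in forced_set:
                r.ma_norm_area = float(rng.uniform(*(_LOW_FRACTION)) * thr)
    return subset, strong, low


# ---------------------------------------------------------------------------
# sequences and assemblies


def _simulate_assembly_a(config: SimConfig) -> tuple[ContigSet, list[str]]:
    rng = _rng(config.seed, "sequences")
    n_total = config.n_causal_contigs + config.n_background_contigs
    lo, hi = config.contig_length_range
    lengths = rng.integers(lo, hi + 1, size=n_total)
    width = max(6, len(str(n_total)))
    ids = [f"tA_{i + 1:0{width}d}" for i in range(n_total)]
    contigs = [(ids[i], random_dna(rng, int(lengths[i]))) for i in range(n_total)]
    causal = sorted(rng.choice(n_total, size=config.n_causal_contigs, replace=False).tolist())
    causal_ids = [ids[i] for i in causal]
    return ContigSet("A", contigs), causal_ids


def derive_second_assembly(
    contigs_a: ContigSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    priority_ids=(),
    mode_probs: tuple[float, float, float] = (0.6, 0.25, 0.15),
) -> tuple[ContigSet, dict[str, list[str]]]:
    """Derive a second, partially overlapping assembly from the first.

    A fraction ``assembly_overlap_fraction`` of A's contigs is carried
    into B under new identifiers, each as an exact copy, a truncation
    keeping at least half the length, or a two-way split (probabilities
    ``mode_probs``).  Contigs named in ``priority_ids`` (the planted
    causal transcripts, when called from the study generator) are always
    carried over; the remaining B contigs are novel random sequence so B
    reaches A's size.  Fragments shorter than ``MIN_FRAGMENT_BP`` are
    not produced: such contigs are copied untruncated.  Returns the new
    ContigSet and the A-id -> B-ids mapping.
    """
    if not contigs_a.contigs:
        raise ValueError("contigs_a is empty")
    if rng is None:
        rng = _rng(config.seed, "assembly_b")
    by_id = dict(contigs_a.contigs)
    all_ids = contigs_a.ids
    n_keep = int(round(config.assembly_overlap_fraction * len(all_ids)))
    keep = set(priority_ids)
    remaining = [cid for cid in all_ids if cid not in keep]
    n_more = max(0, n_keep - len(keep))
    if n_more > 0 and remaining:
        extra = rng.choice(len(remaining), size=min(n_more, len(remaining)), replace=False)
        keep.update(remaining[i] for i in sorted(extra.tolist()))
    kept_sorted = [cid for cid in all_ids if cid in keep]

    b_contigs: list[tuple[str, str]] = []
    mapping: dict[str, list[str]] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"tB_{counter:06d}"

    p = np.asarray(mode_probs, dtype=float)
    p = p / p.sum()
    for cid in kept_sorted:
        seq = by_id[cid]
        L = len(seq)
        mode = ["copy", "truncate", "split"][int(rng.choice(3, p=p))]
        if mode == "truncate" and L >= 2 * MIN_FRAGMENT_BP:
            frac = rng.uniform(0.5, 1.0)
            keep_len = max(MIN_FRAGMENT_BP, int(round(frac * L)))
            sub = seq[:keep_len] if rng.random() < 0.5 else seq[L - keep_len:]
            bid = new_id()
            b_contigs.append((bid, sub))
            mapping[cid] = [bid]
        elif mode == "split" and L >= 2 * MIN_FRAGMENT_BP:
            point = int(round(L * rng.uniform(0.35, 0.65)))
            point = min(max(point, MIN_FRAGMENT_BP), L - MIN_FRAGMENT_BP)
            b1, b2 = new_id(), new_id()
            b_contigs.append((b1, seq[:point]))
            b_contigs.append((b2, seq[point:]))
            mapping[cid] = [b1, b2]
        else:
            bid = new_id()
            b_contigs.append((bid, seq))
            mapping[cid] = [bid]

    lo, hi = config.contig_length_range
    n_novel = max(0, len(all_ids) - len(kept_sorted))
    for _ in range(n_novel):
        b_contigs.append((new_id(), random_dna(rng, int(rng.integers(lo, hi + 1)))))
    return ContigSet("B", b_contigs), mapping


# ---------------------------------------------------------------------------
# counts


def simulate_counts(study: "SimulatedStudy", config: SimConfig, assembly: str = "A") -> ExpressionMatrix:
    """Draw negative-binomial read counts for one assembly's contigs over
    the RNA-seq subset genotypes.

    Target RPKM per cell: causal contigs get ``mean_expression_present``
    in carriers of the transcript locus and ``mean_expression_absent``
    otherwise; background contigs share ``mean_expression_background``
    in every genotype.  Targets are back-converted to expected counts
    through contig length and the genotype's library size
    (mu = rpkm * N * L / 1e9) and drawn as NB(mean mu, variance
    mu + alpha * mu^2); alpha = 0 degenerates to Poisson.  Deterministic
    given the study config and assembly label.
    """
    contigs = study.assemblies[assembly]
    rng = _rng(config.seed, f"counts_{assembly}")
    gids = list(study.subset_ids)
    carriers = np.array([study.truth["carriers"][g] for g in gids], dtype=bool)
    lib = study.library_sizes.reindex(gids).to_numpy(dtype=float)
    causal = set(study.truth["causal_contigs"].get(assembly, []))

    ids = contigs.ids
    lengths = np.array([len(seq) for _, seq in contigs.contigs], dtype=float)
    n_c, n_g = len(ids), len(gids)
    target = np.full((n_c, n_g), config.mean_expression_background, dtype=float)
    causal_rows = np.array([cid in causal for cid in ids], dtype=bool)
    if causal_rows.any():
        row = np.where(carriers, config.mean_expression_present, config.mean_expression_absent)
        target[causal_rows, :] = row[None, :]

    mu = target * lib[None, :] * lengths[:, None] / 1e9
    alpha = config.nb_dispersion
    if alpha > 0:
        r = 1.0 / alpha
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts.astype(np.int64), index=pd.Index(ids, name="contig_id"), columns=gids)
    lengths_s = pd.Series(lengths.astype(int), index=df.index, name="length_bp")
    lib_s = pd.Series(lib, index=pd.Index(gids), name="library_size")
    return ExpressionMatrix(counts=df, lengths_bp=lengths_s, library_sizes=lib_s)


# ---------------------------------------------------------------------------
# top level


def simulate_cross(config: SimConfig) -> SimulatedStudy:
    """Simulate the complete study: cross, phenotypes, RNA-seq subset,
    assemblies, counts, marker table and ground truth.

    Progeny draw a dominant allele independently per locus with
    probability 1/2 from the heterozygous producer parent; a genotype is
    a true producer iff it carries a dominant allele at every model
    locus, and shows a detectable phenotype in a harvest with probability
    ``penetrance`` (non-carriers only draw sub-threshold noise).
    """
    genotypes = _simulate_genotypes(config)
    phenotypes = _simulate_phenotypes(config, genotypes)
    subset_progeny, strong_ids, low_ids = _select_subset(config, genotypes, phenotypes)

    assembly_a, causal_a = _simulate_assembly_a(config)
    assembly_b, mapping = derive_second_assembly(assembly_a, config, priority_ids=causal_a)
    causal_b = sorted(bid for cid in causal_a for bid in mapping.get(cid, []))

    subset_all = [PRODUCER_PARENT_ID, NONPRODUCER_PARENT_ID] + subset_progeny
    lib_rng = _rng(config.seed, "library")
    lib = np.round(lib_rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, size=len(subset_all)))
    library_sizes = pd.Series(lib, index=pd.Index(subset_all), name="library_size")

    by_id = {g.id: g for g in genotypes}
    carriers = {gid: int(by_id[gid].carries(TRANSCRIPT_LOCUS)) for gid in subset_all}
    producers = {g.id: bool(g.carries_all(config.loci)) for g in genotypes}

    truth = {
        "causal_contigs": {"A": causal_a, "B": causal_b},
        "a_to_b": mapping,
        "carriers": carriers,
        "true_producers": producers,
        "subset_ids": subset_all,
        "strong_producer_ids": [PRODUCER_PARENT_ID] + strong_ids,
        "low_producer_ids": low_ids,
    }

    marker_rng = _rng(config.seed, "marker")
    band = []
    for gid in subset_all:
        state = carriers[gid]
        if marker_rng.random() < config.marker_discordance_rate:
            state = 1 - state
        band.append(state)
    marker_table = pd.DataFrame({"genotype_id": subset_all, "band_1500_present": band})

    study = SimulatedStudy(
        config=config,
        genotypes=genotypes,
        phenotypes=phenotypes,
        subset_ids=subset_all,
        assemblies={"A": assembly_a, "B": assembly_b},
        expression={},
        marker_table=marker_table,
        library_sizes=library_sizes,
        truth=truth,
    )
    study.expression["A"] = simulate_counts(study, config, "A")
    study.expression["B"] = simulate_counts(study, config, "B")
    return study


def simulate_ct_table(study: SimulatedStudy, config: SimConfig, n_replicates: int = 3) -> pd.DataFrame:
    """Synthetic qPCR Ct table for the causal transcript over the RNA-seq
    subset: carriers amplify early (~Ct 22), non-carriers late (~Ct 34),
    the constitutive reference sits near Ct 20 in every sample; Gaussian
    technical noise per replicate."""
    rng = _rng(config.seed, "ct")
    rows = []
    for gid in study.subset_ids:
        base = 22.0 if study.truth["carriers"][gid] else 34.0
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": gid,
                    "target_ct": float(base + rng.normal(0.0, 0.15)),
                    "reference_ct": float(20.0 + rng.normal(0.0, 0.1)),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
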