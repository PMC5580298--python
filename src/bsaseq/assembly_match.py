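"""Cross-assembly contig matching by canonical k-mer containment.

Two de novo transcriptome assemblies of the same material rarely agree
contig-for-contig: one assembler's transcript may appear in the other
assembly as an identical copy, a truncation, or split into pieces.  To
decide which contigs are represented in *both* assemblies we compare
contigs by their sets of canonical k-mers (the lexicographic minimum of a
k-mer and its reverse complement, since assembled transcripts have
unknown strand) and score containment,

    containment(x -> y) = |kmers(x) & kmers(y)| / |kmers(x)|,

which, unlike Jaccard similarity, stays 1.0 when y is a fragment of x.
A pair is a match when containment in either direction reaches
``min_containment``.  K-mers containing non-ACGT characters are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_K = 21
DEFAULT_MIN_CONTAINMENT = 0.5

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


@dataclass
class ContigSet:
    """A labelled set of assembled contig sequences (uppercase DNA)."""

    assembly_label: str
    contigs: list[tuple[str, str]]  # (id, sequence)

    def __post_init__(self):
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate contig ids in assembly {self.assembly_label!r}")
        for cid, seq in self.contigs:
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r}")

    @property
    def ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    @classmethod
    def from_fasta(cls, path, assembly_label: str | None = None) -> "ContigSet":
        from Bio import SeqIO

        contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(assembly_label=assembly_label or str(path), contigs=contigs)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in self.contigs]
        seqio_write(records, str(path), "fasta")  # Biopython wraps at 60 columns

    def subset(self, ids) -> "ContigSet":
        wanted = set(ids)
        return ContigSet(self.assembly_label, [(c, s) for c, s in self.contigs if c in wanted])


_POW_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _powers(k: int) -> tuple[np.ndarray, np.ndarray]:
    if k not in _POW_CACHE:
        asc = 4 ** np.arange(k, dtype=np.int64)
        _POW_CACHE[k] = (asc[::-1].copy(), asc)
    return _POW_CACHE[k]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Distinct canonical k-mers of ``seq`` as sorted int64 codes.

    Each k-mer is packed 2 bits/base; the canonical form is the numeric
    minimum of the forward k-mer and its reverse complement (the latter
    computed as ``(4^k - 1) - ascending-power encoding``, since
    complementing maps base code c to 3 - c).  Windows containing a
    non-ACGT character are dropped.
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(codes, k)
    if (codes >= 4).any():
        valid = ~(win >= 4).any(axis=1)
        if not valid.any():
            return np.empty(0, dtype=np.int64)
        win = win[valid]
    win = win.astype(np.int64)
    pow_desc, pow_asc = _powers(k)
    fwd = win @ pow_desc
    rev = (4**k - 1) - (win @ pow_asc)
    return np.unique(np.minimum(fwd, rev))


def n_kmer_positions(seq: str, k: int) -> int:
    """Number of indexable k-mer windows (``L - k + 1`` for clean ACGT)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return 0
    win = sliding_window_view(codes, k)
    return int((~(win >= 4).any(axis=1)).sum())


@dataclass
class KmerIndex:
    """Inverted canonical k-mer index over one contig set.

    ``sorted_kmers`` holds the concatenated distinct k-mers of every
    indexed contig, sorted, with ``owners`` giving the contig index of
    each entry; queries use binary search.  Contigs shorter than k (or
    with no clean window) are recorded as unindexable.
    """

    k: int
    contig_ids: list[str]
    set_sizes: np.ndarray          # distinct-kmer count per contig
    sorted_kmers: np.ndarray
    owners: np.ndarray
    unindexable: list[str] = field(default_factory=list)

    def kmers_of(self, contig_idx: int) -> np.ndarray:
        return np.sort(self.sorted_kmers[self.owners == contig_idx])

    def shared_counts(self, query_kmers: np.ndarray) -> np.ndarray:
        """Distinct shared-kmer count between the query set and every
        indexed contig."""
        counts = np.zeros(len(self.contig_ids), dtype=np.int64)
        if query_kmers.size == 0 or self.sorted_kmers.size == 0:
            return counts
        lo = np.searchsorted(self.sorted_kmers, query_kmers, side="left")
        hi = np.searchsorted(self.sorted_kmers, query_kmers, side="right")
        span = hi - lo
        hit = span > 0
        if not hit.any():
            return counts
        # expand [lo, hi) ranges into flat positions of the owner array
        reps = span[hit]
        starts = lo[hit]
        pos = np.repeat(starts, reps) + _ranges_offsets(reps)
        np.add.at(counts, self.owners[pos], 1)
        return counts


def _ranges_offsets(lengths: np.ndarray) -> np.ndarray:
    """[2,3] -> [0,1,0,1,2]; offsets within consecutive ranges."""
    total = int(lengths.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(lengths)[:-1]
    out[ends] = 1 - lengths[:-1]
    return np.cumsum(out)


def index_kmers(contigs: ContigSet, k: int = DEFAULT_K) -> KmerIndex:
    """Build the canonical k-mer index of a contig set.

    Requires odd ``k >= 11`` (odd k makes a k-mer never equal its own
    reverse complement, so canonicalization is unambiguous).
    """
    if k < 11 or k % 2 == 0:
        raise ValueError(f"k must be an odd integer >= 11, got {k}")
    ids, sizes, kmer_arrays, owner_arrays, unindexable = [], [], [], [], []
    for cid, seq in contigs.contigs:
        km = canonical_kmers(seq, k)
        if km.size == 0:
            unindexable.append(cid)
            continue
        idx = len(ids)
        ids.append(cid)
        sizes.append(km.size)
        kmer_arrays.append(km)
        owner_arrays.append(np.full(km.size, idx, dtype=np.int64))
    if ids:
        kmers = np.concatenate(kmer_arrays)
        owners = np.concatenate(owner_arrays)
        order = np.argsort(kmers)
        kmers, owners = kmers[order], owners[order]
    else:
        kmers = np.empty(0, dtype=np.int64)
        owners = np.empty(0, dtype=np.int64)
    return KmerIndex(
        k=k,
        contig_ids=ids,
        set_sizes=np.asarray(sizes, dtype=np.int64),
        sorted_kmers=kmers,
        owners=owners,
        unindexable=unindexable,
    )


@dataclass
class MatchTable:
    """Qualifying cross-assembly contig pairs with containment scores."""

    pairs: pd.DataFrame  # id_a, id_b, containment_ab, containment_ba, shared_kmers, reciprocal_best
    k: int
    min_containment: float

    COLUMNS = ("id_a", "id_b", "containment_ab", "containment_ba", "shared_kmers", "reciprocal_best")

    @property
    def matched_a_ids(self) -> set[str]:
        return set(self.pairs["id_a"])

    @property
    def matched_b_ids(self) -> set[str]:
        return set(self.pairs["id_b"])

    @classmethod
    def empty(cls, k: int = DEFAULT_K, min_containment: float = DEFAULT_MIN_CONTAINMENT) -> "MatchTable":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)), k=k, min_containment=min_containment)

    @classmethod
    def from_tsv(cls, path, k: int = DEFAULT_K, min_containment: float = DEFAULT_MIN_CONTAINMENT) -> "MatchTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"id_a": str, "id_b": str})
        return cls(df, k=k, min_containment=min_containment)

    def to_tsv(self, path, header_comments=()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.pairs.to_csv(fh, sep="\t", index=False)


def match_assemblies(
    a: ContigSet,
    b: ContigSet,
    k: int = DEFAULT_K,
    min_containment: float = DEFAULT_MIN_CONTAINMENT,
) -> MatchTable:
    """Match contigs of assembly A against assembly B.

    For each ordered pair (x in A, y in B) with at least one shared
    canonical k-mer, containment is computed in both directions on the
    distinct-kmer sets; the pair is reported iff
    ``max(containment_ab, containment_ba) >= min_containment``.  Each A
    contig's best qualifying pair (highest max-containment, ties broken
    by higher shared_kmers, then lexicographic partner id) is flagged
    when it is also the best pair of its B partner (reciprocal best).
    The table is sorted by (id_a, id_b), so it is independent of input
    contig order.
    """
    if not a.contigs or not b.contigs:
        return MatchTable.empty(k=k, min_containment=min_containment)
    idx_b = index_kmers(b, k=k)
    rows = []
    for cid, seq in a.contigs:
        q = canonical_kmers(seq, k)
        if q.size == 0:
            continue
        shared = idx_b.shared_counts(q)
        hits = np.nonzero(shared)[0]
        for j in hits:
            c_ab = shared[j] / q.size
            c_ba = shared[j] / idx_b.set_sizes[j]
            if max(c_ab, c_ba) >= min_containment:
                rows.append((cid, idx_b.contig_ids[j], float(c_ab), float(c_ba), int(shared[j])))
    df = pd.DataFrame(rows, columns=list(MatchTable.COLUMNS[:5]))
    df["reciprocal_best"] = 0
    if len(df):
        df["_score"] = df[["containment_ab", "containment_ba"]].max(axis=1)
        best_a = _best_partner(df, "id_a", "id_b")
        best_b = _best_partner(df, "id_b", "id_a")
        recip = {(x, y) for x, y in best_a.items() if best_b.get(y) == x}
        df["reciprocal_best"] = [int((r.id_a, r.id_b) in recip) for r in df.itertuples(index=False)]
        df = df.drop(columns="_score")
        df = df.sort_values(["id_a", "id_b"], kind="stable").reset_index(drop=True)
    return MatchTable(df, k=k, min_containment=min_containment)


def _best_partner(df: pd.DataFrame, group_col: str, partner_col: str) -> dict[str, str]:
    ranked = df.sort_values(
        [group_col, "_score", "shared_kmers", partner_col],
        ascending=[True, False, False, True],
        kind="stable",
    )
    firsts = ranked.drop_duplicates(subset=group_col, keep="first")
    return dict(zip(firsts[group_col], firsts[partner_col]))


def containment(x: str, y: str, k: int = DEFAULT_K) -> float:
    """Direct containment of sequence x's canonical k-mer set in y's."""
    kx = canonical_kmers(x, k)
    if kx.size == 0:
        return 0.0
    ky = canonical_kmers(y, k)
    return float(np.isin(kx, ky).sum() / kx.size)
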