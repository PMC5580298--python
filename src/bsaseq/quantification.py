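"""Read-count quantification: RPKM conversion and presence/absence calls.

Expression is summarized as RPKM (reads per kilobase of transcript per
million mapped reads),

    rpkm = 1e9 * C / (N * L)

where ``C`` is the read count assigned to a contig in one genotype's
library, ``L`` the contig length in bp and ``N`` the genotype's library
size.  Detection is a trinary call at two strict thresholds: a contig is
*present* in a genotype when RPKM > 10, *absent* when RPKM < 5, and
*ambiguous* in between.  Values exactly on a threshold are ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PRESENT_MIN_DEFAULT = 10.0
ABSENT_MAX_DEFAULT = 5.0

#: single-character encodings used in presence TSVs
PRESENT, ABSENT, AMBIGUOUS = "P", "A", "U"


def _read_commented_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _write_commented_tsv(df: pd.DataFrame, path, header_comments=()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Raw read counts per contig per genotype, plus contig lengths.

    Parameters
    ----------
    counts
        Integer DataFrame, contigs on the index, genotype ids as columns.
    lengths_bp
        Contig lengths in bp, indexed like ``counts``.
    library_sizes
        Optional per-genotype library sizes (total reads).  When omitted,
        column sums of ``counts`` are used, i.e. N counts only assigned
        reads.
    """

    counts: pd.DataFrame
    lengths_bp: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        if not self.counts.index.equals(pd.Index(self.lengths_bp.index)):
            raise ValueError("counts index and lengths_bp index differ")
        if (np.asarray(self.lengths_bp) <= 0).any():
            raise ValueError("contig lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is not None:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise ValueError("library_sizes missing for some genotypes")
            if (self.library_sizes <= 0).any():
                raise ValueError("library sizes must be positive")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def effective_library_sizes(self) -> pd.Series:
        """Library sizes used for RPKM: explicit override or column sums."""
        if self.library_sizes is not None:
            return self.library_sizes.astype(float)
        return self.counts.sum(axis=0).astype(float)

    # -- TSV dialect: contig_id, length_bp, then one column per genotype ----
    @classmethod
    def from_tsv(cls, path, library_sizes: pd.Series | None = None) -> "ExpressionMatrix":
        df = _read_commented_tsv(path)
        df = df.set_index("contig_id")
        lengths = df.pop("length_bp")
        return cls(counts=df, lengths_bp=lengths, library_sizes=library_sizes)

    def to_tsv(self, path, header_comments=()) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths_bp)
        out = out.reset_index().rename(columns={"index": "contig_id"})
        out.columns = ["contig_id", "length_bp", *self.counts.columns]
        _write_commented_tsv(out, path, header_comments)


@dataclass
class RPKMMatrix:
    """RPKM values on the same contig x genotype axes as the count matrix."""

    values: pd.DataFrame
    lengths_bp: pd.Series

    @property
    def contig_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path) -> "RPKMMatrix":
        df = _read_commented_tsv(path).set_index("contig_id")
        lengths = df.pop("length_bp")
        return cls(values=df, lengths_bp=lengths)

    def to_tsv(self, path, header_comments=()) -> None:
        out = self.values.copy()
        out.insert(0, "length_bp", self.lengths_bp)
        out = out.reset_index()
        out.columns = ["contig_id", "length_bp", *self.values.columns]
        _write_commented_tsv(out, path, header_comments)


@dataclass
class PresenceMatrix:
    """Trinary present/absent/ambiguous calls per contig per genotype."""

    calls: pd.DataFrame  # values in {"P", "A", "U"}
    present_min: float = PRESENT_MIN_DEFAULT
    absent_max: float = ABSENT_MAX_DEFAULT

    def __post_init__(self):
        if self.absent_max > self.present_min:
            raise ValueError("absent_max must be <= present_min")

    def present(self) -> pd.DataFrame:
        return self.calls == PRESENT

    def absent(self) -> pd.DataFrame:
        return self.calls == ABSENT

    @classmethod
    def from_tsv(cls, path, present_min=PRESENT_MIN_DEFAULT, absent_max=ABSENT_MAX_DEFAULT) -> "PresenceMatrix":
        df = _read_commented_tsv(path).set_index("contig_id")
        return cls(calls=df, present_min=present_min, absent_max=absent_max)

    def to_tsv(self, path, header_comments=()) -> None:
        out = self.calls.reset_index()
        out.columns = ["contig_id", *self.calls.columns]
        _write_commented_tsv(out, path, header_comments)


def compute_rpkm(matrix: ExpressionMatrix) -> RPKMMatrix:
    """Convert raw counts to RPKM, ``1e9 * C / (N * L)``.

    With ``library_sizes`` equal to the column sums, the values satisfy
    the conservation identity ``sum_i rpkm_i * L_i == 1e9`` per genotype.

    Raises
    ------
    ValueError
        If any contig length or library size is zero/negative.
    """
    n = matrix.effective_library_sizes
    if (n <= 0).any():
        raise ValueError("library sizes must be positive (empty library?)")
    lengths = matrix.lengths_bp.to_numpy(dtype=float)[:, None]
    counts = matrix.counts.to_numpy(dtype=float)
    values = 1e9 * counts / (n.to_numpy()[None, :] * lengths)
    df = pd.DataFrame(values, index=matrix.counts.index, columns=matrix.counts.columns)
    return RPKMMatrix(values=df, lengths_bp=matrix.lengths_bp)


def classify_presence(
    rpkm: RPKMMatrix,
    present_min: float = PRESENT_MIN_DEFAULT,
    absent_max: float = ABSENT_MAX_DEFAULT,
) -> PresenceMatrix:
    """Call each cell present (RPKM > present_min), absent (< absent_max),
    or ambiguous.  Both inequalities are strict: a value exactly at a
    threshold is ambiguous."""
    if absent_max > present_min:
        raise ValueError(f"inverted thresholds: absent_max={absent_max} > present_min={present_min}")
    v = rpkm.values.to_numpy(dtype=float)
    calls = np.full(v.shape, AMBIGUOUS, dtype=object)
    calls[v > present_min] = PRESENT
    calls[v < absent_max] = ABSENT
    df = pd.DataFrame(calls, index=rpkm.values.index, columns=rpkm.values.columns)
    return PresenceMatrix(calls=df, present_min=present_min, absent_max=absent_max)
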