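"""Segregation genetics for a dominant volatile-producer allele.

The cross is producer x non-producer in an F1 design: the producer parent
is heterozygous for a dominant allele at every locus the model requires
(one or two unlinked loci, disomic inheritance), the non-producer parent
carries none.  Expected producer fractions follow from gamete enumeration
(1/2 per locus), scaled by an effective penetrance that absorbs
environmental loss of expression of the trait.  Observed producer counts
are compared with a model by an exact binomial test, and marker/transcript
co-segregation by an exact conditional 2x2 test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

MODEL_LOCI = {"one_locus": 1, "two_locus": 2}

# above this n the exact-rational enumeration is pointlessly slow and
# scipy's implementation of the same minlike test is used instead
_EXACT_RATIONAL_MAX_N = 2000


@dataclass
class GeneticModel:
    """Dominant-allele model: 'one_locus' or 'two_locus', with penetrance."""

    model: str
    penetrance: float = 1.0

    def __post_init__(self):
        if self.model not in MODEL_LOCI:
            raise ValueError(f"unknown model {self.model!r}; expected one of {sorted(MODEL_LOCI)}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")

    @property
    def n_loci(self) -> int:
        return MODEL_LOCI[self.model]


@dataclass
class SegregationTest:
    k: int
    n: int
    p0: float
    p_value: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise ValueError("k out of range")


@dataclass
class CosegTable:
    """2x2 marker-band x transcript-detection contingency summary.

    n11: band present & transcript detected; n00: both absent;
    n10/n01: discordant cells.  Concordance is (n11 + n00) / total and
    exact_p the two-sided conditional (hypergeometric) p-value.
    """

    n11: int
    n10: int
    n01: int
    n00: int
    concordance: float
    exact_p: float
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def expected_producer_fraction(model: GeneticModel) -> float:
    """Expected producer fraction in the F1, by gamete enumeration.

    The heterozygous parent transmits the dominant allele at each locus
    with probability 1/2, independently (unlinked loci); the null parent
    transmits nothing.  A progeny is a (potential) producer iff it
    carries a dominant allele at every model locus, and expresses the
    trait with probability ``penetrance``.
    """
    loci = model.n_loci
    producer = 0
    gametes = list(itertools.product([0, 1], repeat=loci))  # per-locus transmission
    for g in gametes:
        if all(g):
            producer += 1
    return producer / len(gametes) * model.penetrance


def exact_binomial_pvalue(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minlike convention).

    Sums P(X = j) over every outcome j whose probability is less than or
    equal to that of the observed k, under X ~ Binomial(n, p0).  Computed
    with exact rational arithmetic so ties (e.g. the mirror outcome at
    p0 = 1/2) are handled without floating-point ambiguity.
    """
    if not 0 <= k <= n:
        raise ValueError("k out of range")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if n > _EXACT_RATIONAL_MAX_N:
        return float(stats.binomtest(k, n, p0).pvalue)
    p = Fraction(p0)
    q = 1 - p
    # pmf(j) = C(n,j) p^j q^(n-j); compare via exact rationals
    pmfs = [math.comb(n, j) * p**j * q ** (n - j) for j in range(n + 1)]
    obs = pmfs[k]
    total = sum(pm for pm in pmfs if pm <= obs)
    return float(min(total, Fraction(1)))


def binomial_segregation_test(k: int, n: int, p0: float) -> SegregationTest:
    """Exact test of an observed producer count against a model fraction.

    Returns the minlike two-sided p-value and the exact (Clopper-Pearson)
    95% confidence interval for the producer fraction k/n.
    """
    p_value = exact_binomial_pvalue(k, n, p0)
    ci = stats.binomtest(k, n, p0).proportion_ci(confidence_level=0.95, method="exact")
    return SegregationTest(k=k, n=n, p0=p0, p_value=p_value, ci_low=float(ci.low), ci_high=float(ci.high))


def marker_cosegregation(marker, transcript) -> CosegTable:
    """Cross-tabulate per-genotype marker band presence vs transcript
    detection (both 0/1, aligned by genotype).

    ``marker`` and ``transcript`` may be dicts keyed by genotype id or
    equal-length sequences.  Genotypes with a missing value (None/NaN) in
    either feature are excluded and counted in ``n_excluded``.  The exact
    p-value is the two-sided conditional test on the 2x2 table (Fisher's
    exact test).
    """
    m, t, n_excluded = _align_binary(marker, transcript)
    if m.size < 2:
        raise ValueError("need at least 2 genotypes with complete data")
    n11 = int(((m == 1) & (t == 1)).sum())
    n10 = int(((m == 1) & (t == 0)).sum())
    n01 = int(((m == 0) & (t == 1)).sum())
    n00 = int(((m == 0) & (t == 0)).sum())
    total = n11 + n10 + n01 + n00
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return CosegTable(
        n11=n11,
        n10=n10,
        n01=n01,
        n00=n00,
        concordance=(n11 + n00) / total,
        exact_p=float(p),
        n_excluded=n_excluded,
    )


def _align_binary(marker, transcript) -> tuple[np.ndarray, np.ndarray, int]:
    if isinstance(marker, dict) or isinstance(transcript, dict):
        if not (isinstance(marker, dict) and isinstance(transcript, dict)):
            raise TypeError("marker and transcript must both be dicts or both sequences")
        keys = sorted(set(marker) & set(transcript))
        pairs = [(marker[k], transcript[k]) for k in keys]
    else:
        if len(marker) != len(transcript):
            raise ValueError("marker and transcript must cover the same genotypes")
        pairs = list(zip(marker, transcript))
    clean = [
        (int(a), int(b))
        for a, b in pairs
        if a is not None and b is not None and not (isinstance(a, float) and math.isnan(a)) and not (isinstance(b, float) and math.isnan(b))
    ]
    n_excluded = len(pairs) - len(clean)
    if any(v not in (0, 1) for pair in clean for v in pair):
        raise ValueError("marker/transcript values must be 0 or 1")
    arr = np.asarray(clean, dtype=int).reshape(-1, 2)
    return arr[:, 0], arr[:, 1], n_excluded
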