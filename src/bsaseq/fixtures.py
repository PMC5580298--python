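"""Packaged worked-example fixtures.

Small literal datasets from the emulated study, stored as plain TSV under
``bsaseq/fixtures/``:

* ``table1_rpkm.tsv`` — the five candidate transcripts with their RPKM
  values in the two parents and the two producer seedlings (values as
  printed, 2 decimals; lengths are the spanned reference-genome
  intervals).
* ``segregation_counts.tsv`` — observed producer counts in the two
  published crosses (37/114 and 46/189).
* ``marker_coseg.tsv`` — twelve segregating progeny scored for the
  ~1.5 kb marker band and transcript detection, perfectly concordant
  (the band and transcript segregate 1:1).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .quantification import RPKMMatrix

TABLE1_GENOTYPES = ["Mara", "Elyana", "P098", "P103"]
TABLE1_PRODUCERS = ["Mara", "P098", "P103"]
TABLE1_NONPRODUCER_PARENT = "Elyana"

#: contig -> (length_bp, rpkm in Mara, Elyana, P098, P103)
TABLE1_ROWS = {
    "contig_1885": (1328, (131.23, 0.34, 57.74, 85.39)),
    "contig_7159": (1479, (44.47, 0.24, 60.64, 37.05)),
    "contig_12547": (2492, (26.01, 1.75, 37.43, 33.52)),
    "contig_10605": (597, (48.69, 0.67, 27.46, 114.68)),
    "contig_5826": (1704, (26.52, 2.61, 42.15, 41.24)),
}

SEGREGATION_COUNTS = {
    "Elyana_x_Mara_des_Bois": (37, 114),
    "Mieze_Schindler_x_Elsanta": (46, 189),
}

#: (band present, transcript detected) per progeny; 6 carriers, 6 non-carriers
MARKER_COSEG_ROWS = [("S%02d" % i, 1, 1) for i in range(1, 7)] + [("S%02d" % i, 0, 0) for i in range(7, 13)]


def _fixture_path(name: str):
    return resources.files("bsaseq").joinpath("fixtures", name)


def write_fixtures(outdir) -> list[Path]:
    """Write the three fixture TSVs into ``outdir``; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out / "table1_rpkm.tsv"
    rows = []
    for cid, (length, values) in TABLE1_ROWS.items():
        rows.append({"contig_id": cid, "length_bp": length, **dict(zip(TABLE1_GENOTYPES, values))})
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.2f")
    paths.append(p)

    p = out / "segregation_counts.tsv"
    pd.DataFrame(
        [{"population": name, "n_producers": k, "n_total": n} for name, (k, n) in SEGREGATION_COUNTS.items()]
    ).to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = out / "marker_coseg.tsv"
    pd.DataFrame(MARKER_COSEG_ROWS, columns=["genotype_id", "band_1500_present", "transcript_detected"]).to_csv(
        p, sep="\t", index=False
    )
    paths.append(p)
    return paths


def load_table1() -> RPKMMatrix:
    """The packaged candidate-transcript RPKM fixture as an RPKMMatrix."""
    with resources.as_file(_fixture_path("table1_rpkm.tsv")) as path:
        return RPKMMatrix.from_tsv(path)


def load_segregation_counts() -> dict[str, tuple[int, int]]:
    with resources.as_file(_fixture_path("segregation_counts.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return {str(r.population): (int(r.n_producers), int(r.n_total)) for r in df.itertuples(index=False)}


def load_marker_coseg() -> pd.DataFrame:
    with resources.as_file(_fixture_path("marker_coseg.tsv")) as path:
        return pd.read_csv(path, sep="\t", comment="#")
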