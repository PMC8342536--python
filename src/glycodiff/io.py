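"""TSV readers/writers and sample-group bookkeeping.

File dialects
-------------
Glycopeptide quant table (long TSV): columns
``sample_id, protein, glycosite, glycan, rt, auc``; the glycan column uses
the compact composition notation of :mod:`glycodiff.glycans`.

Protein matrix (wide TSV): first column ``protein``, remaining columns are
sample ids; empty cells are missing values. Intensities are log2 scale.

Metadata TSV: columns ``sample_id, grade, gleason`` with grade in
{Normal, G1, G2, G3} and gleason in {NA, GG2, GG3, GG4, GG5}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GLYCO_COLUMNS = ["sample_id", "protein", "glycosite", "glycan", "rt", "auc"]
META_COLUMNS = ["sample_id", "grade", "gleason"]
GRADES = ["Normal", "G1", "G2", "G3"]
GLEASON_GRADES = ["GG2", "GG3", "GG4", "GG5"]

#: Gleason groups used when comparing grading schemes (papered convention:
#: GG2 ~ G1, GG3+GG4 ~ G2, GG5 ~ G3).
GLEASON_SCHEME_PAIRS = [
    (("GG2",), "G1"),
    (("GG3", "GG4"), "G2"),
    (("GG5",), "G3"),
]


def read_glyco_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "protein": str,
                                            "glycosite": str, "glycan": str})
    missing = [c for c in GLYCO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"glyco table {path}: missing columns {missing}")
    return df[GLYCO_COLUMNS]


def read_protein_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "protein"
    df.columns = df.columns.astype(str)
    return df.astype(float)


def read_metadata(path) -> pd.DataFrame:
    # keep the literal "NA" gleason label as a string
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path}: missing columns {missing}")
    return df[META_COLUMNS]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def group_series(metadata: pd.DataFrame, scheme: str = "pathological") -> pd.Series:
    """Map sample ids to group labels under a grading scheme.

    ``pathological``: Normal/G1/G2/G3. ``two_group``: Normal vs PCa (any
    G1-G3). ``gleason``: Normal plus GG2-GG5 for cancer samples.
    """
    meta = metadata.set_index("sample_id")
    if scheme == "pathological":
        s = meta["grade"]
    elif scheme == "two_group":
        s = meta["grade"].map(lambda g: "Normal" if g == "Normal" else "PCa")
    elif scheme == "gleason":
        s = np.where(meta["grade"] == "Normal", "Normal", meta["gleason"])
        s = pd.Series(s, index=meta.index)
    else:
        raise ValueError(f"unknown group scheme {scheme!r}")
    s = s.astype(str)
    s.name = "group"
    return s


def dedupe_records(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Resolve duplicate (sample, glycopeptide) quant records.

    Keeps the maximum-AUC record per (sample_id, protein, glycosite,
    glycan) key. Returns the deduplicated table and the number of
    duplicates dropped.
    """
    key = ["sample_id", "protein", "glycosite", "glycan"]
    n_before = len(df)
    out = (df.sort_values("auc", ascending=False, kind="stable")
             .drop_duplicates(subset=key, keep="first")
             .sort_index())
    return out.reset_index(drop=True), n_before - len(out)
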