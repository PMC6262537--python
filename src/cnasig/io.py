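"""Readers and writers for the on-disk formats of the CNA pipeline.

Formats
-------
* CNA matrix: TSV whose first four columns are ``probe_id, chromosome,
  start, end`` (0-based half-open), followed by one column per patient of
  log2 ratios; blank cells are missing values, never zero.
* Clinical table: CSV with the schema of a CRCLM surgical cohort
  (demographics, synchronous/relapse status, TNM stage, primary site, and
  optional RFS/OS time+event columns).
* Gene annotation: BED4 (chrom, start, end, symbol), 0-based half-open.
* SEG: tab-delimited segmented copy number
  (sample, chromosome, start, end, num probes, mean log2 ratio).

A packaged fixture carries the printed clinical characteristics of the
21-patient CRCLM discovery cohort (GEO accession GSE103088); its survival
columns are blank because they live in the archive, not the printed table.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

__all__ = [
    "read_cna_matrix",
    "write_cna_matrix",
    "read_clinical",
    "write_clinical",
    "load_crclm_clinical",
    "summarize_clinical",
    "read_gene_bed",
    "write_gene_bed",
    "write_seg",
    "read_seg",
]

_ANNOT_COLS = ["probe_id", "chromosome", "start", "end"]

REQUIRED_CLINICAL = ["patient_id", "sex", "age", "synchronous", "relapse"]

_TRUE = {"yes", "y", "true", "1", "relapse", "relapsed", "event", "m"}
_FALSE = {"no", "n", "false", "0", "non-relapse", "none", ""}

#: primary sites counted as colon when summarizing ("rectosigmoid" is a
#: colonic site; only literal "rectum" is rectal)
COLON_SITES = {"cecum", "ascending", "transverse", "descending", "sigmoid", "rectosigmoid"}


def write_cna_matrix(matrix: pd.DataFrame, probes: pd.DataFrame, path) -> None:
    """Write a probes × patients matrix with its annotation as TSV."""
    ann = probes.set_index("probe_id").loc[matrix.index, ["chromosome", "start", "end"]]
    out = pd.concat([ann.reset_index(), matrix.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_cna_matrix(path):
    """Read a TSV CNA matrix; returns ``(matrix, probe_annotation)``.

    Blank cells become NaN.  Duplicate probe ids or non-numeric log2 values
    are errors (the offending row/column is named).
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"CNA matrix missing annotation columns: {missing}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe ids: {dups[:5]}")
    probes = df[_ANNOT_COLS].copy()
    if (probes["start"] >= probes["end"]).any():
        raise ValueError("malformed probe interval: start >= end")
    patient_cols = [c for c in df.columns if c not in _ANNOT_COLS]
    if not patient_cols:
        raise ValueError("CNA matrix has no patient columns")
    matrix = df[patient_cols].copy()
    for col in patient_cols:
        try:
            matrix[col] = pd.to_numeric(matrix[col])
        except (ValueError, TypeError) as exc:
            bad = matrix[pd.to_numeric(matrix[col], errors="coerce").isna() & matrix[col].notna()]
            row = df.loc[bad.index[0], "probe_id"] if len(bad) else "?"
            raise ValueError(f"non-numeric value in column {col!r}, probe {row!r}") from exc
    matrix.index = pd.Index(df["probe_id"], name="probe_id")
    probes = probes.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    return matrix.loc[probes["probe_id"]], probes


def _to_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE or s == "nan":
            return False
        raise ValueError(f"cannot interpret {v!r} as boolean in column {column!r}")
    return series.map(conv)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical CSV, normalizing Yes/No/Relapse-style booleans.

    Unknown stage strings are preserved verbatim; survival columns are
    optional and may be blank (NaN).
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "stage": str, "primary_site": str})
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {dups}")
    for col in ("synchronous", "relapse", "multifocal", "cea_elevated", "rfs_event", "os_event"):
        if col in df.columns and not df[col].isna().all():
            df[col] = _to_bool(df[col], col)
    for col in ("rfs_time", "os_time"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
            if (df[col].dropna() < 0).any():
                raise ValueError(f"negative times in column {col!r}")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def load_crclm_clinical() -> pd.DataFrame:
    """Load the packaged 21-patient CRCLM discovery-cohort clinical table."""
    ref = importlib.resources.files("cnasig") / "data" / "crclm_clinical.csv"
    with importlib.resources.as_file(ref) as p:
        return read_clinical(p)


def summarize_clinical(clinical: pd.DataFrame) -> dict:
    """Cohort counts and age summary for a clinical table.

    Primary sites are rolled up to colon vs rectum (rectosigmoid counts as
    colon).  Fields that are entirely missing are omitted from the summary.
    """
    if len(clinical) == 0:
        raise ValueError("empty clinical table")
    out: dict = {"n": int(len(clinical))}
    out["age_mean"] = float(round(clinical["age"].mean(), 1))
    out["age_min"] = float(clinical["age"].min())
    out["age_max"] = float(clinical["age"].max())
    out["n_male"] = int((clinical["sex"] == "M").sum())
    out["n_female"] = int((clinical["sex"] == "F").sum())
    out["n_relapse"] = int(clinical["relapse"].sum())
    out["n_non_relapse"] = int((~clinical["relapse"]).sum())
    out["n_synchronous"] = int(clinical["synchronous"].sum())
    out["n_metachronous"] = int((~clinical["synchronous"]).sum())
    if "primary_site" in clinical.columns and clinical["primary_site"].notna().any():
        site = clinical["primary_site"].str.strip().str.lower()
        out["n_rectum"] = int((site == "rectum").sum())
        out["n_colon"] = int(site.isin(COLON_SITES).sum())
        out["site_counts"] = site.value_counts().to_dict()
    for col in ("rfs_time", "os_time"):
        if col in clinical.columns and clinical[col].notna().any():
            out[f"{col}_mean"] = float(round(clinical[col].mean(), 1))
    return out


def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED4 gene annotation (chrom, start, end, symbol), half-open."""
    genes = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chromosome", "start", "end", "symbol"],
        dtype={"chromosome": str, "symbol": str},
    )
    genes["start"] = pd.to_numeric(genes["start"])
    genes["end"] = pd.to_numeric(genes["end"])
    if (genes["start"] < 0).any():
        raise ValueError("negative interval start in BED")
    if (genes["start"] >= genes["end"]).any():
        bad = genes.loc[genes["start"] >= genes["end"], "symbol"].tolist()
        raise ValueError(f"malformed BED intervals (start >= end): {bad}")
    if genes["symbol"].duplicated().any():
        raise ValueError("duplicate gene symbols in BED")
    genes = genes[["symbol", "chromosome", "start", "end"]]
    return genes.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    genes[["chromosome", "start", "end", "symbol"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_seg(block_matrix: pd.DataFrame, blocks: pd.DataFrame, path) -> None:
    """Write per-patient block means as a SEG file.

    Columns: sample, chromosome, start, end, num_probes, seg_mean (6 d.p.).
    """
    ann = blocks.set_index("block_id").loc[block_matrix.index]
    rows = []
    for patient in block_matrix.columns:
        vals = block_matrix[patient]
        for block_id, v in vals.items():
            a = ann.loc[block_id]
            rows.append(
                (patient, a["chromosome"], int(a["start"]), int(a["end"]),
                 int(a["n_probes"]), "" if pd.isna(v) else f"{v:.6f}")
            )
    out = pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "num_probes", "seg_mean"])
    out.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    if (seg["start"] >= seg["end"]).any():
        raise ValueError("malformed SEG intervals (start >= end)")
    return seg
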