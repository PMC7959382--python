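"""Readers and writers for the pipeline's file formats.

The feature and phenotype matrices use a semicolon-separated dialect: the
first column holds strain ids, the second (feature matrices only) the
subspecies annotation, and the remaining columns one feature each.  Columns
standing for several collapsed features carry comma-joined ids in the
header.  Phenotype files have 13 columns — strain id plus the 12 condition
combinations — with missing measurements as empty fields.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import FeatureMatrix, Representation
from .kinetics import ALL_CONDITIONS, Condition, PhCurve, PhenotypeTable

DELIM = ";"


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix in the semicolon dialect (integer values)."""
    path = Path(path)
    vals = matrix.values
    with open(path, "w") as fh:
        fh.write(DELIM.join(["Strain", "Subspecies", *map(str, vals.columns)]) + "\n")
        sub = matrix.subspecies
        arr = vals.to_numpy()
        for i, strain in enumerate(vals.index):
            row = arr[i]
            fh.write(
                DELIM.join([str(strain), str(sub[strain]), *(str(int(v)) for v in row)]) + "\n"
            )


def read_matrix(path: str | Path, representation: Representation = "gene") -> FeatureMatrix:
    """Read a semicolon-dialect feature matrix.

    Comma-joined header cells become single columns whose membership is
    recorded in ``collapse_map``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(DELIM)
        if len(header) < 2:
            raise ValueError(f"{path}: expected at least strain and subspecies columns")
        feat_names = header[2:]
        strains, subs, data = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(DELIM)
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})")
            strains.append(parts[0])
            subs.append(parts[1])
            try:
                data.append([int(v) for v in parts[2:]])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer value ({e})") from None
    if len(set(strains)) != len(strains):
        raise ValueError(f"{path}: duplicate strain ids")
    values = pd.DataFrame(
        np.asarray(data, dtype=np.int64).reshape(len(strains), len(feat_names)),
        index=strains,
        columns=feat_names,
    )
    values.index.name = "strain"
    collapse_map = {name: name.split(",") for name in feat_names if "," in name}
    return FeatureMatrix(
        representation=representation,
        values=values,
        subspecies=pd.Series(subs, index=strains, name="subspecies"),
        collapse_map=collapse_map,
    )


def _format_vmax(v: float) -> str:
    # repr round-trips doubles exactly, so write∘read is lossless
    return "" if np.isnan(v) else repr(float(v))


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    """Write a 13-column semicolon phenotype file; missing values as empty fields."""
    path = Path(path)
    vals = table.values
    with open(path, "w") as fh:
        fh.write(DELIM.join(["Strain", *vals.columns]) + "\n")
        for strain, row in vals.iterrows():
            fh.write(DELIM.join([str(strain), *(_format_vmax(v) for v in row)]) + "\n")


def read_phenotypes(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> PhenotypeTable:
    """Read a semicolon phenotype file; empty fields become missing.

    ``column_map`` renames non-standard condition headers to the
    ``DW_YE_30``-style labels before validation.
    """
    df = pd.read_csv(path, sep=DELIM, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "strain"
    if column_map:
        df = df.rename(columns=dict(column_map))
    expected = {c.label for c in ALL_CONDITIONS}
    unknown = set(df.columns) - expected
    if unknown:
        raise ValueError(
            f"{path}: unrecognised condition columns {sorted(unknown)}; "
            "pass column_map to rename them"
        )
    return PhenotypeTable(df)


def write_roary(table: pd.DataFrame, path: str | Path) -> None:
    """Write a Roary-style gene_presence_absence CSV (quoted fields)."""
    table.to_csv(path, index=False, quoting=1)


def read_roary(path: str | Path) -> pd.DataFrame:
    """Read a Roary-style gene_presence_absence CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "Gene" not in df.columns:
        raise ValueError(f"{path}: not a Roary-style table (no 'Gene' column)")
    return df


#: pfam_scan output column order (pfam_scan.pl -fasta ... -dir ...)
PFAMSCAN_COLUMNS = (
    "seq_id",
    "aln_start",
    "aln_end",
    "env_start",
    "env_end",
    "hmm_acc",
    "hmm_name",
    "type",
    "hmm_start",
    "hmm_end",
    "hmm_len",
    "bit_score",
    "evalue",
    "significance",
    "clan",
)


def write_pfamscan(hits: pd.DataFrame, path: str | Path) -> None:
    """Write domain hits as a pfam_scan-style whitespace table.

    ``hits`` needs at least seq_id, hmm_acc and hmm_name; the remaining
    pfam_scan columns are filled with placeholder values.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# pfam_scan.pl,  run as part of a synthetic data emission\n")
        fh.write("# <seq id> <alignment start> <alignment end> <envelope start> "
                 "<envelope end> <hmm acc> <hmm name> <type> <hmm start> <hmm end> "
                 "<hmm length> <bit score> <E-value> <significance> <clan>\n")
        for _, row in hits.iterrows():
            fields = [
                str(row["seq_id"]),
                str(row.get("aln_start", 1)),
                str(row.get("aln_end", 100)),
                str(row.get("env_start", 1)),
                str(row.get("env_end", 100)),
                str(row["hmm_acc"]),
                str(row["hmm_name"]),
                str(row.get("type", "Domain")),
                str(row.get("hmm_start", 1)),
                str(row.get("hmm_end", 100)),
                str(row.get("hmm_len", 100)),
                str(row.get("bit_score", 100.0)),
                str(row.get("evalue", 1e-30)),
                str(row.get("significance", 1)),
                str(row.get("clan", "No_clan")),
            ]
            fh.write(" ".join(fields) + "\n")


def read_pfamscan(path: str | Path) -> pd.DataFrame:
    """Read a pfam_scan-style whitespace-delimited hit table ('#' comments)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path}: malformed pfam_scan line: {line!r}")
            rows.append(parts[: len(PFAMSCAN_COLUMNS)])
    df = pd.DataFrame(rows, columns=list(PFAMSCAN_COLUMNS)[: len(rows[0]) if rows else 15])
    if not len(df):
        return pd.DataFrame(columns=list(PFAMSCAN_COLUMNS))
    return df


def read_fasta_dir(path: str | Path) -> dict[str, list]:
    """Load per-strain FASTA files from a directory (strain id = file stem)."""
    from Bio import SeqIO

    path = Path(path)
    genomes = {}
    for f in sorted(path.glob("*.fasta")):
        genomes[f.stem] = list(SeqIO.parse(f, "fasta"))
    if not genomes:
        raise FileNotFoundError(f"no .fasta files under {path}")
    return genomes


def read_kinetics_long(path: str | Path) -> list[PhCurve]:
    """Read long-form kinetic measurements into curves.

    Expected columns: strain_id, temperature_C, volume, yeast, time_h, value,
    value_kind — one row per time point, any delimiter pandas can sniff from
    ';' or ','.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"strain_id", "temperature_C", "volume", "yeast", "time_h", "value", "value_kind"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: kinetics table needs columns {sorted(required)}")
    curves = []
    keys = ["strain_id", "temperature_C", "volume", "yeast", "value_kind"]
    for (sid, temp, vol, yeast, kind), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            PhCurve(
                strain_id=str(sid),
                condition=Condition(int(temp), str(vol), str(yeast)),
                times=grp["time_h"].to_numpy(),
                values=grp["value"].to_numpy(),
                value_kind=str(kind),
            )
        )
    return curves


def write_kinetics_long(curves: list[PhCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, v in zip(c.times, c.values):
            rows.append(
                (c.strain_id, c.condition.temperature_C, c.condition.volume,
                 c.condition.yeast, t, v, c.value_kind)
            )
    pd.DataFrame(
        rows,
        columns=["strain_id", "temperature_C", "volume", "yeast", "time_h", "value", "value_kind"],
    ).to_csv(path, sep=";", index=False)


def read_calibration_pairs(path: str | Path) -> list[tuple[float, float]]:
    """Read a two-column (hue, pH) calibration table."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: calibration table needs two columns (hue, pH)")
    return list(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float)))
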