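"""Delimited-table input/output for the pipeline.

All tables are comma-separated with a header row and "NA" for missing:

* ``genotypes.csv`` — wide lines x markers numeric code matrix, first
  column ``line``;
* ``map.csv`` — ``marker, chrom, pos_cm, type`` (plus ``dominant_phase``
  when written by the simulator);
* ``phenotypes.csv`` — long table ``line, trait, year, environment, value``;
* ``lineage.csv`` — ``line, lineage, generation``.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_genotypes",
    "read_map",
    "read_phenotypes",
    "read_lineage",
    "read_tables",
    "write_genotypes",
    "write_kinship",
    "read_kinship",
    "write_dataset",
]

_NA = "NA"


class SchemaError(ValueError):
    """A table violates its expected schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[_NA])
    if df.columns[0] != "line":
        raise SchemaError(f"{path}: first column must be 'line', got {df.columns[0]!r}")
    df = df.set_index("line")
    try:
        return df.astype(float)
    except ValueError as e:
        raise SchemaError(f"{path}: non-numeric genotype code ({e})") from None


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[_NA], keep_default_na=False)
    _require_columns(df, ["marker", "chrom", "pos_cm", "type"], path)
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise SchemaError(f"{path}: duplicated marker id {dup!r}")
    if (df["pos_cm"].astype(float) < 0).any():
        row = int(df.index[df["pos_cm"].astype(float) < 0][0]) + 2
        raise SchemaError(f"{path}: negative position at row {row}, column 'pos_cm'")
    bad = ~df["type"].isin(["dominant", "codominant"])
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise SchemaError(
            f"{path}: marker type must be dominant/codominant at row {row}, column 'type'"
        )
    return df


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[_NA])
    _require_columns(df, ["line", "trait", "year", "environment", "value"], path)
    return df


def read_lineage(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[_NA])
    _require_columns(df, ["line", "lineage", "generation"], path)
    return df


def read_tables(
    genotypes, map_, phenotypes, lineage
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the four pipeline tables.

    Markers in the genotype matrix must appear in the map; lines named
    in the phenotype and lineage tables must be genotyped.
    """
    gm = read_genotypes(genotypes)
    gmap = read_map(map_)
    pheno = read_phenotypes(phenotypes)
    lin = read_lineage(lineage)

    unknown_markers = [m for m in gm.columns if m not in set(gmap["marker"])]
    if unknown_markers:
        raise SchemaError(
            f"{genotypes}: markers absent from {map_}: {unknown_markers[:5]}"
        )
    known_lines = set(gm.index)
    for name, table in (("phenotypes", pheno), ("lineage", lin)):
        bad = ~table["line"].isin(known_lines)
        if bad.any():
            row = int(table.index[bad][0]) + 2
            raise SchemaError(
                f"{name} table: unknown line {table.loc[table.index[bad][0], 'line']!r} "
                f"at row {row}, column 'line'"
            )
    return gm, gmap, pheno, lin


def write_genotypes(gm: pd.DataFrame, path) -> None:
    gm.to_csv(path, index_label="line", na_rep=_NA)


def write_kinship(K: pd.DataFrame, path) -> None:
    K.to_csv(path, index_label="line", na_rep=_NA)


def read_kinship(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("line").astype(float)
    df.columns.name = None
    return df


def write_dataset(dataset, out_dir) -> dict[str, str]:
    """Write a simulated dataset as the four delimited tables + provenance.

    The genotype table stacks the F2 and RIL matrices (union of marker
    panels, NA where a line was not assayed on a marker).  Returns the
    mapping of table name to file path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = pd.concat([dataset.genotypes_f2, dataset.genotypes_ril], axis=0)
    geno = geno.reindex(columns=dataset.marker_map["marker"].tolist())
    geno = geno.dropna(axis=1, how="all")
    paths = {
        "genotypes": str(out / "genotypes.csv"),
        "map": str(out / "map.csv"),
        "phenotypes": str(out / "phenotypes.csv"),
        "lineage": str(out / "lineage.csv"),
        "provenance": str(out / "provenance.json"),
    }
    write_genotypes(geno, paths["genotypes"])
    dataset.marker_map.to_csv(paths["map"], index=False, na_rep=_NA)
    dataset.phenotypes.to_csv(paths["phenotypes"], index=False, na_rep=_NA)
    dataset.lineage.to_csv(paths["lineage"], index=False, na_rep=_NA)
    with open(paths["provenance"], "w") as fh:
        json.dump({"sim_config": dataset.config.to_dict()}, fh, indent=2, default=str)
    return paths
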