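"""CSV readers/writers for the pipeline artifacts.

Conventions: UTF-8 CSV with header rows; positions in cM, 0-based at each
chromosome start; missing genotype calls written as ``NA``. Every writer
round-trips through its reader.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import CrossRecord, DesignSpec, FounderSet, Pedigree


class FormatError(ValueError):
    pass


# -- pedigree ---------------------------------------------------------------


def write_pedigree_csv(pedigree: Pedigree, path):
    rows = [
        {"id": n, "mother": "", "father": "", "generation": "founder"}
        for n in pedigree.founders.names
    ]
    rows += [
        {"id": r.id, "mother": r.mother, "father": r.father, "generation": r.generation}
        for r in pedigree.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pedigree_csv(path, design: DesignSpec | None = None) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    founders = tuple(df[df["generation"] == "founder"]["id"])
    records = []
    seen = set(founders)
    for k, row in df[df["generation"] != "founder"].iterrows():
        for parent in (row["mother"], row["father"]):
            if parent not in seen:
                raise FormatError(
                    f"line {k + 2}: parent {parent!r} referenced before definition"
                )
        records.append(
            CrossRecord(row["id"], row["mother"], row["father"], row["generation"])
        )
        seen.add(row["id"])
    ped = Pedigree(
        founders=FounderSet(founders),
        design=design or DesignSpec(),
        records=records,
    )
    return ped


# -- genotypes --------------------------------------------------------------


def write_genotype_csv(calls, line_ids, marker_names, path):
    df = pd.DataFrame(np.asarray(calls), index=line_ids, columns=marker_names)
    df = df.astype("object").where(df >= 0, "NA")
    df.index.name = "line"
    df.to_csv(path)


def read_genotype_csv(path):
    df = pd.read_csv(path, index_col="line", keep_default_na=False)
    arr = df.replace("NA", -1).to_numpy(dtype=float)
    if np.any(arr != np.round(arr)):
        raise FormatError("genotype calls must be integers or NA")
    return arr.astype(np.int16), list(df.index), list(df.columns)


# -- intensities ------------------------------------------------------------


def write_intensity_csv(intensities, line_ids, marker_names, path):
    n, m, _ = np.asarray(intensities).shape
    df = pd.DataFrame(
        {
            "line": np.repeat(line_ids, m),
            "marker": np.tile(marker_names, n),
            "x": np.asarray(intensities)[:, :, 0].ravel(),
            "y": np.asarray(intensities)[:, :, 1].ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_intensity_csv(path):
    df = pd.read_csv(path)
    lines = list(dict.fromkeys(df["line"]))
    markers = list(dict.fromkeys(df["marker"]))
    arr = np.empty((len(lines), len(markers), 2))
    arr[:, :, 0] = df["x"].to_numpy().reshape(len(lines), len(markers))
    arr[:, :, 1] = df["y"].to_numpy().reshape(len(lines), len(markers))
    return arr, lines, markers


# -- genetic map ------------------------------------------------------------


def write_map_csv(df_map: pd.DataFrame, path):
    df_map.to_csv(path, index=False)


def read_map_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("chromosome", "marker", "position_cM"):
        if col not in df.columns:
            raise FormatError(f"map CSV missing column {col!r}")
    for c, grp in df.groupby("chromosome", sort=False):
        if np.any(np.diff(grp["position_cM"].to_numpy()) < 0):
            raise FormatError(f"map positions decrease on chromosome {c}")
    return df


# -- scans ------------------------------------------------------------------


def write_scan_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def read_scan_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
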