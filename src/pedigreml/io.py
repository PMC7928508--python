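"""Reading and writing the delimited phenotype tables.

Phenotype files are delimited text with columns ``animal``, ``generation``,
``hatch`` and one column per trait; missing values are empty or ``NA``.
"""

from __future__ import annotations

import pandas as pd

ID_COLUMNS = ("animal", "generation", "hatch")


def read_phenotypes(path, sep=None) -> pd.DataFrame:
    """Read a phenotype table; trait columns become floats with NaN missing."""
    df = pd.read_csv(path, sep=sep, engine="python",
                     na_values=["", "NA", "na", "."])
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} lacks columns: {missing}")
    df["animal"] = df["animal"].astype(str)
    for c in ("generation", "hatch"):
        df[c] = df[c].astype(int)
    for c in df.columns:
        if c not in ID_COLUMNS:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def trait_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in ID_COLUMNS]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
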