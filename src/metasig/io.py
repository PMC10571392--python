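"""Plain-TSV readers/writers for the pipeline's table formats.

All tables are UTF-8, tab-delimited, with a header row and sample (or
feature) ids in the first column.
"""

from __future__ import annotations

import pandas as pd

from .catalog import ValidationError


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_abundance(path) -> pd.DataFrame:
    """Samples x features relative-abundance matrix."""
    df = read_table(path)
    if (df.values < 0).any():
        raise ValidationError(f"negative abundances in {path}")
    return df


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError(f"metadata {path} lacks a sample_id column")
    return df.set_index("sample_id", drop=False)


def read_identity(path) -> pd.DataFrame:
    df = read_table(path)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"identity matrix {path} is not square/aligned")
    return df


def read_modules(path) -> dict:
    """modules.tsv: columns module_id, definition."""
    from .functions import parse_module_definition

    df = pd.read_csv(path, sep="\t")
    return {
        row["module_id"]: parse_module_definition(row["definition"],
                                                  module_id=row["module_id"])
        for _, row in df.iterrows()
    }


def read_presence(path) -> pd.DataFrame:
    return read_table(path).astype(bool)
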