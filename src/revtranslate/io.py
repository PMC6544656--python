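"""Plain-text table readers/writers shared by the CLI stages.

TSV dialect: tab-separated, header row, '.' decimal.  Expression matrices
are genes x samples with gene ids in the first column; trait tables are
indexed by sample id.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    return m


def write_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", index_label="gene_id")


def read_traits(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    if "group" not in t.columns:
        raise ValueError(f"traits table {path} lacks a 'group' column")
    return t


def write_traits(t: pd.DataFrame, path: str | Path) -> None:
    t.to_csv(path, sep="\t", index_label="sample_id")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_csv_table(path: str | Path, index_col=0) -> pd.DataFrame:
    t = pd.read_csv(path, index_col=index_col)
    t.index = t.index.astype(str)
    return t
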