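"""Tab-separated file formats shared by the CLI stages.

All tables are TSV with a mandatory header row, '.' decimal separator, and
gzip-transparent reading (pandas infers compression from the filename).
Expression matrices carry the probe/gene id in the first column with sample
ids as the remaining headers.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import pandas as pd

from .harmonize import ProbeMatrix


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_probe_map_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs probe_id and gene_symbol columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return df


def read_probe_matrix(expr_path, probemap_path, dataset_id: str | None = None) -> ProbeMatrix:
    values = read_expression_tsv(expr_path)
    pmap = read_probe_map_tsv(probemap_path)
    if dataset_id is None:
        dataset_id = Path(str(expr_path)).stem.replace(".expr", "").replace(".tsv", "")
    return ProbeMatrix(dataset_id=dataset_id, values=values, probe_gene_map=pmap)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def write_table_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label,
              float_format="%.10g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


DAYS_PER_MONTH = 30.436875  # mean Gregorian month


def months_from_days(days):
    """Convert follow-up times in days to the package's month unit."""
    import numpy as np

    return np.asarray(days, dtype=float) / DAYS_PER_MONTH
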