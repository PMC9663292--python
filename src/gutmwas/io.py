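"""Reading and writing abundance tables and metadata.

Tables on disk follow the merged-profiler convention: features as rows,
samples as columns, a header row of sample ids. In memory all tables are
oriented samples x features; orientation is handled only here.

Two dialects are supported: ``plain-matrix`` (first column ``feature``) and
``metaphlan-merged`` (first column ``clade_name`` holding pipe-separated
taxonomy strings with rank prefixes ``k__ ... s__``; reading requires a rank
selection when ranks are mixed, and strips the clade prefix to the requested
rank's name).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from gutmwas.exceptions import FormatError

__all__ = ["read_abundance_table", "write_abundance_table", "read_metadata", "write_metadata"]

_RANK_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}


def write_abundance_table(table: pd.DataFrame, path, dialect: str = "plain-matrix") -> None:
    """Write a samples x features table as features-as-rows TSV."""
    out = table.T
    out.index.name = "clade_name" if dialect == "metaphlan-merged" else "feature"
    out.to_csv(path, sep="\t")


def read_abundance_table(
    path,
    dialect: str = "plain-matrix",
    rank: str | None = None,
    validate_relative: bool = False,
) -> pd.DataFrame:
    """Read a features x samples TSV into a samples x features DataFrame.

    With ``validate_relative`` the per-sample sums must be 1 or 100 within
    1e-6 (tables summing to 100 are rescaled to fractions).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    expected_first = "clade_name" if dialect == "metaphlan-merged" else "feature"
    if not header or header[0] != expected_first:
        raise FormatError(
            f"{path.name} line 1: expected first header field {expected_first!r}, got {header[0] if header else ''!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    if dialect == "metaphlan-merged":
        last = df.index.map(lambda s: str(s).split("|")[-1])
        prefixes = {str(name)[:3] for name in last}
        if rank is None:
            if len(prefixes) > 1:
                raise FormatError("table mixes taxonomic ranks; specify rank=")
        else:
            if rank not in _RANK_PREFIX:
                raise ValueError(f"unknown rank {rank!r}")
            keep = last.str.startswith(_RANK_PREFIX[rank])
            df = df.loc[keep]
            df.index = last[keep].str[3:]
    table = df.T  # samples x features
    vals = table.to_numpy(float)
    if (vals < 0).any():
        raise FormatError(f"{path.name}: negative abundance values")
    if validate_relative:
        sums = vals.sum(axis=1)
        if abs(sums - 100.0).max() < 1e-4:
            table = table / 100.0
        elif abs(sums - 1.0).max() > 1e-6:
            raise FormatError(f"{path.name}: relative abundances do not sum to 1 (or 100) per sample")
    return table


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample").to_csv(path, sep="\t")
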