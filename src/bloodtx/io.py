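"""Readers and writers for the tab-delimited formats the pipeline touches.

All files are tab-delimited UTF-8 with '.' decimal separators.  For the
expression matrix the first column holds probe ids and the header row
holds sample ids (the first header cell is ignored).  Detection flags
travel in a parallel file of single characters (P/M/A) with identical
labels.  Outputs written by :func:`write_table` carry a single header
comment line recording the package version and, when available, a
configuration hash, so every result file is self-describing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import ExpressionMatrix, GeneSet, ProbeAnnotation, SampleTable


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")


def read_expression_matrix(path, flag_path=None) -> ExpressionMatrix:
    """Read a raw probe x sample intensity matrix (stage ``raw``).

    Parameters
    ----------
    path
        Tab-delimited file; first column probe ids, header row sample ids.
    flag_path
        Optional parallel file of P/M/A detection calls.

    Raises
    ------
    ValueError
        On duplicate probe/sample ids (naming the duplicates) or
        non-numeric cells (naming row and column).
    """
    raw = _read_tsv(path)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(values.isna().to_numpy() & raw.notna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric cell at probe {raw.index[i]!r}, sample "
            f"{raw.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    if values.isna().to_numpy().any():
        i, j = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at probe {values.index[i]!r}, sample {values.columns[j]!r}"
        )
    flags = None
    if flag_path is not None:
        flags = _read_tsv(flag_path)
        flags = flags.reindex(index=values.index, columns=values.columns)
        if flags.isna().to_numpy().any():
            raise ValueError("flag file does not cover every matrix cell")
    return ExpressionMatrix(values.astype(float), stage="raw", flags=flags)


def write_expression_matrix(matrix: ExpressionMatrix, path, flag_path=None,
                            config_hash: Optional[str] = None) -> None:
    write_table(matrix.values, path, index_label="probe_id", config_hash=config_hash)
    if flag_path is not None and matrix.flags is not None:
        write_table(matrix.flags, flag_path, index_label="probe_id",
                    config_hash=config_hash)


def read_sample_table(path) -> SampleTable:
    """Read and validate sample metadata (sample_id, group, pair_id[, age, sex])."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError("sample table missing column: sample_id")
    df = df.set_index("sample_id")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path,
                       config_hash: Optional[str] = None) -> None:
    write_table(samples.table, path, index_label="sample_id", config_hash=config_hash)


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "probe_id" not in df.columns:
        raise ValueError("annotation missing column: probe_id")
    return ProbeAnnotation(df.set_index("probe_id"))


def write_probe_annotation(annotation: ProbeAnnotation, path,
                           config_hash: Optional[str] = None) -> None:
    write_table(annotation.table, path, index_label="probe_id",
                config_hash=config_hash)


@dataclass(frozen=True)
class GeneListReport:
    """Line-count bookkeeping for a plain-text gene list."""

    n_lines: int
    n_unique: int

    def __str__(self) -> str:  # "3 lines, 2 unique"
        return f"{self.n_lines} lines, {self.n_unique} unique"


def read_gene_list(path, name: Optional[str] = None) -> tuple[GeneSet, GeneListReport]:
    """Read a one-symbol-per-line gene list; duplicates are collapsed.

    Returns the deduplicated :class:`GeneSet` together with a report
    carrying the original and deduplicated line counts.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"gene list {path} is empty")
    members = frozenset(lines)
    gs = GeneSet(name or Path(path).stem, f"gene list from {Path(path).name}", members)
    return gs, GeneListReport(n_lines=len(lines), n_unique=len(members))


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, members per line)."""
    sets = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
        name, desc, *members = fields
        members = [m.strip() for m in members if m.strip()]
        sets.append(GeneSet(name, desc, frozenset(members)))
    if not sets:
        raise ValueError(f"GMT file {path} is empty")
    return sets


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def write_table(df: pd.DataFrame, path, index_label: Optional[str] = None,
                config_hash: Optional[str] = None, index: bool = True) -> None:
    """Write a DataFrame as TSV with a provenance comment line on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tag = f"# bloodtx {__version__}"
    if config_hash:
        tag += f" config={config_hash}"
    with open(path, "w") as fh:
        fh.write(tag + "\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_table(path, index_col=0) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping (for output provenance)."""
    import yaml

    text = yaml.safe_dump(obj, sort_keys=True, default_flow_style=False)
    return hashlib.sha256(text.encode()).hexdigest()[:10]
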