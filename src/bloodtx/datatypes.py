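"""Core containers shared by every pipeline stage.

The pipeline operates on a probe-by-sample expression matrix that moves
through a fixed sequence of processing stages (``raw`` intensities ->
``log2`` -> per-sample percentile ``shifted`` -> per-probe median
``baselined``).  The containers here are thin, validated wrappers around
:class:`pandas.DataFrame` so that downstream code can rely on unique
identifiers, consistent shapes and an explicit record of which stage a
matrix is in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

STAGES = ("raw", "log2", "shifted", "baselined")

#: Detection-call characters: present / marginal / absent.
FLAG_CHARS = frozenset({"P", "M", "A"})

GROUPS = ("case", "control")


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dups = sorted(labels[labels.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what} ids: {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values plus optional detection flags.

    Parameters
    ----------
    values
        DataFrame with probe ids as the index and sample ids as columns.
    stage
        One of :data:`STAGES`; records which transformations have been
        applied.  Values must be finite from ``log2`` onward.
    flags
        Optional DataFrame of single-character detection calls
        (P/M/A), same shape and labels as ``values``.
    """

    values: pd.DataFrame
    stage: str = "raw"
    flags: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TypeError("expression values must be numeric")
        if self.stage != "raw" and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at probe {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r} (stage={self.stage})"
            )
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise ValueError("flags shape does not match values shape")
            if not (
                self.flags.index.equals(self.values.index)
                and self.flags.columns.equals(self.values.columns)
            ):
                raise ValueError("flags labels do not match values labels")
            chars = set(np.unique(self.flags.to_numpy().astype(str)))
            unknown = chars - FLAG_CHARS
            if unknown:
                raise ValueError(f"unknown flag characters: {sorted(unknown)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``probe_ids`` (order as given)."""
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        flags = self.flags.loc[list(probe_ids)] if self.flags is not None else None
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.stage, flags)

    def with_values(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """New matrix with replaced values/stage, carrying flags along."""
        flags = self.flags
        if flags is not None and not flags.index.equals(values.index):
            flags = flags.loc[values.index]
        return ExpressionMatrix(values, stage, flags)


@dataclass
class SampleTable:
    """Sample metadata for a pairwise-matched case-control design.

    Wraps a DataFrame indexed by sample id with columns ``group``
    (case/control), ``pair_id`` and optionally ``age`` and ``sex``.
    Each pair id must link exactly one case to one control, which also
    forces the two group sizes to be equal.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "pair_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "sample")
        bad_groups = set(self.table["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
        for pair_id, sub in self.table.groupby("pair_id"):
            groups = sorted(sub["group"].tolist())
            if groups != ["case", "control"]:
                raise ValueError(
                    f"pair {pair_id!r} must contain exactly one case and one "
                    f"control, got {groups}"
                )
        if "sex" in self.table.columns:
            bad_sex = set(self.table["sex"].dropna()) - {"F", "M"}
            if bad_sex:
                raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def case_ids(self) -> list:
        return self.table.index[self.table["group"] == "case"].tolist()

    @property
    def control_ids(self) -> list:
        return self.table.index[self.table["group"] == "control"].tolist()

    @property
    def n_case(self) -> int:
        return int((self.table["group"] == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.table["group"] == "control").sum())

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """(case_id, control_id) tuples, ordered by pair id."""
        out = []
        for pair_id, sub in sorted(self.table.groupby("pair_id"), key=lambda kv: str(kv[0])):
            case = sub.index[sub["group"] == "case"][0]
            ctrl = sub.index[sub["group"] == "control"][0]
            out.append((case, ctrl))
        return out

    def group_mask(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Boolean array over ``sample_ids``: True where the sample is a case."""
        g = self.table["group"]
        return np.array([g[s] == "case" for s in sample_ids])


@dataclass
class ProbeAnnotation:
    """Probe id -> gene symbol / Entrez id mapping.

    A probe may lack a gene symbol (empty/NaN); such probes are kept in
    probe-level analyses but excluded from symbol-keyed output.
    """

    table: pd.DataFrame  # index: probe_id; columns: gene_symbol, entrez_id

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe")
        for col in ("gene_symbol", "entrez_id"):
            if col not in self.table.columns:
                self.table[col] = pd.NA

    def symbol_of(self, probe_id: str) -> Optional[str]:
        if probe_id not in self.table.index:
            return None
        sym = self.table.at[probe_id, "gene_symbol"]
        if pd.isna(sym) or sym == "":
            return None
        return str(sym)

    def symbols(self, probe_ids: Iterable[str]) -> pd.Series:
        """Gene symbols for ``probe_ids`` (NaN where absent)."""
        s = self.table["gene_symbol"].reindex(list(probe_ids))
        return s.replace("", pd.NA)

    def probes_for_symbols(self, symbols: Iterable[str]) -> list:
        """All probe ids whose symbol matches any of ``symbols`` (case-insensitive)."""
        wanted = {str(s).strip().upper() for s in symbols}
        sym = self.table["gene_symbol"].astype("string").str.strip().str.upper()
        return self.table.index[sym.isin(wanted)].tolist()


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (candidate list or pathway set)."""

    name: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members
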