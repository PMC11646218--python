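"""Pairwise-comparison table ingest and clade summary statistics.

The table-ingest mode works from a supplementary-style spreadsheet of
pairwise superposition results (per pair: RMSD, number of superimposed
residues, SAS, 1−Qscore) rather than from raw structures, so printed
summary statistics and clade-recovery checks can be reproduced without
re-running any structural alignment.

Clade means are computed over *within-clade* pairs (both endpoints in the
clade).  When a tree is checked for clade recovery, a clade counts as
recovered exactly when its label set forms a bipartition of the unrooted
tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from foldphylo.disttree import PhyloTree
from foldphylo.metrics import DistanceMatrix

__all__ = [
    "PairwiseTable",
    "CladeMap",
    "SchemaError",
    "EmptyScopeError",
    "load_table",
    "table_from_dataframe",
    "load_clade_map",
    "summarize",
    "matrix_from_table",
    "clades_recovered",
]

logger = logging.getLogger(__name__)

SAS_CONSISTENCY_TOL = 0.005

_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "id_a": ("id_a", "ida", "id1", "structure_a", "structure1", "query", "a"),
    "id_b": ("id_b", "idb", "id2", "structure_b", "structure2", "target", "b"),
    "rmsd": ("rmsd", "rmsd_a", "rmsd(a)", "rms"),
    "n_aligned": (
        "n_aligned", "naligned", "nalign", "n_sup", "nsup", "nres",
        "superimposed_residues", "number_of_superimposed_residues", "n_res",
    ),
    "sas": ("sas",),
    "one_minus_q": ("one_minus_q", "1-q", "1_q", "1-qscore", "1_qscore", "oneminusq"),
    "n_a": ("n_a", "na", "len_a", "length_a"),
    "n_b": ("n_b", "nb", "len_b", "length_b"),
}


class SchemaError(ValueError):
    """Mandatory columns missing from a pairwise table."""


class EmptyScopeError(ValueError):
    """A summary scope selected zero rows."""


@dataclass
class PairwiseTable:
    """Validated pairwise-comparison rows plus consistency flags.

    ``flags`` lists (row_index, message) for rows whose SAS disagrees with
    RMSD·100/Nsup beyond the tolerance; flagged rows are kept, not dropped.
    """

    df: pd.DataFrame
    flags: list[tuple[int, str]] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.df["id_a"]) | set(self.df["id_b"]))

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def is_complete(self) -> bool:
        L = len(self.labels)
        return self.n_rows == L * (L - 1) // 2


@dataclass
class CladeMap:
    """Label -> clade assignment plus optional taxon domain per label."""

    clade: dict[str, int | str]
    taxon_domain: dict[str, str] = field(default_factory=dict)

    def members(self, clade_id) -> set[str]:
        return {l for l, c in self.clade.items() if c == clade_id}

    def clade_ids(self) -> list:
        ids = {c for c in self.clade.values() if c != "unassigned"}
        return sorted(ids, key=str)

    def check_covers(self, labels) -> None:
        missing = sorted(set(labels) - set(self.clade))
        if missing:
            raise ValueError(f"labels not mapped to a clade: {missing}")


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    def norm(c: str) -> str:
        return str(c).strip().lower().replace(" ", "_").replace("-", "_")

    renames = {}
    for col in df.columns:
        n = norm(col)
        for canon, synonyms in _COLUMN_SYNONYMS.items():
            if n in tuple(norm(s) for s in synonyms):
                renames[col] = canon
                break
    return df.rename(columns=renames)


def table_from_dataframe(df: pd.DataFrame) -> PairwiseTable:
    """Validate a pairwise dataframe into a :class:`PairwiseTable`.

    Raises :class:`SchemaError` when mandatory columns are missing; raises
    ``ValueError`` on self-pairs or repeated unordered pairs.  Rows whose
    SAS column disagrees with RMSD·100/Nsup by more than 0.005 are flagged
    (and logged) but retained.
    """
    df = _canonicalize_columns(df.copy())
    mandatory = ["id_a", "id_b", "rmsd", "n_aligned", "sas", "one_minus_q"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    df["id_a"] = df["id_a"].astype(str)
    df["id_b"] = df["id_b"].astype(str)
    for col in ("rmsd", "sas", "one_minus_q"):
        df[col] = pd.to_numeric(df[col])
    df["n_aligned"] = pd.to_numeric(df["n_aligned"]).astype(int)

    if (df["id_a"] == df["id_b"]).any():
        bad = df.loc[df["id_a"] == df["id_b"], "id_a"].iloc[0]
        raise ValueError(f"self-pair in table: {bad!r}")
    keys = [frozenset((a, b)) for a, b in zip(df["id_a"], df["id_b"])]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValueError(f"pair listed more than once: {sorted(dup)}")

    flags: list[tuple[int, str]] = []
    ok = df["n_aligned"] >= 1
    expected = np.where(ok, df["rmsd"] * 100.0 / df["n_aligned"].where(ok, 1), np.nan)
    bad = ok & (np.abs(df["sas"] - expected) > SAS_CONSISTENCY_TOL)
    for i in df.index[bad]:
        msg = (
            f"row {i} ({df.at[i, 'id_a']},{df.at[i, 'id_b']}): sas={df.at[i, 'sas']:.4f} "
            f"but rmsd*100/n_aligned={expected[df.index.get_loc(i)]:.4f}"
        )
        flags.append((int(i), msg))
        logger.warning("inconsistent SAS kept: %s", msg)
    return PairwiseTable(df=df.reset_index(drop=True), flags=flags)


def load_table(path: str | Path, dialect: str = "auto") -> PairwiseTable:
    """Load a pairwise-comparison table from TSV, CSV or xlsx.

    ``dialect`` may be ``"auto"`` (from extension), ``"tsv"``, ``"csv"`` or
    ``"xlsx"``.  Column headers are matched case-insensitively against
    common synonyms (e.g. ``Nsup``, ``1-Qscore``).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
                   ".xlsx": "xlsx", ".xls": "xlsx"}.get(path.suffix.lower(), "tsv")
    if dialect == "xlsx":
        df = pd.read_excel(path)
    elif dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return table_from_dataframe(df)


def load_clade_map(path: str | Path) -> CladeMap:
    """Read a clade-membership TSV with columns id, clade[, taxon_domain]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "id" not in df.columns or "clade" not in df.columns:
        raise SchemaError("clade map needs columns 'id' and 'clade'")
    clade: dict[str, int | str] = {}
    for _, row in df.iterrows():
        val = row["clade"]
        if val is None or str(val).strip().lower() in ("", "unassigned", "nan"):
            clade[row["id"]] = "unassigned"
        else:
            try:
                clade[row["id"]] = int(val)
            except ValueError:
                clade[row["id"]] = str(val)
    domains = {}
    if "taxon_domain" in df.columns:
        domains = {r["id"]: r["taxon_domain"] for _, r in df.iterrows()
                   if isinstance(r["taxon_domain"], str)}
    return CladeMap(clade=clade, taxon_domain=domains)


def summarize(
    table: PairwiseTable,
    clades: CladeMap | dict[str, int] | None = None,
    scope: str | int = "all",
) -> dict[str, float]:
    """Arithmetic means of Nsup, SAS and 1−Q over the selected rows.

    ``scope="all"`` uses every row; a clade id restricts to rows whose
    *both* endpoints belong to that clade.  Returns a record with
    ``mean_n_aligned``, ``mean_sas``, ``mean_one_minus_q`` and ``n_pairs``.
    """
    df = table.df
    if scope == "all":
        sel = df
    else:
        if clades is None:
            raise ValueError("clade scope requires a clade map")
        cl = clades.clade if isinstance(clades, CladeMap) else clades
        members = {l for l, c in cl.items() if c == scope}
        sel = df[df["id_a"].isin(members) & df["id_b"].isin(members)]
    if len(sel) == 0:
        raise EmptyScopeError(f"no rows in scope {scope!r}")
    return {
        "mean_n_aligned": float(sel["n_aligned"].mean()),
        "mean_sas": float(sel["sas"].mean()),
        "mean_one_minus_q": float(sel["one_minus_q"].mean()),
        "n_pairs": int(len(sel)),
    }


def matrix_from_table(table: PairwiseTable, metric: str = "SAS") -> DistanceMatrix:
    """Distance matrix straight from the table's sas / one_minus_q column.

    The table must cover every unordered pair of its label universe.
    """
    if not table.is_complete():
        L = len(table.labels)
        raise ValueError(
            f"table has {table.n_rows} rows but {L * (L - 1) // 2} pairs are "
            f"needed for {L} labels"
        )
    col = {"SAS": "sas", "1-Q": "one_minus_q"}.get(metric)
    if col is None:
        raise ValueError(f"unknown metric {metric!r}")
    labels = table.labels
    idx = {l: i for i, l in enumerate(labels)}
    D = np.zeros((len(labels), len(labels)))
    for a, b, v in zip(table.df["id_a"], table.df["id_b"], table.df[col]):
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = float(v)
    return DistanceMatrix(labels, D, metric_name=metric)


def clades_recovered(
    tree: PhyloTree, clades: CladeMap | dict[str, int]
) -> tuple[dict, int]:
    """Which clades appear as exact bipartitions of the tree.

    A clade is recovered when its full label set is one side of a split of
    the unrooted tree; singleton clades and clades comprising all leaves
    are trivially recovered.  Returns ``(per-clade bool dict, count)``.
    """
    cl = clades.clade if isinstance(clades, CladeMap) else clades
    leafset = set(tree.labels)
    mapped = {l for l in cl if cl[l] != "unassigned"}
    if not mapped <= leafset:
        raise ValueError(f"tree lacks mapped labels: {sorted(mapped - leafset)}")
    splits = tree.bipartitions(include_trivial=True)
    sides = set(splits) | {frozenset(leafset) - s for s in splits}
    ids = sorted({c for c in cl.values() if c != "unassigned"}, key=str)
    out = {}
    for cid in ids:
        members = frozenset(l for l, c in cl.items() if c == cid)
        if len(members) <= 1 or len(members) >= len(leafset) - 1:
            out[cid] = True
        else:
            out[cid] = members in sides
    return out, sum(out.values())
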