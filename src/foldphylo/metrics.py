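"""Structural distance metrics and labelled distance matrices.

Two normalised distances are computed from each pairwise superposition:

* SAS, the structural alignment score, ``RMSD * 100 / Nsup`` — RMSD
  normalised by the number of superimposed residues; lower means more
  similar; unbounded above.
* ``1 - Q``, where Q is the SSM-style Qscore
  ``Nsup^2 / ((1 + (RMSD/r0)^2) * n_a * n_b)`` — a similarity in (0, 1]
  rewarding long, low-RMSD alignments relative to both protein lengths.
  ``r0`` balances RMSD against alignment length and defaults to 3 Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from foldphylo.superpose import AlignmentResult

__all__ = [
    "DistanceMatrix",
    "sas",
    "qscore",
    "build_matrix",
    "UndefinedDistanceError",
    "IncompleteTableError",
    "write_phylip",
    "read_phylip",
    "write_tsv",
]

R0_DEFAULT = 3.0


class UndefinedDistanceError(ValueError):
    """Distance requested for a pair with no superimposed residues."""


class IncompleteTableError(ValueError):
    """Pairwise results do not cover every unordered label pair exactly once."""


def sas(rmsd: float, n_aligned: int) -> float:
    """Structural alignment score: ``rmsd * 100 / n_aligned``."""
    if n_aligned < 1:
        raise UndefinedDistanceError("SAS undefined for n_aligned = 0")
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    return rmsd * 100.0 / n_aligned


def qscore(n_aligned: int, rmsd: float, n_a: int, n_b: int, r0: float = R0_DEFAULT) -> float:
    """SSM-style Qscore: ``Nsup^2 / ((1 + (rmsd/r0)^2) * n_a * n_b)``.

    Equals 1 for a full-length zero-RMSD superposition of equal-length
    structures and decreases with rmsd and with unaligned residues in
    either structure.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("n_a and n_b must be >= 1")
    if not 0 <= n_aligned <= min(n_a, n_b):
        raise ValueError("n_aligned must lie in [0, min(n_a, n_b)]")
    return n_aligned ** 2 / ((1.0 + (rmsd / r0) ** 2) * n_a * n_b)


@dataclass
class DistanceMatrix:
    """Symmetric labelled matrix of pairwise structural distances."""

    labels: list[str]
    d: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.d < 0):
            raise ValueError("distances must be >= 0")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)], self.metric_name)


def _pair_metric(
    rmsd: float,
    n_aligned: int,
    n_a: int,
    n_b: int,
    metric: str,
    r0: float,
) -> float | None:
    """Distance for one pair; ``None`` marks an undefined (no-match) SAS."""
    if metric == "SAS":
        if n_aligned == 0 or not math.isfinite(rmsd):
            return None
        return sas(rmsd, n_aligned)
    if metric == "1-Q":
        if n_aligned == 0 or not math.isfinite(rmsd):
            return 1.0
        return 1.0 - qscore(n_aligned, rmsd, n_a, n_b, r0=r0)
    raise ValueError(f"unknown metric {metric!r} (expected 'SAS' or '1-Q')")


def build_matrix(
    results: Iterable[AlignmentResult],
    metric: str = "SAS",
    r0: float = R0_DEFAULT,
    no_match_factor: float = 1.5,
) -> DistanceMatrix:
    """Assemble a symmetric distance matrix from pairwise alignment results.

    Every unordered label pair must appear exactly once (either direction);
    duplicates must agree within 1e-6.  Pairs with no structural match
    (``n_aligned = 0``) have their SAS imputed as ``no_match_factor`` times
    the largest observed SAS — downstream least-squares tree and network
    fitting require finite matrices — and 1−Q set to 1.

    Raises
    ------
    IncompleteTableError
        If any unordered pair is missing.
    """
    entries: dict[frozenset[str], float | None] = {}
    labels: list[str] = []
    seen = set()
    for r in results:
        key = frozenset((r.id_a, r.id_b))
        if len(key) != 2:
            raise ValueError(f"self-pair {r.id_a!r} in results")
        val = _pair_metric(r.rmsd, r.n_aligned, r.n_a, r.n_b, metric, r0)
        if key in entries:
            old = entries[key]
            both = old is not None and val is not None
            if (both and abs(old - val) > 1e-6) or (old is None) != (val is None):
                raise ValueError(f"conflicting duplicate for pair {sorted(key)}")
            continue
        entries[key] = val
        for lab in (r.id_a, r.id_b):
            if lab not in seen:
                seen.add(lab)
                labels.append(lab)

    n = len(labels)
    expected = {frozenset((a, b)) for i, a in enumerate(labels) for b in labels[i + 1 :]}
    missing = expected - set(entries)
    if missing:
        raise IncompleteTableError(
            f"missing pairs: {sorted(tuple(sorted(m)) for m in missing)[:10]}"
            + ("..." if len(missing) > 10 else "")
        )

    finite = [v for v in entries.values() if v is not None]
    impute = (max(finite) * no_match_factor) if finite else 1.0
    D = np.zeros((n, n))
    idx = {l: i for i, l in enumerate(labels)}
    for key, val in entries.items():
        a, b = tuple(key)
        v = impute if val is None else val
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = v
    return DistanceMatrix(labels, D, metric_name=metric)


# ---------------------------------------------------------------------------
# matrix serialisation


def write_phylip(dm: DistanceMatrix, path: str | Path, relaxed: bool = False) -> None:
    """Write a square PHYLIP distance matrix.

    Strict dialect: names padded/truncated to 10 characters, space-separated
    distances.  Relaxed dialect: full names, tab-separated.
    """
    lines = [f"{dm.n:5d}"]
    for i, name in enumerate(dm.labels):
        vals = " ".join(f"{v:.10g}" for v in dm.d[i])
        if relaxed:
            lines.append(f"{name}\t" + "\t".join(f"{v:.10g}" for v in dm.d[i]))
        else:
            lines.append(f"{name[:10]:<10s} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path, metric_name: str = "") -> DistanceMatrix:
    """Read a PHYLIP distance matrix (square or lower-triangular)."""
    text = Path(path).read_text().strip().splitlines()
    n = int(text[0].split()[0])
    rows = [line.split() for line in text[1 : n + 1]]
    labels = [r[0] for r in rows]
    D = np.zeros((n, n))
    lower = any(len(r) - 1 != n for r in rows)
    for i, r in enumerate(rows):
        vals = [float(x) for x in r[1:]]
        if lower:
            if len(vals) != i:
                raise ValueError(f"row {labels[i]}: expected {i} lower-triangle values")
            for j, v in enumerate(vals):
                D[i, j] = D[j, i] = v
        else:
            D[i, :] = vals
    if not lower:
        D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels, D, metric_name=metric_name)


def write_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a labelled TSV matrix (header row of labels)."""
    lines = ["\t".join(["id"] + dm.labels)]
    for i, name in enumerate(dm.labels):
        lines.append(name + "\t" + "\t".join(f"{v:.10g}" for v in dm.d[i]))
    Path(path).write_text("\n".join(lines) + "\n")
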