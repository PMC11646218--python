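"""Sequence-independent pairwise structural alignment of Cα traces.

The aligner is a CE-style fragment-seeded iterative superposition: gapless
fragment pairs that superpose well seed an initial rigid transform; from the
transformed coordinates a similarity matrix S(i,j) = 1/(1 + (d_ij/d0)^2) is
scored by global dynamic programming with a linear gap penalty; pairs closer
than a distance cutoff are kept and re-superposed (Kabsch), and the loop
repeats to convergence.  The best seed's converged result is returned.  The
procedure is fully deterministic — seeds are ranked by fragment RMSD and all
DP tie-breaks are fixed.

Output per pair is the superposition statistics the distance metrics need:
RMSD over the matched Cα pairs and the number of superimposed residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from foldphylo.structure_io import Structure

__all__ = ["AlignParams", "AlignmentResult", "kabsch", "align_structures"]


class InsufficientPointsError(ValueError):
    """Fewer than three point pairs given to the superposition."""


@dataclass(frozen=True)
class AlignParams:
    """Tunable parameters of the iterative aligner.

    fragment : gapless seed fragment length (residues)
    n_seeds : number of top-ranked seed fragments refined to convergence
    d0 : distance scale of the DP similarity S = 1/(1+(d/d0)^2), Å
    dcut : matched pairs farther apart than this after superposition are
        dropped before re-superposing, Å
    gap : linear gap penalty per unaligned residue in the DP
    tol_rmsd : convergence threshold on the change in RMSD, Å
    max_iter : iteration cap per seed
    min_core : minimum n_aligned for a seed to count as an alignment
    """

    fragment: int = 8
    n_seeds: int = 20
    d0: float = 3.0
    dcut: float = 5.0
    gap: float = 0.5
    tol_rmsd: float = 1e-4
    max_iter: int = 50
    min_core: int = 12


@dataclass
class AlignmentResult:
    """Outcome of one pairwise superposition.

    ``pairs`` holds (index_in_a, index_in_b) correspondences, strictly
    increasing in both coordinates.  ``n_aligned`` is the number of
    superimposed residues; ``rmsd`` the Cα RMSD over them after optimal
    superposition (``nan`` when no alignment was found).  ``rotation`` /
    ``translation`` map b onto a: b' = b @ rotation.T + translation.
    """

    id_a: str
    id_b: str
    pairs: list[tuple[int, int]]
    rmsd: float
    n_a: int
    n_b: int
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    degenerate: bool = False

    @property
    def n_aligned(self) -> int:
        return len(self.pairs)

    @property
    def aligned(self) -> bool:
        return self.n_aligned > 0


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of Q onto P.

    Returns ``(rotation, translation, rmsd)`` minimizing the RMSD of
    ``Q @ rotation.T + translation`` to P over all rigid motions.  The
    reflection branch of the SVD solution is rejected by correcting the sign
    of the smallest singular vector, so the rotation always has determinant
    +1.  Degenerate (rank-deficient, e.g. collinear) inputs still return the
    optimizer of the proper-rotation problem.

    Raises
    ------
    InsufficientPointsError
        If fewer than three point pairs are supplied.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (k, 3) arrays")
    k = P.shape[0]
    if k < 3:
        raise InsufficientPointsError(f"need ≥ 3 point pairs, got {k}")
    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    P0 = P - cP
    Q0 = Q - cQ
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    ssd = float((P0 ** 2).sum() + (Q0 ** 2).sum() - 2.0 * (S[0] + S[1] + d * S[2]))
    rmsd = float(np.sqrt(max(ssd, 0.0) / k))
    t = cP - R @ cQ
    return R, t, rmsd


def _fragment_seed_rmsds(A: np.ndarray, B: np.ndarray, f: int) -> np.ndarray:
    """RMSD of every gapless fragment pair, batched.

    Returns an (n_a-f+1, n_b-f+1) array of superposition RMSDs of length-f
    windows, computed via the closed-form Kabsch objective on batched 3x3
    SVDs.
    """
    wa = np.lib.stride_tricks.sliding_window_view(A, (f, 3)).reshape(-1, f, 3)
    wb = np.lib.stride_tricks.sliding_window_view(B, (f, 3)).reshape(-1, f, 3)
    wa = wa - wa.mean(axis=1, keepdims=True)
    wb = wb - wb.mean(axis=1, keepdims=True)
    sa = (wa ** 2).sum(axis=(1, 2))
    sb = (wb ** 2).sum(axis=(1, 2))
    # H[i,j] = wb_j^T wa_i  (3x3 per pair)
    H = np.einsum("ifk,jfl->ijlk", wa, wb)  # (na', nb', 3, 3) = wb^T wa
    S = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    trace = S[..., 0] + S[..., 1] - np.where(det < 0, 2.0 * S[..., 2], 0.0) + S[..., 2]
    ssd = sa[:, None] + sb[None, :] - 2.0 * trace
    return np.sqrt(np.maximum(ssd, 0.0) / f)


def _dp_fill(S: np.ndarray, gap: float) -> np.ndarray:
    """Needleman–Wunsch traceback matrix for similarity S with linear gaps.

    Tie-breaking is deterministic: match (diagonal) preferred, then gap in
    the second structure (vertical move), then gap in the first.
    Moves: 0 diagonal, 1 up (gap in b), 2 left (gap in a).
    """
    na, nb = S.shape
    move = np.zeros((na + 1, nb + 1), dtype=np.int8)
    move[0, 1:] = 2
    move[1:, 0] = 1
    prev = -gap * np.arange(nb + 1)
    cur = np.empty(nb + 1)
    for i in range(1, na + 1):
        cur[0] = -gap * i
        Si = S[i - 1]
        mi = move[i]
        for j in range(1, nb + 1):
            d = prev[j - 1] + Si[j - 1]
            u = prev[j] - gap
            l = cur[j - 1] - gap
            if d >= u and d >= l:
                cur[j] = d
                mi[j] = 0
            elif u >= l:
                cur[j] = u
                mi[j] = 1
            else:
                cur[j] = l
                mi[j] = 2
        prev, cur = cur, prev
    return move


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _dp_fill = njit(cache=True)(_dp_fill)
except ImportError:  # pragma: no cover
    pass


def _dp_align(S: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Global alignment maximizing sum of S over matches minus gap per skip."""
    move = _dp_fill(np.ascontiguousarray(S, dtype=np.float64), gap)
    pairs: list[tuple[int, int]] = []
    i, j = S.shape
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 0:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif m == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _refine_from_transform(
    A: np.ndarray, B: np.ndarray, R: np.ndarray, t: np.ndarray, params: AlignParams
) -> tuple[list[tuple[int, int]], float, np.ndarray, np.ndarray]:
    """Iterate DP correspondence + Kabsch re-superposition to convergence."""
    prev_rmsd = np.inf
    prev_n = -1
    pairs: list[tuple[int, int]] = []
    rmsd = np.nan
    for _ in range(params.max_iter):
        Bt = B @ R.T + t
        diff = A[:, None, :] - Bt[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        S = 1.0 / (1.0 + (d / params.d0) ** 2)
        raw = _dp_align(S, params.gap)
        pairs = [(i, j) for i, j in raw if d[i, j] <= params.dcut]
        if len(pairs) < 3:
            return [], np.nan, R, t
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        R, t, rmsd = kabsch(A[ia], B[ib])
        if len(pairs) == prev_n and abs(rmsd - prev_rmsd) < params.tol_rmsd:
            break
        prev_n = len(pairs)
        prev_rmsd = rmsd
    return pairs, rmsd, R, t


def align_structures(
    a: Structure, b: Structure, params: AlignParams | None = None
) -> AlignmentResult:
    """Align two Cα traces and return superposition statistics.

    Seeds are the ``n_seeds`` gapless fragment pairs of length ``fragment``
    with the lowest superposition RMSD; each is refined by alternating
    dynamic-programming correspondence and Kabsch re-superposition.  The
    converged result with the most superimposed residues (ties: lower RMSD,
    then seed rank) is returned.  If no seed reaches ``min_core`` matched
    pairs, a no-alignment result with ``n_aligned = 0`` and ``rmsd = nan``
    is returned rather than raising.
    """
    params = params or AlignParams()
    # canonical input order (by id) makes the result exactly symmetric:
    # aligning (A, B) and (B, A) returns identical n_aligned and rmsd
    if b.id < a.id:
        r = align_structures(b, a, params)
        return AlignmentResult(
            id_a=a.id,
            id_b=b.id,
            pairs=[(j, i) for i, j in r.pairs],
            rmsd=r.rmsd,
            n_a=r.n_b,
            n_b=r.n_a,
            rotation=r.rotation.T,
            translation=-(r.rotation.T @ r.translation),
            degenerate=r.degenerate,
        )
    A = np.asarray(a.coords, dtype=float)
    B = np.asarray(b.coords, dtype=float)
    f = min(params.fragment, len(A), len(B))
    if f < 3:
        return AlignmentResult(a.id, b.id, [], np.nan, len(A), len(B))

    frag_rmsd = _fragment_seed_rmsds(A, B, f)
    flat = frag_rmsd.ravel()
    order = np.argsort(flat, kind="stable")[: params.n_seeds]
    nb_f = frag_rmsd.shape[1]

    best: tuple[int, float, list[tuple[int, int]], np.ndarray, np.ndarray] | None = None
    for rank, idx in enumerate(order):
        i0, j0 = divmod(int(idx), nb_f)
        R, t, _ = kabsch(A[i0 : i0 + f], B[j0 : j0 + f])
        pairs, rmsd, R, t = _refine_from_transform(A, B, R, t, params)
        if len(pairs) < params.min_core:
            continue
        if best is None or (len(pairs), -rmsd) > (best[0], -best[1]):
            best = (len(pairs), rmsd, pairs, R, t)

    if best is None:
        return AlignmentResult(a.id, b.id, [], np.nan, len(A), len(B))
    n_al, rmsd, pairs, R, t = best
    return AlignmentResult(
        id_a=a.id,
        id_b=b.id,
        pairs=pairs,
        rmsd=rmsd,
        n_a=len(A),
        n_b=len(B),
        rotation=R,
        translation=t,
    )
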