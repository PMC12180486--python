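"""Pairwise protein alignment with identity/coverage statistics.

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment under an
affine gap model (Gotoh three-state recurrence).  A gap of length L costs
``gap_open + (L - 1) * gap_extend``; setting ``gap_extend == gap_open``
recovers the linear gap model.  Traceback is fully deterministic with the
tie order diagonal > up > left so that repeated runs produce byte-identical
alignments.

The default scoring scheme is BLOSUM62 with gap open -11 / extend -1,
mirroring common protein-search defaults; simple match/mismatch schemes are
available for controlled tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}

NEG_INF = np.int64(-(2**40))


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 restricted to the 20 standard residues plus X."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.int64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = int(m[a, b])
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both non-positive)."""

    substitution: np.ndarray  # |alphabet| x |alphabet| integer matrix
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution, dtype=np.int64)
        if sub.ndim != 2 or sub.shape[0] != sub.shape[1]:
            raise ValueError("substitution matrix must be square")
        if not np.array_equal(sub, sub.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if self.gap_extend < self.gap_open:
            raise ValueError("gap_extend must be >= gap_open (affine model)")
        object.__setattr__(self, "substitution", sub)

    @classmethod
    def blosum62(cls, gap_open: int = -11, gap_extend: int = -1) -> "ScoringScheme":
        return cls(_blosum62_matrix(), gap_open, gap_extend)

    @classmethod
    def simple(cls, match: int = 1, mismatch: int = -1, gap: int = -1,
               gap_extend: Optional[int] = None) -> "ScoringScheme":
        """Match/mismatch scheme; linear gaps unless gap_extend is given."""
        n = len(AA_ALPHABET)
        sub = np.full((n, n), mismatch, dtype=np.int64)
        np.fill_diagonal(sub, match)
        ge = gap if gap_extend is None else gap_extend
        return cls(sub, gap, ge)


DEFAULT_SCHEME: Optional[ScoringScheme] = None


def default_scheme() -> ScoringScheme:
    global DEFAULT_SCHEME
    if DEFAULT_SCHEME is None:
        DEFAULT_SCHEME = ScoringScheme.blosum62()
    return DEFAULT_SCHEME


def encode_sequence(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in sequence") from None


@dataclass
class AlignmentResult:
    """One pairwise alignment with its summary statistics.

    ``identity`` uses total alignment columns (gaps included) as the
    denominator in global mode, and the local alignment's own columns in
    local mode.  Coverage is the number of residues of each side placed
    opposite a residue (global) or inside the aligned span (local), divided
    by that side's full length.
    """

    aligned_query: str
    aligned_subject: str
    score: int
    identity: float
    query_coverage: float
    subject_coverage: float
    mode: str  # "global" | "local"
    query_start: int = 0  # 0-based start of aligned span (local mode)
    subject_start: int = 0

    def as_text(self) -> str:
        mid = "".join(
            "|" if a == b and a != "-" else " "
            for a, b in zip(self.aligned_query, self.aligned_subject)
        )
        return f"{self.aligned_query}\n{mid}\n{self.aligned_subject}"


# traceback state codes
_M, _X, _Y, _STOP = 0, 1, 2, 3


@njit(cache=True)
def _gotoh_global(a, b, sub, go, ge):  # pragma: no cover - numba kernel
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)  # gap in b (up)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)  # gap in a (left)
    # tb[state, i, j] = predecessor state
    tb = np.full((3, n + 1, m + 1), _STOP, dtype=np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
        tb[_X, i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
        tb[_Y, 0, j] = _M if j == 1 else _Y
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            # diagonal: tie order M > X > Y
            best = M[i - 1, j - 1]
            src = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = _Y
            M[i, j] = best + s
            tb[_M, i, j] = src
            # up (consume a_i, gap in b): open from M/Y, extend from X
            best = M[i - 1, j] + go
            src = _M
            if X[i - 1, j] + ge > best:
                best = X[i - 1, j] + ge
                src = _X
            if Y[i - 1, j] + go > best:
                best = Y[i - 1, j] + go
                src = _Y
            X[i, j] = best
            tb[_X, i, j] = src
            # left (consume b_j, gap in a)
            best = M[i, j - 1] + go
            src = _M
            if X[i, j - 1] + go > best:
                best = X[i, j - 1] + go
                src = _X
            if Y[i, j - 1] + ge > best:
                best = Y[i, j - 1] + ge
                src = _Y
            Y[i, j] = best
            tb[_Y, i, j] = src
    score = M[n, m]
    state = _M
    if X[n, m] > score:
        score = X[n, m]
        state = _X
    if Y[n, m] > score:
        score = Y[n, m]
        state = _Y
    return score, state, tb


@njit(cache=True)
def _gotoh_local(a, b, sub, go, ge):  # pragma: no cover - numba kernel
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1), dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    tb = np.full((3, n + 1, m + 1), _STOP, dtype=np.int8)
    best_score = np.int64(0)
    best_i, best_j = 0, 0
    for i in range(1, n + 1):  # noqa: E501 (kernel kept flat for numba)
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            src = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = _Y
            v = best + s
            if v < 0:
                v = 0
                src = _STOP
            M[i, j] = v
            tb[_M, i, j] = src
            best = M[i - 1, j] + go
            src = _M
            if X[i - 1, j] + ge > best:
                best = X[i - 1, j] + ge
                src = _X
            if Y[i - 1, j] + go > best:
                best = Y[i - 1, j] + go
                src = _Y
            X[i, j] = best
            tb[_X, i, j] = src
            best = M[i, j - 1] + go
            src = _M
            if X[i, j - 1] + go > best:
                best = X[i, j - 1] + go
                src = _X
            if Y[i, j - 1] + ge > best:
                best = Y[i, j - 1] + ge
                src = _Y
            Y[i, j] = best
            tb[_Y, i, j] = src
            if M[i, j] > best_score:
                best_score = M[i, j]
                best_i, best_j = i, j
    return best_score, best_i, best_j, M, tb


def _traceback_global(a: str, b: str, tb: np.ndarray,
                      state: int) -> tuple[str, str]:
    i, j = len(a), len(b)
    qa: list[str] = []
    qb: list[str] = []
    while i > 0 or j > 0:
        prev = tb[state, i, j]
        if state == _M:
            qa.append(a[i - 1])
            qb.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == _X:
            qa.append(a[i - 1])
            qb.append("-")
            i -= 1
        else:  # _Y
            qa.append("-")
            qb.append(b[j - 1])
            j -= 1
        state = int(prev)
    return "".join(reversed(qa)), "".join(reversed(qb))


def _traceback_local(a: str, b: str, tb: np.ndarray, M: np.ndarray,
                     bi: int, bj: int) -> tuple[str, str, int, int]:
    i, j, state = bi, bj, _M
    qa: list[str] = []
    qb: list[str] = []
    while True:
        if state == _M:
            if M[i, j] == 0:
                break
            qa.append(a[i - 1])
            qb.append(b[j - 1])
            prev = tb[_M, i, j]
            i -= 1
            j -= 1
        elif state == _X:
            qa.append(a[i - 1])
            qb.append("-")
            prev = tb[_X, i, j]
            i -= 1
        elif state == _Y:
            qa.append("-")
            qb.append(b[j - 1])
            prev = tb[_Y, i, j]
            j -= 1
        else:
            break
        state = int(prev)
    return "".join(reversed(qa)), "".join(reversed(qb)), i, j


def _identity(qa: str, qb: str, denominator: str = "columns") -> float:
    if not qa:
        return 0.0
    ident = sum(1 for x, y in zip(qa, qb) if x == y and x != "-")
    if denominator == "columns":
        return ident / len(qa)
    if denominator == "matched":
        matched = sum(1 for x, y in zip(qa, qb) if x != "-" and y != "-")
        return ident / matched if matched else 0.0
    raise ValueError(f"unknown identity denominator {denominator!r}")


def needleman_wunsch(a: str, b: str, scoring: Optional[ScoringScheme] = None,
                     identity_denominator: str = "columns") -> AlignmentResult:
    """Optimal global alignment (affine gaps, deterministic traceback)."""
    scoring = scoring or default_scheme()
    a, b = a.upper(), b.upper()
    if not a or not b:
        # degenerate: align everything against gaps at pure gap cost
        n = max(len(a), len(b))
        score = 0 if n == 0 else scoring.gap_open + (n - 1) * scoring.gap_extend
        qa = a if a else "-" * len(b)
        qb = b if b else "-" * len(a)
        return AlignmentResult(qa, qb, int(score), 0.0,
                               0.0, 0.0, "global")
    ea, eb = encode_sequence(a), encode_sequence(b)
    score, state, tb = _gotoh_global(ea, eb, scoring.substitution,
                                     scoring.gap_open, scoring.gap_extend)
    qa, qb = _traceback_global(a, b, tb, int(state))
    both = sum(1 for x, y in zip(qa, qb) if x != "-" and y != "-")
    return AlignmentResult(
        aligned_query=qa,
        aligned_subject=qb,
        score=int(score),
        identity=_identity(qa, qb, identity_denominator),
        query_coverage=both / len(a),
        subject_coverage=both / len(b),
        mode="global",
    )


def smith_waterman(a: str, b: str,
                   scoring: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimal local alignment; empty alignment when nothing scores > 0.

    Coverage is aligned-span length over full sequence length, per side.
    """
    scoring = scoring or default_scheme()
    a, b = a.upper(), b.upper()
    if not a or not b:
        return AlignmentResult("", "", 0, 0.0, 0.0, 0.0, "local")
    ea, eb = encode_sequence(a), encode_sequence(b)
    score, bi, bj, M, tb = _gotoh_local(ea, eb, scoring.substitution,
                                        scoring.gap_open, scoring.gap_extend)
    if score <= 0:
        return AlignmentResult("", "", 0, 0.0, 0.0, 0.0, "local")
    qa, qb, si, sj = _traceback_local(a, b, tb, M, int(bi), int(bj))
    span_a = len(qa) - qa.count("-")
    span_b = len(qb) - qb.count("-")
    return AlignmentResult(
        aligned_query=qa,
        aligned_subject=qb,
        score=int(score),
        identity=_identity(qa, qb),
        query_coverage=span_a / len(a),
        subject_coverage=span_b / len(b),
        mode="local",
        query_start=si,
        subject_start=sj,
    )


def is_homologous(a: str, b: str, id_thresh: float = 0.50,
                  cov_thresh: float = 0.50, mode: str = "local",
                  scoring: Optional[ScoringScheme] = None) -> bool:
    """Homology predicate: identity AND both coverages strictly above thresholds."""
    if not (0 <= id_thresh <= 1 and 0 <= cov_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if mode == "local":
        res = smith_waterman(a, b, scoring)
    elif mode == "global":
        res = needleman_wunsch(a, b, scoring)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (res.identity > id_thresh
            and res.query_coverage > cov_thresh
            and res.subject_coverage > cov_thresh)


def alignment_tsv_row(query_id: str, subject_id: str, res: AlignmentResult) -> str:
    return "\t".join([
        query_id, subject_id,
        f"{res.identity:.4f}", f"{res.query_coverage:.4f}",
        f"{res.subject_coverage:.4f}", str(res.score),
    ])
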