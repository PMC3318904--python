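"""Score-only Smith-Waterman local alignment with affine gaps.

The recurrence, with substitution score s(i, j) for query position i against
subject position j and gap penalties (open G, extend GE; a gap of length k
costs G + GE*k):

    E[i][j] = max(H[i][j-1] - (G+GE), E[i][j-1] - GE)      # gap in query
    F[i][j] = max(H[i-1][j] - (G+GE), F[i-1][j] - GE)      # gap in subject
    H[i][j] = max(0, H[i-1][j-1] + s(i,j), E[i][j], F[i][j])

and the alignment score is the maximum H over all cells.  Only scores are
computed (no traceback): the permutation-null pipeline consumes scores alone.

Two execution paths share this contract.  The default *inter-task* path runs
one task at a time to completion, row-major, with O(min-dim) memory; batches
iterate over tasks.  The *intra-task* path evaluates cells in anti-diagonal
(wavefront) order — all cells on one anti-diagonal are mutually independent —
and must produce identical scores; it exists to mirror cooperative-parallel
evaluation and is checked against the row-major path in tests.

An exhaustive enumerator over all gapped local alignments
(:func:`sw_score_exhaustive`) serves as an independent oracle for tiny
instances only; it is exponential and not part of the production path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from numba import njit

from .scoring import GapPenalties, MatrixError, QueryProfile, SubstitutionMatrix, build_local_profile
from .seq_io import Sequence

Scheme = Union[QueryProfile, SubstitutionMatrix]


@dataclass(frozen=True)
class AlignmentTask:
    query: Sequence
    subject: Sequence
    scheme: Scheme
    gaps: GapPenalties

    def __post_init__(self):
        if isinstance(self.scheme, QueryProfile) and self.scheme.length != len(self.query):
            raise MatrixError(
                f"profile length {self.scheme.length} != query length {len(self.query)}"
            )


def _profile_matrix(query: Sequence, scheme: Scheme) -> np.ndarray:
    """Scores as an (|alphabet|, m) slab: column i scores subject residues vs query[i]."""
    if isinstance(scheme, SubstitutionMatrix):
        return build_local_profile(query, scheme).scores
    return scheme.scores


@njit(cache=True)
def _sw_kernel(profile, query_len, subject, gap_open_first, gap_extend):
    """Row-major score-only SW; linear memory over the query dimension."""
    m = query_len
    neg_inf = np.int64(-(1 << 40))
    h_row = np.zeros(m + 1, dtype=np.int64)  # H[i][j-1] sweeping to H[i][j]
    e_row = np.full(m + 1, neg_inf, dtype=np.int64)
    best = np.int64(0)
    for j in range(subject.shape[0]):
        res = subject[j]
        h_diag = np.int64(0)  # H[i-1][j-1]; H[0][*] == 0
        h_above = np.int64(0)  # H[i-1][j]
        f = neg_inf
        for i in range(1, m + 1):
            e = max(h_row[i] - gap_open_first, e_row[i] - gap_extend)
            f = max(h_above - gap_open_first, f - gap_extend)
            h = h_diag + profile[res, i - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = np.int64(0)
            h_diag = h_row[i]
            h_row[i] = h
            e_row[i] = e
            h_above = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_batch_kernel(profile, query_len, subjects, lengths, gap_open_first, gap_extend):
    n_tasks = subjects.shape[0]
    out = np.zeros(n_tasks, dtype=np.int64)
    for t in range(n_tasks):
        out[t] = _sw_kernel(
            profile, query_len, subjects[t, : lengths[t]], gap_open_first, gap_extend
        )
    return out


@njit(cache=True)
def _sw_wavefront_kernel(profile, query_len, subject, gap_open_first, gap_extend):
    """Anti-diagonal evaluation order; full matrices, identical scores."""
    m = query_len
    n = subject.shape[0]
    neg_inf = np.int64(-(1 << 40))
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), neg_inf, dtype=np.int64)
    F = np.full((m + 1, n + 1), neg_inf, dtype=np.int64)
    best = np.int64(0)
    for d in range(2, m + n + 1):  # anti-diagonal index: i + j = d
        i_lo = max(1, d - n)
        i_hi = min(m, d - 1)
        for i in range(i_lo, i_hi + 1):
            j = d - i
            e = max(H[i, j - 1] - gap_open_first, E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - gap_open_first, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + profile[subject[j - 1], i - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = np.int64(0)
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
    return best


def sw_score(task: AlignmentTask, *, order: str = "row") -> int:
    """Optimal local alignment score of one task.

    ``order`` selects the evaluation schedule: ``"row"`` (default,
    linear-memory row-major) or ``"wavefront"`` (anti-diagonal).  Both
    return the same score for every input.
    """
    if len(task.query) < 1 or len(task.subject) < 1:
        raise ValueError("empty sequence in alignment task")
    profile = np.ascontiguousarray(_profile_matrix(task.query, task.scheme))
    subject = task.subject.codes()
    g1 = task.gaps.open + task.gaps.extend
    if order == "row":
        score = _sw_kernel(profile, len(task.query), subject, g1, task.gaps.extend)
    elif order == "wavefront":
        score = _sw_wavefront_kernel(profile, len(task.query), subject, g1, task.gaps.extend)
    else:
        raise ValueError(f"unknown evaluation order {order!r}")
    return int(score)


def sw_score_batch(
    query: Sequence,
    subjects,
    scheme: Scheme,
    gaps: GapPenalties = GapPenalties(),
) -> list[int]:
    """Scores of ``query`` against each subject, in input order.

    Semantically a loop of :func:`sw_score`; the batch path packs subjects
    into one padded code array so the kernel runs without per-task Python
    overhead.  Padding never affects scores because true lengths are passed
    alongside.
    """
    subjects = list(subjects)
    if not subjects:
        return []
    if isinstance(scheme, QueryProfile) and scheme.length != len(query):
        raise MatrixError(
            f"profile length {scheme.length} != query length {len(query)}"
        )
    profile = np.ascontiguousarray(_profile_matrix(query, scheme))
    lengths = np.array([len(s) for s in subjects], dtype=np.int64)
    if lengths.min() < 1:
        raise ValueError("empty subject sequence in batch")
    packed = np.zeros((len(subjects), int(lengths.max())), dtype=np.uint8)
    for t, s in enumerate(subjects):
        packed[t, : lengths[t]] = s.codes()
    g1 = gaps.open + gaps.extend
    scores = _sw_batch_kernel(profile, len(query), packed, lengths, g1, gaps.extend)
    return [int(x) for x in scores]


def sw_score_codes_batch(
    profile: np.ndarray,
    query_len: int,
    packed_subjects: np.ndarray,
    lengths: np.ndarray,
    gaps: GapPenalties,
) -> np.ndarray:
    """Low-level batch entry for callers that already hold encoded arrays."""
    return _sw_batch_kernel(
        np.ascontiguousarray(profile),
        query_len,
        packed_subjects,
        lengths,
        gaps.open + gaps.extend,
        gaps.extend,
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle (test-only, exponential)
# ---------------------------------------------------------------------------

def sw_score_exhaustive(
    query: Sequence,
    subject: Sequence,
    scheme: Scheme,
    gaps: GapPenalties = GapPenalties(),
) -> int:
    """Best score over *all* gapped local alignments, by direct enumeration.

    A local alignment is fully determined by its matched columns: a strictly
    increasing set of query positions paired, in order, with a strictly
    increasing set of subject positions.  Residues skipped between two
    consecutive matched columns form gap runs, one per sequence, each costing
    open + extend * run_length.  This enumerates every such skeleton — all
    sum_k C(m,k)*C(n,k) of them — with no dynamic programming, so it is an
    independent check of the DP kernels.  Exponential; lengths <= ~8 only.
    """
    from itertools import combinations

    profile = _profile_matrix(query, scheme)
    sub = subject.codes()
    m, n = len(query), len(subject)
    g1 = gaps.open + gaps.extend
    ge = gaps.extend

    def gap_cost(run: int) -> int:
        return g1 + ge * (run - 1) if run > 0 else 0

    best = 0
    qpos = range(m)
    spos = range(n)
    for k in range(1, min(m, n) + 1):
        for qsel in combinations(qpos, k):
            for ssel in combinations(spos, k):
                score = 0
                for t in range(k):
                    score += int(profile[sub[ssel[t]], qsel[t]])
                    if t > 0:
                        score -= gap_cost(qsel[t] - qsel[t - 1] - 1)
                        score -= gap_cost(ssel[t] - ssel[t - 1] - 1)
                if score > best:
                    best = score
    return best
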