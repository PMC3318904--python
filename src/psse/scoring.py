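"""Substitution matrices, query profiles, and the PSI-BLAST ASCII PSSM reader.

Two scoring layouts are supported.  A standard substitution matrix is indexed
by (subject residue, query residue).  A *query profile* re-indexes scores by
(subject residue, query position): the "local" profile is a pure layout
transform of a substitution matrix (column ``i`` is the matrix column of
``query[i]``), while a "position-specific" profile carries PSSM scores that
genuinely differ between occurrences of the same residue.  Alignment treats
both identically through ``scores[subject_residue][query_position]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

import numpy as np
from Bio.Align import substitution_matrices

from .seq_io import PROTEIN_ALPHABET, Sequence

#: PSI-BLAST column order for the 20 score columns of an ASCII PSSM.
PSSM_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"


class MatrixError(ValueError):
    """Raised for malformed matrix or PSSM input."""


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap penalties: a gap of length k costs ``open + extend * k``.

    Note the convention: ``open`` is charged once per gap *in addition to*
    the per-residue ``extend``, so the first gap residue costs
    ``open + extend`` (with the defaults, 12) and each further residue 2.
    Some tools instead fold the first extension into "open"; converting
    between the conventions is ``open_other = open + extend``.
    """

    open: int = 10
    extend: int = 2

    def __post_init__(self):
        if self.open < 0 or self.extend < 0:
            raise ValueError("gap penalties must be nonnegative")

    def cost(self, k: int) -> int:
        return self.open + self.extend * k if k > 0 else 0


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Square integer substitution matrix over an ordered residue alphabet."""

    name: str
    alphabet: str
    scores: np.ndarray  # (|alphabet|, |alphabet|) int32

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.int32)
        if s.shape != (len(self.alphabet), len(self.alphabet)):
            raise MatrixError(
                f"matrix {self.name!r}: score block {s.shape} does not match "
                f"alphabet of length {len(self.alphabet)}"
            )
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.alphabet)})

    def score(self, a: str, b: str) -> int:
        idx = self._index
        try:
            return int(self.scores[idx[a], idx[b]])
        except KeyError as exc:
            raise MatrixError(f"residue {exc.args[0]!r} not in matrix alphabet") from exc

    @property
    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.scores, self.scores.T))


def _check_matrix_shape(path) -> None:
    """Reject ragged NCBI matrix files (row width != header width)."""
    n_cols = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.split():
                continue
            tokens = line.split()
            if n_cols is None:
                n_cols = len(tokens)  # header: alphabet only
            elif len(tokens) != n_cols + 1:  # label + one score per column
                raise MatrixError(
                    f"{path}, line {lineno}: expected {n_cols} scores, "
                    f"got {len(tokens) - 1}"
                )


def load_matrix(name_or_path: str) -> SubstitutionMatrix:
    """Load a built-in matrix by name (e.g. ``"BLOSUM62"``) or an NCBI-format file.

    The NCBI text format has ``#`` comment lines, a header row naming the
    alphabet, and one labelled score row per residue.  Scores must be
    integers; ragged rows raise :class:`MatrixError`.
    """
    builtin = name_or_path.upper()
    if builtin in substitution_matrices.load():
        arr = substitution_matrices.load(builtin)
    else:
        _check_matrix_shape(name_or_path)
        try:
            arr = substitution_matrices.read(str(name_or_path))
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise MatrixError(f"cannot parse matrix file {name_or_path}: {exc}") from exc
        builtin = str(name_or_path)
    scores = np.asarray(arr)
    if not np.allclose(scores, np.round(scores)):
        raise MatrixError(f"matrix {builtin!r} has non-integer scores")
    return SubstitutionMatrix(
        name=builtin,
        alphabet="".join(arr.alphabet),
        scores=np.round(scores).astype(np.int32),
    )


@dataclass(frozen=True)
class QueryProfile:
    """Scores re-indexed by (subject residue, query position).

    ``scores`` has shape ``(|alphabet|, L)``; ``kind`` records whether the
    profile is a layout transform of a substitution matrix ("local") or
    PSSM-derived ("position_specific").
    """

    query_id: str
    query_residues: str
    alphabet: str
    scores: np.ndarray
    kind: Literal["local", "position_specific"]

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.int32)
        if s.shape != (len(self.alphabet), len(self.query_residues)):
            raise MatrixError(
                f"profile for {self.query_id!r}: shape {s.shape} != "
                f"({len(self.alphabet)}, {len(self.query_residues)})"
            )
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.alphabet)})

    @property
    def length(self) -> int:
        return len(self.query_residues)

    def score(self, subject_residue: str, query_position: int) -> int:
        """The lookup ``scores[subject_residue][query_position]``."""
        if not 0 <= query_position < self.length:
            raise IndexError(
                f"query position {query_position} out of range [0, {self.length})"
            )
        idx = self._index
        if subject_residue not in idx:
            raise MatrixError(f"residue {subject_residue!r} not in profile alphabet")
        return int(self.scores[idx[subject_residue], query_position])


def profile_score(profile: QueryProfile, subject_residue: str, query_position: int) -> int:
    return profile.score(subject_residue, query_position)


def build_local_profile(query: Sequence, matrix: SubstitutionMatrix) -> QueryProfile:
    """Re-index ``matrix`` by query position: column i is the matrix column of query[i].

    Alignment scores are provably unchanged by this transform; it exists so
    that matrix- and PSSM-based scoring share one code path.
    """
    idx = {a: i for i, a in enumerate(matrix.alphabet)}
    for pos, aa in enumerate(query.residues):
        if aa not in idx:
            raise MatrixError(
                f"query {query.id!r}: residue {aa!r} at position {pos + 1} "
                f"not in matrix alphabet"
            )
    cols = np.array([idx[aa] for aa in query.residues])
    return QueryProfile(
        query_id=query.id,
        query_residues=query.residues,
        alphabet=matrix.alphabet,
        scores=matrix.scores[:, cols],
        kind="local",
    )


_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Z\*])((?:\s+-?\d+)+)\s*$")


def read_ascii_pssm(
    path,
    *,
    ambiguity: Literal["blosum62", "constant"] = "blosum62",
    ambiguity_penalty: int = -4,
) -> QueryProfile:
    """Read a PSI-BLAST ``-out_ascii_pssm`` file into a position-specific profile.

    The dialect: free-form header lines, a column-header line listing the 20
    standard residues, then one row per query position carrying the position
    index, the query residue, and at least 20 integer log-odds scores (only
    the first 20 are used; the weighted-percentage block is ignored).

    ASCII PSSMs carry no scores for B, Z, X, ``*``.  By default those rows
    are filled from BLOSUM62 against the query residue at each position;
    with ``ambiguity="constant"`` they are set to ``ambiguity_penalty``.
    """
    with open(path) as handle:
        lines = handle.readlines()

    rows = []
    residues = []
    for lineno, line in enumerate(lines, start=1):
        m = _PSSM_ROW.match(line)
        if not m:
            continue
        position = int(m.group(1))
        scores = [int(tok) for tok in m.group(3).split()]
        if len(scores) < 20:
            raise MatrixError(
                f"{path}, line {lineno}: expected >= 20 score columns, got {len(scores)}"
            )
        if position != len(rows) + 1:
            raise MatrixError(
                f"{path}, line {lineno}: position {position} out of order "
                f"(expected {len(rows) + 1})"
            )
        rows.append(scores[:20])
        residues.append(m.group(2))

    if not rows:
        raise MatrixError(f"{path}: no PSSM rows found (truncated or wrong format?)")

    query_residues = "".join(residues)
    length = len(rows)
    scores = np.zeros((len(PROTEIN_ALPHABET), length), dtype=np.int32)
    pssm = np.array(rows, dtype=np.int32).T  # (20, L) in PSI-BLAST column order
    for k, aa in enumerate(PSSM_COLUMN_ORDER):
        scores[PROTEIN_ALPHABET.index(aa)] = pssm[k]

    if ambiguity == "blosum62":
        blosum = load_matrix("BLOSUM62")
        bidx = {a: i for i, a in enumerate(blosum.alphabet)}
        qcols = np.array([bidx[aa] for aa in query_residues])
        for aa in PROTEIN_ALPHABET[20:]:
            scores[PROTEIN_ALPHABET.index(aa)] = blosum.scores[bidx[aa], qcols]
    elif ambiguity == "constant":
        for aa in PROTEIN_ALPHABET[20:]:
            scores[PROTEIN_ALPHABET.index(aa)] = ambiguity_penalty
    else:
        raise ValueError(f"unknown ambiguity rule {ambiguity!r}")

    return QueryProfile(
        query_id=str(path),
        query_residues=query_residues,
        alphabet=PROTEIN_ALPHABET,
        scores=scores,
        kind="position_specific",
    )


def write_ascii_pssm(profile_scores: np.ndarray, query: Sequence, path) -> None:
    """Write a synthetic ASCII PSSM in the PSI-BLAST dialect.

    ``profile_scores`` has shape (20, L) in PSI-BLAST column order.  Used by
    the fixture generator; output round-trips through :func:`read_ascii_pssm`.
    """
    scores = np.asarray(profile_scores, dtype=int)
    if scores.shape != (20, len(query)):
        raise MatrixError(
            f"expected (20, {len(query)}) score block, got {scores.shape}"
        )
    with open(path, "w") as out:
        out.write("\n")
        out.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        out.write("            " + "  ".join(PSSM_COLUMN_ORDER) + "\n")
        for i, aa in enumerate(query.residues):
            row = " ".join(f"{int(scores[k, i]):3d}" for k in range(20))
            out.write(f"{i + 1:5d} {aa}  {row}\n")
        out.write("\n")
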