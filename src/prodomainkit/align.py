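"""Progressive multiple alignment and parsimony-informative site counting.

The aligner is deliberately self-contained: affine-gap Needleman–Wunsch
(Gotoh three-state DP) for pairs, generalised to average sum-of-pairs
profile–profile scoring for the progressive stage, with a guide tree built
by neighbor joining on k-mer distances.  Traceback tie-breaking is fixed
(match/mismatch preferred over a gap in the first profile, preferred over a
gap in the second) so alignments are deterministic.

Informative sites follow the standard parsimony-informative criterion under
complete deletion: columns containing any gap or X are excluded, and a
retained column is informative iff at least two distinct residues each occur
at least twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS, GAP, Alignment, ProteinRecord

NEG_INF = -1e30

#: Residue order used by profile count matrices; X last.
ALPHABET = AMINO_ACIDS + "X"
_IDX = {ch: i for i, ch in enumerate(ALPHABET)}


def _blosum62() -> np.ndarray:
    """BLOSUM62 over ALPHABET; X scores floored to the matrix minimum."""
    raw = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n))
    floor = min(raw[a][b] for a in AMINO_ACIDS for b in AMINO_ACIDS)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = floor
            else:
                mat[i, j] = raw[a][b]
    return mat


_MATRICES = {"BLOSUM62": _blosum62()}


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for pairwise and progressive alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0   # first residue of a gap run
    gap_extend: float = -1.0  # each subsequent residue
    k: int = 3                # k-mer size for guide-tree distances

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.matrix not in _MATRICES:
            raise ValueError(f"unknown substitution matrix {self.matrix!r}")

    @property
    def score_matrix(self) -> np.ndarray:
        return _MATRICES[self.matrix]


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """(n_cols, |ALPHABET|) residue count matrix; gaps contribute nothing."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, len(ALPHABET)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                counts[j, _IDX[ch]] += 1
    return counts


def _align_profiles(
    counts_a: np.ndarray, counts_b: np.ndarray, n_a: int, n_b: int, params: AlignParams
) -> tuple[list[tuple[int, int]], float]:
    """Affine-gap global alignment of two profiles.

    Returns a list of column pairs (ia, ib), 0-based, with -1 marking a gap
    column, plus the optimal score.  Column score is the average sum-of-pairs
    BLOSUM score between the profiles' residue counts.
    """
    m, n = counts_a.shape[0], counts_b.shape[0]
    sub = counts_a @ params.score_matrix @ counts_b.T / (n_a * n_b)
    go, ge = params.gap_open, params.gap_extend

    M = np.full((m + 1, n + 1), NEG_INF)
    Gx = np.full((m + 1, n + 1), NEG_INF)  # gap in A (consumes B column)
    Gy = np.full((m + 1, n + 1), NEG_INF)  # gap in B (consumes A column)
    M[0, 0] = 0.0
    j_idx = np.arange(1, n + 1)
    # terminal gaps are penalized like internal ones
    Gx[0, 1:] = go + ge * (j_idx - 1)
    i_idx = np.arange(1, m + 1)
    Gy[1:, 0] = go + ge * (i_idx - 1)

    for i in range(1, m + 1):
        diag = np.maximum(np.maximum(M[i - 1, :n], Gx[i - 1, :n]), Gy[i - 1, :n])
        M[i, 1:] = diag + sub[i - 1, :]
        Gy[i, 1:] = np.maximum(M[i - 1, 1:] + go, Gy[i - 1, 1:] + ge)
        # Gx[i, j] = max_{k<j} M[i, k] + go + ge*(j-1-k)  (prefix-max scan)
        t = np.maximum.accumulate(M[i, :n] - ge * np.arange(n))
        Gx[i, 1:] = t + go + ge * (j_idx - 1)

    # traceback: prefer M over Gx over Gy at every tie
    path: list[tuple[int, int]] = []
    i, j = m, n
    best = max(M[i, j], Gx[i, j], Gy[i, j])
    if M[i, j] == best:
        state = "M"
    elif Gx[i, j] == best:
        state = "X"
    else:
        state = "Y"
    score = best
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            prev = max(M[i - 1, j - 1], Gx[i - 1, j - 1], Gy[i - 1, j - 1])
            if M[i - 1, j - 1] == prev:
                state = "M"
            elif Gx[i - 1, j - 1] == prev:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            path.append((-1, j - 1))
            state = "M" if M[i, j - 1] + go == Gx[i, j] else "X"
            j -= 1
        else:  # Y
            path.append((i - 1, -1))
            state = "M" if M[i - 1, j] + go == Gy[i, j] else "Y"
            i -= 1
    path.reverse()
    return path, float(score)


def pairwise_global_align(
    a: str, b: str, params: AlignParams | None = None
) -> tuple[str, str, float]:
    """Optimal affine-gap global alignment of two sequences.

    Returns (aligned_a, aligned_b, score); deterministic tie-breaking prefers
    match/mismatch columns, then a gap in ``a``, then a gap in ``b``.
    """
    if not a or not b:
        raise ValueError("pairwise_global_align requires non-empty sequences")
    params = params or AlignParams()
    ca, cb = _profile_counts([a]), _profile_counts([b])
    path, score = _align_profiles(ca, cb, 1, 1, params)
    row_a = "".join(a[ia] if ia >= 0 else GAP for ia, _ in path)
    row_b = "".join(b[ib] if ib >= 0 else GAP for _, ib in path)
    return row_a, row_b, score


def _merge(rows_a: list[str], rows_b: list[str], params: AlignParams) -> list[str]:
    """Merge two sub-alignments along the optimal profile–profile path."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    path, _ = _align_profiles(ca, cb, len(rows_a), len(rows_b), params)
    out_a = ["".join(r[ia] if ia >= 0 else GAP for ia, _ in path) for r in rows_a]
    out_b = ["".join(r[ib] if ib >= 0 else GAP for _, ib in path) for r in rows_b]
    return out_a + out_b


def kmer_distance_matrix(records: Sequence[ProteinRecord], k: int = 3) -> np.ndarray:
    """1 - (shared k-mers / smaller k-mer count), multiset semantics."""
    from collections import Counter

    counters = [Counter(r.sequence[i : i + k] for i in range(len(r.sequence) - k + 1))
                for r in records]
    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = counters[i], counters[j]
            shared = sum(min(ci[w], cj[w]) for w in ci)
            denom = min(sum(ci.values()), sum(cj.values()))
            d = 1.0 - shared / denom if denom > 0 else 1.0
            dm[i, j] = dm[j, i] = d
    return dm


def progressive_align(
    records: Sequence[ProteinRecord], params: AlignParams | None = None
) -> Alignment:
    """Progressive multiple alignment guided by an NJ tree on k-mer distances.

    Sub-alignments are merged bottom-up by profile–profile affine alignment;
    output row order equals input order.
    """
    params = params or AlignParams()
    records = list(records)
    if len(records) < 2:
        raise ValueError("progressive_align requires at least 2 records")
    ids = [r.id for r in records]
    if len(records) == 2:
        ra, rb, _ = pairwise_global_align(records[0].sequence, records[1].sequence, params)
        return Alignment(ids, [ra, rb])

    from . import trees as _trees

    dm = kmer_distance_matrix(records, k=params.k)
    guide = _trees.nj(_trees.DistanceMatrix(ids, dm))
    try:
        guide.reroot_at_midpoint(update_bipartitions=False)
    except (ValueError, AttributeError):
        pass  # all-zero branch lengths (identical inputs): any rooting works

    # merge sub-alignments bottom-up over the rooted guide tree; rooting can
    # leave a taxon on an internal node, so taxa are collected wherever found
    def build(node) -> tuple[list[str], list[str]]:
        child_parts = [build(ch) for ch in node.child_nodes()]
        if node.taxon is not None:
            rid = node.taxon.label
            child_parts.insert(0, ([rid], [records[ids.index(rid)].sequence]))
        if not child_parts:
            raise ValueError("guide tree node carries neither taxon nor children")
        acc_ids, acc_rows = child_parts[0]
        for nxt_ids, nxt_rows in child_parts[1:]:
            acc_rows = _merge(acc_rows, nxt_rows, params)
            acc_ids = acc_ids + nxt_ids
        return acc_ids, acc_rows

    out_ids, out_rows = build(guide.seed_node)
    order = [out_ids.index(i) for i in ids]
    aln = Alignment(ids, [out_rows[i] for i in order])
    for rec in records:  # ungapping must reproduce the inputs exactly
        assert aln.ungapped(rec.id) == rec.sequence
    return aln


@dataclass
class InformativeSiteReport:
    """Alignment-length / informative-site statistics under complete deletion."""

    n_cols_with_gaps: int
    n_informative: int
    informative_column_indices: list[int] = field(default_factory=list)
    n_gap_free_cols: int = 0
    n_gap_chars: int = 0


def count_informative(aln: Alignment, deletion_mode: str = "complete") -> InformativeSiteReport:
    """Count parsimony-informative sites among gap-free columns.

    Columns containing any gap or X are excluded (complete deletion); a
    retained column is informative iff >= 2 distinct residues each occur
    >= 2 times.  Requires >= 4 rows.
    """
    if deletion_mode != "complete":
        raise ValueError(f"unsupported deletion mode {deletion_mode!r}")
    if aln.n_rows < 4:
        raise ValueError("informative-site counting requires >= 4 rows")
    informative: list[int] = []
    n_gap_free = 0
    n_gap_chars = sum(row.count(GAP) for row in aln.matrix)
    for col in range(1, aln.n_cols + 1):
        column = aln.column(col)
        if GAP in column or "X" in column:
            continue
        n_gap_free += 1
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        if sum(1 for c in counts.values() if c >= 2) >= 2:
            informative.append(col)
    return InformativeSiteReport(
        n_cols_with_gaps=aln.n_cols,
        n_informative=len(informative),
        informative_column_indices=informative,
        n_gap_free_cols=n_gap_free,
        n_gap_chars=n_gap_chars,
    )
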