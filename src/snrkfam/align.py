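"""Pairwise protein alignment with BLAST-style E-values.

Local alignments follow the Smith-Waterman-Gotoh contract: optimal score
under a substitution matrix (BLOSUM62 by default) and affine gap costs,
where a gap of length k costs ``gap_open + k * gap_extend``.  Raw scores S
are converted to bit scores S' = (lambda*S - ln K)/ln 2 and E-values
E = m*n*2^(-S') using Karlin-Altschul statistics; the default lambda/K are
the published constants for gapped BLOSUM62 with open 11 / extend 1
(lambda = 0.267 nats, K = 0.041), configurable on the scheme.

The search space m*n can be pairwise (query length x target length) or
database-style (query length x summed lengths of all candidates), matching
how BLAST reports E-values against a sequence database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AA20) | {"X"}


class AlignmentInputError(ValueError):
    pass


def _blosum62_with_neutral_x() -> substitution_matrices.Array:
    mat = substitution_matrices.load("BLOSUM62").copy()
    for aa in mat.alphabet:
        mat["X", aa] = 0.0
        mat[aa, "X"] = 0.0
    return mat


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0     # cost of opening a gap (positive)
    gap_extend: float = 1.0    # cost per gapped position (positive)
    lam: float = 0.267         # nats per raw-score unit
    K: float = 0.041
    matrix: substitution_matrices.Array = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.matrix is None:
            if self.matrix_name == "BLOSUM62":
                self.matrix = _blosum62_with_neutral_x()
            else:
                self.matrix = substitution_matrices.load(self.matrix_name)
        arr = np.asarray(self.matrix)
        if not np.allclose(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.matrix
        # biopython charges open_gap_score on the first gapped position:
        # total for k gapped positions = open + k*extend requires these scores
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        if mode == "global":
            _set_end_gap_scores(al, 0.0, 0.0)
        return al

    def bitscore(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / math.log(2)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bitscore(raw))


@dataclass
class AlignmentHit:
    query: str
    target: str
    score: float
    bitscore: float
    evalue: float
    query_span: tuple[int, int]   # 1-based closed on the query
    target_span: tuple[int, int]  # 1-based closed on the target


def _set_end_gap_scores(al: Align.PairwiseAligner, open_score: float,
                        extend_score: float) -> None:
    try:  # biopython >= 1.88 naming
        al.open_end_insertion_score = open_score
        al.extend_end_insertion_score = extend_score
        al.open_end_deletion_score = open_score
        al.extend_end_deletion_score = extend_score
    except AttributeError:  # pragma: no cover - older releases
        al.target_end_open_gap_score = open_score
        al.target_end_extend_gap_score = extend_score
        al.query_end_open_gap_score = open_score
        al.query_end_extend_gap_score = extend_score


def _check(seq: str, name: str) -> str:
    if not seq:
        raise AlignmentInputError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise AlignmentInputError(f"{name}: unknown residue(s) {sorted(bad)}")
    return seq


def local_align(query: str, target: str, scheme: ScoringScheme | None = None,
                query_id: str = "query", target_id: str = "target",
                search_space: int | None = None) -> AlignmentHit:
    """Optimal local alignment of two proteins with its E-value.

    ``search_space`` overrides the n of m*n (database-style E-values);
    by default n is the target length (pairwise E-value).
    """
    scheme = scheme or ScoringScheme()
    q = _check(query, query_id)
    t = _check(target, target_id)
    n = search_space if search_space is not None else len(t)
    aln = scheme.aligner("local").align(q, t)
    try:
        best = aln[0]
    except IndexError:
        best = None
    if best is None or len(best.aligned[0]) == 0:
        # no residue pair scores positively: the optimal local alignment is
        # empty (score 0, empty spans)
        return AlignmentHit(query_id, target_id, 0.0, scheme.bitscore(0.0),
                            scheme.evalue(0.0, len(q), n), (0, 0), (0, 0))
    qs, ts = best.aligned  # blocks: (n,2) 0-based half-open
    # biopython orders .aligned as (target, query) for align(target, query);
    # we called align(q, t) so best.aligned[0] indexes q.
    qspan = (int(qs[0][0]) + 1, int(qs[-1][1]))
    tspan = (int(ts[0][0]) + 1, int(ts[-1][1]))
    score = float(best.score)
    return AlignmentHit(query_id, target_id, score, scheme.bitscore(score),
                        scheme.evalue(score, len(q), n), qspan, tspan)


def global_align_score(a: str, b: str, scheme: ScoringScheme | None = None,
                       end_gaps_free: bool = True) -> float:
    """Needleman-Wunsch-Gotoh global alignment score (used by the MSA)."""
    scheme = scheme or ScoringScheme()
    al = scheme.aligner("global")
    if not end_gaps_free:
        _set_end_gap_scores(al, al.open_gap_score, al.extend_gap_score)
    return float(al.score(_check(a, "a"), _check(b, "b")))


def pairwise_identity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Fraction of identical residues over aligned (non-gap) columns of the
    optimal global alignment."""
    scheme = scheme or ScoringScheme()
    best = scheme.aligner("global").align(_check(a, "a"), _check(b, "b"))[0]
    sa, sb = best.aligned
    same = compared = 0
    for (a0, a1), (b0, b1) in zip(sa, sb):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            compared += 1
            same += a[i] == b[j]
    return same / compared if compared else 0.0
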