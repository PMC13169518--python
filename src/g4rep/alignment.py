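"""Pairwise sequence identity and coverage for homology reduction.

Identity is measured on a global alignment with free terminal gaps (overlap
alignment), the natural choice when the two proteins may differ in length:
terminal overhangs count against coverage, not against identity.

Definitions used throughout the curation pipeline:

* ``identity``   — matched positions / columns of the aligned core, where the
  aligned core runs from the first to the last aligned residue pair and
  internal gap columns are counted in the denominator but never as matches.
* ``coverage_x`` — span of x inside the aligned core / length of x.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class PairwiseResult:
    identity: float
    coverage_a: float
    coverage_b: float


def _make_aligner(
    matrix: str | None,
    match_score: float,
    mismatch_score: float,
    open_gap_score: float,
    extend_gap_score: float,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match_score
        aligner.mismatch_score = mismatch_score
    aligner.open_gap_score = open_gap_score
    aligner.extend_gap_score = extend_gap_score
    # Free terminal gaps: overhangs are a coverage matter, not a penalty.
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    *,
    matrix: str | None = "BLOSUM62",
    match_score: float = 1.0,
    mismatch_score: float = 0.0,
    open_gap_score: float = -11.0,
    extend_gap_score: float = -1.0,
) -> PairwiseResult:
    """Align ``a`` against ``b`` and return (identity, coverage_a, coverage_b).

    By default scores with BLOSUM62 and affine gaps (-11/-1).  Passing
    ``matrix=None`` switches to simple match/mismatch scoring, which makes the
    optimum reproducible by a plain dynamic-programming implementation.
    All three returned values lie in [0, 1].
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    aligner = _make_aligner(
        matrix, match_score, mismatch_score, open_gap_score, extend_gap_score
    )
    alignment = aligner.align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned

    if len(blocks_a) == 0:  # degenerate: nothing aligned at all
        return PairwiseResult(0.0, 0.0, 0.0)

    matches = 0
    pairs = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        pairs += a1 - a0
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if a[i] == b[j]:
                matches += 1

    # Internal gap columns between consecutive aligned blocks.
    gap_cols = 0
    for k in range(len(blocks_a) - 1):
        gap_cols += blocks_a[k + 1][0] - blocks_a[k][1]
        gap_cols += blocks_b[k + 1][0] - blocks_b[k][1]

    columns = pairs + gap_cols
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    return PairwiseResult(
        identity=matches / columns if columns else 0.0,
        coverage_a=span_a / len(a),
        coverage_b=span_b / len(b),
    )
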