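"""Shared pairwise-alignment configuration and identity bookkeeping.

One place defines the scoring used across the event detectors and the
pseudogene mapper so reports can cite a single parameter set:
protein local/global alignments use BLOSUM62 with gap open 11 / extend 1;
nucleotide alignments use match +2 / mismatch -3, gap open 5 / extend 2.
Identity is always matches / aligned columns with terminal gaps excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["AlignmentHit", "make_aligner", "align_local", "align_global",
           "gapped_strings", "percent_identity", "ALIGNMENT_PARAMS"]

ALIGNMENT_PARAMS = {
    "protein": "BLOSUM62, gap open 11, gap extend 1",
    "dna": "match +2, mismatch -3, gap open 5, gap extend 2",
}


@lru_cache(maxsize=None)
def make_aligner(kind: str, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if kind == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    elif kind == "dna":
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:
        raise ValueError(f"unknown alignment kind {kind!r}")
    if mode == "global":
        # do not charge terminal gaps: sequences may be partial
        aligner.end_gap_score = 0.0
    return aligner


@dataclass
class AlignmentHit:
    """A pairwise alignment reduced to the fields the pipeline consumes.

    Spans are 0-based half-open in the *unaligned* sequences; identity is
    matches over aligned columns (mismatches and internal gaps included,
    terminal gaps excluded).
    """

    score: float
    target_span: tuple[int, int]
    query_span: tuple[int, int]
    identity_pct: float
    n_columns: int
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]


def _summarise(alignment, target: str, query: str) -> AlignmentHit:
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return AlignmentHit(float(alignment.score), (0, 0), (0, 0), 0.0, 0, [])
    matches = 0
    columns = 0
    prev_t = prev_q = None
    blocks = []
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            columns += (t0 - prev_t) + (q0 - prev_q)  # internal gap columns
        for a, b in zip(target[t0:t1], query[q0:q1]):
            columns += 1
            if a == b:
                matches += 1
        blocks.append(((int(t0), int(t1)), (int(q0), int(q1))))
        prev_t, prev_q = t1, q1
    identity = 100.0 * matches / columns if columns else 0.0
    return AlignmentHit(
        score=float(alignment.score),
        target_span=(int(t_blocks[0][0]), int(t_blocks[-1][1])),
        query_span=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
        identity_pct=identity,
        n_columns=columns,
        blocks=blocks,
    )


def align_local(target: str, query: str, kind: str = "protein") -> AlignmentHit:
    """Best Smith–Waterman local alignment of ``query`` against ``target``.

    Unrelated sequences (no positive-scoring segment) yield an empty hit
    with zero score and spans."""
    aligner = make_aligner(kind, "local")
    alignments = aligner.align(target, query)
    try:
        best = alignments[0]
    except IndexError:
        return AlignmentHit(0.0, (0, 0), (0, 0), 0.0, 0, [])
    return _summarise(best, target, query)


def align_global(target: str, query: str, kind: str = "protein") -> AlignmentHit:
    """Needleman–Wunsch global alignment with free terminal gaps."""
    aligner = make_aligner(kind, "global")
    alignments = aligner.align(target, query)
    return _summarise(alignments[0], target, query)


def gapped_strings(target: str, query: str, kind: str = "protein",
                   mode: str = "global") -> tuple[str, str]:
    """Aligned sequences as two equal-length gapped strings."""
    aligner = make_aligner(kind, mode)
    alignment = aligner.align(target, query)[0]
    return str(alignment[0]), str(alignment[1])


def percent_identity(a: str, b: str) -> float:
    """Identity of two equal-length (possibly gapped) strings, terminal gaps
    excluded, gap-gap columns skipped."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    start = 0
    end = len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        # trim only columns that are terminal gaps in either sequence
        if a[start] != "-" and b[start] != "-":
            break
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        if a[end - 1] != "-" and b[end - 1] != "-":
            break
        end -= 1
    matches = columns = 0
    for x, y in zip(a[start:end], b[start:end]):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y:
            matches += 1
    return 100.0 * matches / columns if columns else 0.0
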