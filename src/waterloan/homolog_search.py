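"""Template ranking by pairwise sequence similarity.

Templates are scored against the query sequence with an optimal local
(Smith–Waterman) alignment under BLOSUM62 with affine gaps, and the raw
score is converted to a bit score with the gapped Karlin–Altschul
constants (λ = 0.267, K = 0.041 for BLOSUM62 11/1) so that the familiar
blastp bit-score scale — and a user threshold such as 300 — remains
meaningful. Gap cost follows the BLAST convention: a gap of length k
costs ``gap_open + k·gap_extend``.

Ranking order: templates matching the query's functional state first
(when a state is given), then bit score descending, then resolution
ascending, then (entry id, chain) lexicographically for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .exceptions import DataError
from .water_db import ReferenceDB, TemplateEntry

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
# gapped Karlin-Altschul constants for BLOSUM62 11/1
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AlignmentResult:
    """Optimal local alignment of query vs template."""

    score_raw: float
    score_bits: float
    pct_identity: float
    #: (query index, template index) pairs for aligned non-gap columns,
    #: strictly increasing in both sequences.
    correspondence: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RankedTemplate:
    template: TemplateEntry
    alignment: AlignmentResult
    state_match: bool
    rank: int


def _make_aligner(
    matrix: str, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: length-k gap costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw: float, lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K) -> float:
    """Normalised bit score S' = (λ·S − ln K) / ln 2."""
    return (lam * raw - math.log(k)) / math.log(2.0)


def align_pair(
    query_seq: str,
    template_seq: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> AlignmentResult:
    """Optimal local alignment of two amino-acid sequences.

    Identity is reported over aligned (non-gap) columns only, as in
    common BLAST output.
    """
    for label, seq in (("query", query_seq), ("template", template_seq)):
        if not seq:
            raise DataError(f"{label} sequence is empty")
        if not set(seq) & STANDARD_AA:
            raise DataError(f"{label} sequence contains no standard residues")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(query_seq, template_seq)
    try:
        best = alignments[0]
    except IndexError:
        # no positive-scoring local alignment exists at all
        return AlignmentResult(
            score_raw=0.0, score_bits=bit_score(0.0, lam, k),
            pct_identity=0.0, correspondence=[],
        )
    raw = float(best.score)

    pairs: list[tuple[int, int]] = []
    n_identical = 0
    for (qs, qe), (ts, te) in zip(*best.aligned):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            pairs.append((qi, ti))
            if query_seq[qi] == template_seq[ti]:
                n_identical += 1
    pct = 100.0 * n_identical / len(pairs) if pairs else 0.0
    return AlignmentResult(
        score_raw=raw,
        score_bits=bit_score(raw, lam, k),
        pct_identity=pct,
        correspondence=pairs,
    )


def rank_templates(
    db: ReferenceDB,
    query_seq: str,
    query_state: str = "unknown",
    score_min: float = 0.0,
    state_priority: bool = True,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> list[RankedTemplate]:
    """Score every DB entry and return those above ``score_min``, ranked.

    With ``state_priority`` (default) and a known query state, templates
    in the matching functional state sort ahead of all others; the
    alternative (state as a tie-break only) is available by turning the
    flag off. An empty list — not an exception — signals that no
    template clears the threshold.
    """
    if not db.entries:
        raise DataError("reference DB is empty")
    scored: list[RankedTemplate] = []
    for entry in db.entries:
        aln = align_pair(
            query_seq, entry.sequence, matrix, gap_open, gap_extend, lam, k
        )
        if aln.score_bits < score_min:
            continue
        scored.append(
            RankedTemplate(
                template=entry,
                alignment=aln,
                state_match=(query_state != "unknown" and entry.state == query_state),
                rank=0,
            )
        )

    def sort_key(rt: RankedTemplate):
        state_key = (
            (0 if rt.state_match else 1)
            if (state_priority and query_state != "unknown")
            else 0
        )
        return (
            state_key,
            -rt.alignment.score_bits,
            rt.template.resolution,
            rt.template.entry_id,
            rt.template.chain_id,
        )

    scored.sort(key=sort_key)
    for i, rt in enumerate(scored, start=1):
        rt.rank = i
    return scored
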