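"""Pairwise global alignment with the pipeline's fixed scoring scheme.

All sequence comparisons in the pipeline (copy discovery, the 80-80-80
family rule, inter-LTR divergence) use the same affine scheme so that
identities are reproducible: match +1, mismatch -1, gap open -3, gap
extend -1 (a gap of length L costs 3 + L). Alignment itself is delegated
to Biopython's ``PairwiseAligner`` (Needleman-Wunsch / Gotoh in C); the
first optimal traceback it reports is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -3.0
GAP_EXTEND = -1.0

GAP = "-"


@dataclass
class PairwiseAlignment:
    """A gapped pair of sequences plus the alignment score.

    ``a_aligned`` and ``b_aligned`` have equal length; columns where both
    rows are gaps never occur.
    """

    a_aligned: str
    b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned rows differ in length")

    # -- column bookkeeping -------------------------------------------------

    def _core_span(self) -> tuple[int, int]:
        """Column range [lo, hi) excluding terminal gap runs."""
        a, b = self.a_aligned, self.b_aligned
        lo, hi = 0, len(a)
        while lo < hi and (a[lo] == GAP or b[lo] == GAP):
            lo += 1
        while hi > lo and (a[hi - 1] == GAP or b[hi - 1] == GAP):
            hi -= 1
        return lo, hi

    @property
    def columns(self) -> int:
        """Alignment columns excluding terminal gaps."""
        lo, hi = self._core_span()
        return hi - lo

    @property
    def matches(self) -> int:
        lo, hi = self._core_span()
        a, b = self.a_aligned, self.b_aligned
        return sum(
            1 for i in range(lo, hi) if a[i] == b[i] and a[i] != GAP and a[i] != "N"
        )

    @property
    def identity(self) -> float:
        cols = self.columns
        return self.matches / cols if cols else 0.0

    def aligned_positions_b(self) -> int:
        """Number of b positions aligned to (non-gap vs non-gap) a positions."""
        return sum(
            1
            for x, y in zip(self.a_aligned, self.b_aligned)
            if x != GAP and y != GAP
        )

    def gap_free_columns(self) -> list[tuple[str, str]]:
        """Base pairs from columns where neither row is gapped."""
        return [
            (x, y)
            for x, y in zip(self.a_aligned, self.b_aligned)
            if x != GAP and y != GAP
        ]


@lru_cache(maxsize=4)
def _aligner(free_end_gaps_a: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    # Biopython charges open+extend on the first gap base; -4 then -1 per
    # extra base realises "open -3, extend -1 per base".
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    if free_end_gaps_a:
        # overhangs of sequence a (e.g. a genome window) are free
        aligner.end_deletion_score = 0.0
    return aligner


def global_align(a: str, b: str, *, free_end_gaps_a: bool = False) -> PairwiseAlignment:
    """Optimal global alignment of ``a`` and ``b``.

    With ``free_end_gaps_a`` the alignment is semi-global: unaligned
    overhangs of ``a`` cost nothing, so a short reference ``b`` can be
    placed inside a longer window ``a``.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aln = _aligner(free_end_gaps_a).align(a.upper(), b.upper())[0]
    return PairwiseAlignment(aln[0], aln[1], aln.score)
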