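"""Reference-guided mining of full-length LTR retrotransposon copies.

Copies of a reference element are located by exact k-mer seeding,
diagonal clustering and semi-global alignment of the reference into the
candidate window, on both strands. Candidates are then pushed through
the structural filters used for copy-number determination: at least 80 %
of the reference length aligned, above 80 % identity, canonical TG..CA
termini after +/-3 bp boundary refinement, and (reported, not required)
a 4-6 bp target-site duplication.

LTR boundaries on a copy are obtained by projecting the reference LTR
coordinates through the alignment, then refining each outer boundary
within +/-3 bp to recover the terminal motif; de novo LTR discovery is
out of scope because the pipeline always starts from an annotated
reference.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    GAP,
    GAP_EXTEND,
    GAP_OPEN,
    MATCH_SCORE,
    MISMATCH_SCORE,
    PairwiseAlignment,
    global_align,
)
from .records import (
    FULL_LENGTH,
    REJECTED_COVERAGE,
    REJECTED_IDENTITY,
    REJECTED_TERMINI,
    ElementCopy,
    GenomeSequence,
    Interval,
    ReferenceElement,
    reverse_complement,
)

DEFAULT_SEED_K = 12
_REPORT_FLOOR_IDENTITY = 0.5
_REPORT_FLOOR_COVERAGE = 0.3


@dataclass
class _Candidate:
    """Scored alignment of the reference into one genome window."""

    interval: Interval  # on the oriented genome
    strand: str
    identity: float
    coverage: float
    alignment: PairwiseAlignment  # trimmed to the best-scoring column run
    window_start: int  # oriented-genome coordinate of the window
    a_offset: int  # window bases preceding the trimmed alignment
    b_offset: int  # reference bases preceding the trimmed alignment
    reference: ReferenceElement


def _trim_alignment(aln: PairwiseAlignment) -> tuple[PairwiseAlignment, int, int]:
    """Restrict an alignment to its maximum-scoring contiguous column run.

    A semi-global alignment happily drags unmatched reference through
    random flanking sequence as mismatch columns; trimming to the
    best-scoring run (Kadane over per-column scores) recovers the
    genuinely homologous segment so identity and coverage reflect it.
    Returns (trimmed alignment, a-chars before it, b-chars before it).
    """
    a, b = aln.a_aligned, aln.b_aligned
    scores = []
    gap_a = gap_b = False
    for ca, cb in zip(a, b):
        if ca == GAP:
            scores.append(GAP_EXTEND + (0.0 if gap_a else GAP_OPEN))
            gap_a, gap_b = True, False
        elif cb == GAP:
            scores.append(GAP_EXTEND + (0.0 if gap_b else GAP_OPEN))
            gap_a, gap_b = False, True
        else:
            scores.append(MATCH_SCORE if ca == cb else MISMATCH_SCORE)
            gap_a = gap_b = False
    best_sum = run_sum = 0.0
    best = (0, 0)
    run_start = 0
    for i, s in enumerate(scores):
        if run_sum <= 0:
            run_sum = s
            run_start = i
        else:
            run_sum += s
        if run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, i + 1)
    lo, hi = best
    a_off = sum(1 for c in a[:lo] if c != GAP)
    b_off = sum(1 for c in b[:lo] if c != GAP)
    trimmed = PairwiseAlignment(a[lo:hi], b[lo:hi], best_sum)
    return trimmed, a_off, b_off


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _seed_hits(index: dict[str, list[int]], ref: str, k: int) -> list[tuple[int, int]]:
    hits = []
    for r in range(len(ref) - k + 1):
        kmer = ref[r : r + k]
        for g in index.get(kmer, ()):
            hits.append((g, r))
    return hits


def _cluster_hits(
    hits: list[tuple[int, int]], ref_len: int, min_hits: int = 3
) -> list[tuple[int, int, int, int]]:
    """Group seed hits into candidate loci.

    Hits are sorted by diagonal then genome position and merged while the
    diagonal drifts less than ``band`` and genome positions are within a
    reference length. Returns (g_min, g_max, r_min, r_max) per cluster.
    """
    if not hits:
        return []
    band = max(60, ref_len // 10)
    hits = sorted(hits, key=lambda h: (h[0] - h[1], h[0]))
    clusters = []
    cur = [hits[0]]
    for h in hits[1:]:
        d_prev = cur[-1][0] - cur[-1][1]
        d_here = h[0] - h[1]
        if abs(d_here - d_prev) <= band and abs(h[0] - cur[-1][0]) <= ref_len:
            cur.append(h)
        else:
            clusters.append(cur)
            cur = [h]
    clusters.append(cur)
    out = []
    for cl in clusters:
        # isolated seed hits are almost always chance k-mer collisions
        if len(cl) < min_hits:
            continue
        gs = [g for g, _ in cl]
        rs = [r for _, r in cl]
        out.append((min(gs), max(gs), min(rs), max(rs)))
    return out


def _merge_windows(windows: list[tuple[int, int]], slack: int = 0) -> list[tuple[int, int]]:
    if not windows:
        return []
    windows = sorted(windows)
    merged = [list(windows[0])]
    for s, e in windows[1:]:
        if s <= merged[-1][1] + slack:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _scan_strand(
    seq: str, reference: ReferenceElement, strand: str, seed_k: int
) -> list[_Candidate]:
    ref = reference.sequence
    k = seed_k
    index = _kmer_index(seq, k)
    hits = _seed_hits(index, ref, k)
    pad = 30
    windows = []
    for g_min, g_max, r_min, r_max in _cluster_hits(hits, len(ref)):
        start = max(0, g_min - r_min - pad)
        end = min(len(seq), g_max + k + (len(ref) - r_max - k) + pad)
        windows.append((start, end))
    candidates = []
    for start, end in _merge_windows(windows, slack=50):
        window = seq[start:end]
        if len(window) < seed_k:
            continue
        aln, a_off, b_off = _trim_alignment(
            global_align(window, ref, free_end_gaps_a=True)
        )
        if aln.columns == 0:
            continue
        identity = aln.identity
        coverage = aln.aligned_positions_b() / len(ref)
        # copy interval: genome positions spanned by the aligned core
        g_lo, g_hi = _window_span(aln)
        candidates.append(
            _Candidate(
                interval=Interval(start + a_off + g_lo, start + a_off + g_hi),
                strand=strand,
                identity=identity,
                coverage=coverage,
                alignment=aln,
                window_start=start,
                a_offset=a_off,
                b_offset=b_off,
                reference=reference,
            )
        )
    return candidates


def _window_span(aln: PairwiseAlignment) -> tuple[int, int]:
    """Window coordinates covered by the trimmed alignment core."""
    lo, hi = aln._core_span()
    a = aln.a_aligned
    g_lo = sum(1 for c in a[:lo] if c != GAP)
    g_hi = g_lo + sum(1 for c in a[lo:hi] if c != GAP)
    return g_lo, g_hi


def _project_ref_to_window(aln: PairwiseAlignment, ref_pos: int) -> Optional[int]:
    """Map a reference coordinate (relative to the trimmed alignment) to a
    window coordinate; None when the position lies outside the alignment."""
    if ref_pos < 0:
        return None
    g = 0
    r = 0
    for ca, cb in zip(aln.a_aligned, aln.b_aligned):
        if r == ref_pos and cb != GAP:
            return g
        if ca != GAP:
            g += 1
        if cb != GAP:
            r += 1
    return None


def find_copies(
    genome,
    reference: ReferenceElement,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    seed_k: int = DEFAULT_SEED_K,
) -> list[ElementCopy]:
    """Locate and structurally validate copies of one reference element.

    Returns every scored locus above a loose reporting floor; copies that
    fail a filter carry an explanatory ``status`` and only copies passing
    identity, coverage and termini checks are ``full_length``. Loci on
    both strands are searched; overlaps are resolved in favour of higher
    identity.
    """
    return mine_genome(genome, [reference], min_identity, min_coverage, seed_k)


def mine_genome(
    genome,
    references: Sequence[ReferenceElement],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    seed_k: int = DEFAULT_SEED_K,
) -> list[ElementCopy]:
    """Mine a genome against a panel of references.

    Overlapping hits to multiple references are assigned to the reference
    with the highest identity; ties go to the longer reference.
    """
    if isinstance(genome, str):
        genome = GenomeSequence(id="genome", sequence=genome)
    seq_fwd = genome.sequence
    if not seq_fwd:
        raise ValueError("empty genome")
    seq_rev = reverse_complement(seq_fwd)
    n = len(seq_fwd)

    candidates: list[_Candidate] = []
    for ref in references:
        if len(ref) < 100:
            raise ValueError(f"reference {ref.family_name} shorter than 100 bp")
        if len(ref) < seed_k:
            raise ValueError("reference shorter than seed length")
        candidates.extend(_scan_strand(seq_fwd, ref, "+", seed_k))
        candidates.extend(_scan_strand(seq_rev, ref, "-", seed_k))

    candidates = [
        c
        for c in candidates
        if c.identity >= _REPORT_FLOOR_IDENTITY and c.coverage >= _REPORT_FLOOR_COVERAGE
    ]
    # overlap resolution in genome coordinates: best identity wins
    def genome_interval(c: _Candidate) -> Interval:
        if c.strand == "+":
            return c.interval
        return Interval(n - c.interval.end, n - c.interval.start)

    candidates.sort(
        key=lambda c: (-c.identity, -len(c.reference), genome_interval(c).start)
    )
    kept: list[_Candidate] = []
    for cand in candidates:
        gi = genome_interval(cand)
        clash = False
        for other in kept:
            oi = genome_interval(other)
            if gi.overlap(oi) > 0.25 * min(len(gi), len(oi)):
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: genome_interval(c).start)

    copies = []
    for i, cand in enumerate(kept, start=1):
        oriented = seq_fwd if cand.strand == "+" else seq_rev
        copy = _build_copy(cand, oriented, genome.id, f"{genome.id}_copy_{i}",
                           min_identity, min_coverage)
        if cand.strand == "-":
            copy = _flip_copy(copy, n)
        copies.append(copy)
    return copies


def _build_copy(
    cand: _Candidate,
    oriented_seq: str,
    genome_id: str,
    copy_id: str,
    min_identity: float,
    min_coverage: float,
) -> ElementCopy:
    ref = cand.reference
    copy = ElementCopy(
        copy_id=copy_id,
        genome_id=genome_id,
        family_name=ref.family_name,
        interval=cand.interval,
        strand=cand.strand,
        identity=cand.identity,
        coverage=cand.coverage,
    )
    if cand.identity < min_identity:
        copy.status = REJECTED_IDENTITY
        return copy
    if cand.coverage < min_coverage:
        copy.status = REJECTED_COVERAGE
        return copy
    try:
        ltr5, ltr3 = delimit_ltrs(cand, oriented_seq)
    except ValueError:
        copy.status = REJECTED_COVERAGE
        return copy
    copy.ltr5_interval = ltr5
    copy.ltr3_interval = ltr3
    copy.interval = Interval(ltr5.start, ltr3.end)
    copy.termini_ok = check_termini(copy, oriented_seq)
    if not copy.termini_ok:
        copy.status = REJECTED_TERMINI
        return copy
    copy.status = FULL_LENGTH
    copy.tsd = detect_tsd(oriented_seq, copy)
    return copy


def _flip_copy(copy: ElementCopy, n: int) -> ElementCopy:
    """Map a copy scored on the reverse-complemented genome back to forward
    coordinates. LTR roles stay element-relative (5' LTR first in element
    orientation), so their intervals swap ends on the forward strand."""

    def flip(iv: Optional[Interval]) -> Optional[Interval]:
        if iv is None:
            return None
        return Interval(n - iv.end, n - iv.start)

    copy.interval = flip(copy.interval)
    copy.ltr5_interval = flip(copy.ltr5_interval)
    copy.ltr3_interval = flip(copy.ltr3_interval)
    return copy


def delimit_ltrs(cand: _Candidate, oriented_seq: str) -> tuple[Interval, Interval]:
    """Project reference LTR boundaries onto the copy and refine termini.

    The four boundaries are projected through the alignment; the copy's
    outer boundaries (5' LTR start, 3' LTR end) are then shifted within
    +/-3 bp to land on the TG / CA terminal motifs when present.
    """
    ref = cand.reference
    aln = cand.alignment
    base = cand.window_start + cand.a_offset

    def proj(ref_pos: int) -> int:
        # a boundary base sitting in a gap column projects via the nearest
        # aligned neighbour within the refinement radius
        for off in sorted(range(-3, 4), key=abs):
            g = _project_ref_to_window(aln, ref_pos - cand.b_offset + off)
            if g is not None:
                return base + g - off
        raise ValueError("LTR projection outside copy interval")

    l5s = proj(ref.ltr5_interval.start)
    l5e = proj(ref.ltr5_interval.end - 1) + 1
    l3s = proj(ref.ltr3_interval.start)
    l3e = proj(ref.ltr3_interval.end - 1) + 1
    lo, hi = cand.interval.start, cand.interval.end
    if not (lo <= l5s < l5e <= l3e and l5e <= l3s < l3e <= hi + 3):
        raise ValueError("LTR projection outside copy interval")

    l5s = _refine_start(oriented_seq, l5s)
    l3e = _refine_end(oriented_seq, l3e)
    if l5s >= l5e or l3s >= l3e:
        raise ValueError("degenerate LTR interval after refinement")
    return Interval(l5s, l5e), Interval(l3s, l3e)


def _refine_start(seq: str, pos: int, radius: int = 3) -> int:
    """Nearest offset within +/-radius whose first dinucleotide is TG."""
    best = None
    for off in sorted(range(-radius, radius + 1), key=abs):
        p = pos + off
        if 0 <= p <= len(seq) - 2 and seq[p : p + 2] == "TG":
            best = p
            break
    return best if best is not None else pos


def _refine_end(seq: str, pos: int, radius: int = 3) -> int:
    """Nearest offset within +/-radius whose last dinucleotide is CA."""
    best = None
    for off in sorted(range(-radius, radius + 1), key=abs):
        p = pos + off
        if 2 <= p <= len(seq) and seq[p - 2 : p] == "CA":
            best = p
            break
    return best if best is not None else pos


def check_termini(copy: ElementCopy, seq: str) -> bool:
    """Canonical termini: 5' LTR starts TG, 3' LTR ends CA.

    ``seq`` must be in element orientation (the forward genome for +
    copies, its reverse complement for - copies). N bases never match.
    """
    if copy.ltr5_interval is None or copy.ltr3_interval is None:
        raise ValueError("LTR intervals not set")
    s = copy.ltr5_interval.start
    e = copy.ltr3_interval.end
    return seq[s : s + 2] == "TG" and seq[e - 2 : e] == "CA"


def detect_tsd(
    seq: str, copy: ElementCopy, min_len: int = 4, max_len: int = 6
) -> Optional[str]:
    """Longest exact duplication flanking the copy, ``max_len`` down to
    ``min_len``; None when flanks disagree at every width or the copy
    sits at a contig edge. N bases never match."""
    s, e = copy.interval.start, copy.interval.end
    if s < max_len or e + max_len > len(seq):
        warnings.warn(f"{copy.copy_id}: too close to contig edge for TSD detection")
        return None
    for k in range(max_len, min_len - 1, -1):
        left = seq[s - k : s]
        right = seq[e : e + k]
        if left == right and "N" not in left:
            return left
    return None


def detect_ppt(
    seq: str, copy: ElementCopy, window: int = 50, min_len: int = 10
) -> Optional[Interval]:
    """Longest purine run of >= ``min_len`` within ``window`` bp upstream
    of the 3' LTR (element orientation); None if absent."""
    if copy.ltr3_interval is None:
        raise ValueError("3' LTR interval not set")
    end = copy.ltr3_interval.start
    start = max(0, end - window)
    best: Optional[Interval] = None
    run_start = None
    for i in range(start, end + 1):
        in_run = i < end and seq[i] in "AG"
        if in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            if i - run_start >= min_len and (best is None or i - run_start > len(best)):
                best = Interval(run_start, i)
            run_start = None
    return best


def copy_density(
    copies: Sequence[ElementCopy],
    genome_lengths: dict[str, int],
    window_bp: int,
) -> pd.DataFrame:
    """Full-length copy counts per genomic window (tabular density map)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rows = []
    for gid, length in genome_lengths.items():
        n_windows = max(1, -(-length // window_bp))
        counts = np.zeros(n_windows, dtype=int)
        for copy in copies:
            if copy.genome_id == gid and copy.is_full_length:
                mid = (copy.interval.start + copy.interval.end) // 2
                counts[min(mid // window_bp, n_windows - 1)] += 1
        for w in range(n_windows):
            rows.append(
                {
                    "genome_id": gid,
                    "window_start": w * window_bp,
                    "window_end": min((w + 1) * window_bp, length),
                    "n_copies": int(counts[w]),
                }
            )
    return pd.DataFrame(rows)
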