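"""Family classification, LTR divergence, insertion dating and diversity.

The two LTRs of an element are identical at integration, so the
Kimura two-parameter distance K between them, divided by twice the
per-site substitution rate r, dates the insertion: T = K / 2r with
r = 1.5e-8 substitutions/site/year by default. Families follow the
80-80-80 rule: elements belong to one family when their LTRs share at
least 80 % identity over at least 80 % of the (shorter) LTR, taken as
single-linkage components. Family names are assembled as
``RLC``/``RLG`` (Copia/Gypsy) + "_" + host code + lineage + "_" + index,
e.g. ``RLC_egAle_1``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .alignment import PairwiseAlignment, global_align
from .records import ElementCopy

DEFAULT_RATE = 1.5e-8  # substitutions/site/year

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_ACGT = set("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: substitutions have saturated the signal."""


class NotIntactError(ValueError):
    """Element lacks the two-LTR + TSD structure required for dating."""


@dataclass
class DivergenceEstimate:
    """K2P divergence between two aligned sequences (pairwise deletion)."""

    sites: int
    P: float  # transition proportion
    Q: float  # transversion proportion
    K: float  # substitutions/site

    @property
    def p_distance(self) -> float:
        return self.P + self.Q


@dataclass
class AgeEstimate:
    K: float
    r: float
    T: float  # years


@dataclass
class DiversityStat:
    family_name: str
    n_sequences: int
    Pi: float
    sd: float
    n_pairs: int


@dataclass
class FamilyAssignment:
    member_ids: list[str]
    index: int
    family_name: Optional[str] = None
    superfamily: Optional[str] = None
    lineage: Optional[str] = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class LineageCall:
    lineage: str
    distance: Optional[float]
    ambiguous: bool = False


def align_pair_global(seq_a: str, seq_b: str) -> PairwiseAlignment:
    """Optimal global alignment under the pipeline scoring scheme."""
    return global_align(seq_a, seq_b, free_end_gaps_a=False)


def k2p_from_proportions(P: float, Q: float, sites: int = 0) -> DivergenceEstimate:
    """K2P distance from transition/transversion proportions.

    K = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]; raises ``SaturationError``
    outside the domain of the logarithms.
    """
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError("invalid substitution proportions")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated divergence (P={P:.4f}, Q={Q:.4f})")
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DivergenceEstimate(sites=sites, P=P, Q=Q, K=K + 0.0 if K else 0.0)


def k2p_distance(alignment: PairwiseAlignment) -> DivergenceEstimate:
    """K2P divergence over gap-free, unambiguous columns of an alignment."""
    ts = tv = sites = 0
    for a, b in alignment.gap_free_columns():
        if a not in _ACGT or b not in _ACGT:
            continue
        sites += 1
        if a == b:
            continue
        if (a, b) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no usable (gap-free, unambiguous) columns")
    return k2p_from_proportions(ts / sites, tv / sites, sites)


def insertion_time(K: float, r: float = DEFAULT_RATE) -> AgeEstimate:
    """Insertion age T = K / 2r in years."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if r <= 0:
        raise ValueError("substitution rate must be > 0")
    return AgeEstimate(K=K, r=r, T=K / (2.0 * r))


def date_element(copy: ElementCopy, genome_seq: str, r: float = DEFAULT_RATE) -> AgeEstimate:
    """Date one intact copy from its inter-LTR divergence.

    ``genome_seq`` must be in element orientation (forward genome for +
    copies, reverse complement for - copies, matching the mined
    intervals). Requires the intact criterion: full length with both
    LTRs delimited and a TSD present.
    """
    if not copy.is_intact:
        raise NotIntactError(f"{copy.copy_id} is not intact (needs 2 LTRs + TSD)")
    ltr5 = genome_seq[copy.ltr5_interval.start : copy.ltr5_interval.end]
    ltr3 = genome_seq[copy.ltr3_interval.start : copy.ltr3_interval.end]
    est = k2p_distance(align_pair_global(ltr5, ltr3))
    return insertion_time(est.K, r)


# ---------------------------------------------------------------------------
# 80-80-80 family classification
# ---------------------------------------------------------------------------


def _pair_identity_coverage(a: str, b: str) -> tuple[float, float]:
    aln = align_pair_global(a, b)
    shorter = min(len(a), len(b))
    coverage = aln.aligned_positions_b() / shorter if shorter else 0.0
    return aln.identity, coverage


def assign_families(
    ltr_sequences: dict[str, str],
    id_threshold: float = 0.80,
    cov_threshold: float = 0.80,
) -> list[FamilyAssignment]:
    """Single-linkage families under the 80-80-80 rule.

    Two LTRs are linked when their global alignment reaches
    ``id_threshold`` identity over at least ``cov_threshold`` of the
    shorter LTR. Families are numbered 1..n by descending size, ties by
    lexicographically smallest member id.
    """
    if not ltr_sequences:
        raise ValueError("need at least one sequence")
    graph = nx.Graph()
    graph.add_nodes_from(ltr_sequences)
    for ida, idb in itertools.combinations(sorted(ltr_sequences), 2):
        ident, cov = _pair_identity_coverage(ltr_sequences[ida], ltr_sequences[idb])
        if ident >= id_threshold and cov >= cov_threshold:
            graph.add_edge(ida, idb)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return [
        FamilyAssignment(member_ids=members, index=i)
        for i, members in enumerate(components, start=1)
    ]


def name_family(superfamily: str, host_code: str, lineage: str, index: int) -> str:
    """Standard family name, e.g. (Copia, "eg", "Ale", 1) -> "RLC_egAle_1"."""
    prefixes = {"Copia": "RLC", "Gypsy": "RLG"}
    if superfamily not in prefixes:
        raise ValueError(f"unknown superfamily {superfamily!r}")
    return f"{prefixes[superfamily]}_{host_code}{lineage}_{index}"


def name_families(
    assignments: Sequence[FamilyAssignment],
    superfamily: str,
    host_code: str = "eg",
    lineage: str = "",
) -> list[FamilyAssignment]:
    """Fill in standard names on a list of family assignments in place."""
    for fam in assignments:
        fam.superfamily = superfamily
        fam.lineage = lineage
        fam.family_name = name_family(superfamily, host_code, lineage, fam.index)
    return list(assignments)


def assign_lineage(
    rt_fragment: str,
    reference_panel: Sequence[tuple[str, str]],
    ceiling: float = 0.6,
) -> LineageCall:
    """Nearest-reference lineage call on a reverse-transcriptase fragment.

    The query inherits the lineage of the panel member at minimum K2P
    distance; distances beyond ``ceiling`` (or saturated against every
    panel member) give "unclassified". Exact ties keep the first panel
    member and set the ambiguity flag.
    """
    if not reference_panel:
        raise ValueError("empty reference panel")
    best: Optional[tuple[float, str]] = None
    ambiguous = False
    for lineage, seq in reference_panel:
        try:
            dist = k2p_distance(align_pair_global(rt_fragment, seq)).K
        except SaturationError:
            continue
        if best is None or dist < best[0] - 1e-12:
            best = (dist, lineage)
            ambiguous = False
        elif abs(dist - best[0]) <= 1e-12 and lineage != best[1]:
            ambiguous = True
    if best is None or best[0] > ceiling:
        return LineageCall(lineage="unclassified", distance=None if best is None else best[0])
    return LineageCall(lineage=best[1], distance=best[0], ambiguous=ambiguous)


def ltr_diversity(
    family_ltr_set: dict[str, str], family_name: str = ""
) -> DiversityStat:
    """Average pairwise nucleotide diversity (Pi) of a family's LTRs.

    Pi is the mean over all unordered pairs of the per-pair p-distance
    (differences / gap-free compared sites, pairwise deletion); ``sd`` is
    the sample standard deviation over pairs (0 for a single pair).
    """
    if len(family_ltr_set) < 2:
        raise ValueError("need at least two sequences")
    pdists = []
    for ida, idb in itertools.combinations(sorted(family_ltr_set), 2):
        aln = align_pair_global(family_ltr_set[ida], family_ltr_set[idb])
        diffs = sites = 0
        for a, b in aln.gap_free_columns():
            if a not in _ACGT or b not in _ACGT:
                continue
            sites += 1
            if a != b:
                diffs += 1
        if sites == 0:
            raise ValueError(f"no comparable sites for pair ({ida}, {idb})")
        pdists.append(diffs / sites)
    arr = np.asarray(pdists)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return DiversityStat(
        family_name=family_name,
        n_sequences=len(family_ltr_set),
        Pi=float(arr.mean()),
        sd=sd,
        n_pairs=len(arr),
    )
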