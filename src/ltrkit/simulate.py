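"""Synthetic genomes, Ct tables and marker matrices with known truth.

The generator emulates the three data domains of the study: (a) a
background genome with planted full-length LTR retrotransposon copies of
known family, age, target-site duplication and termini; (b) qPCR /
RT-qPCR Ct tables with configurable amplification efficiency and
Gaussian noise; (c) species-structured dominant-marker band matrices.

Sequence evolution follows the Kimura two-parameter Markov process:
transitions and transversions occur at independent exponential rates,
back-mutations included, so the divergence estimator downstream sees
exactly the model it inverts. LTR termini (the TG..CA dinucleotides) are
exempt from mutation by default so structural checks can be tested
independently of dating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .markers import MarkerMatrix
from .records import Interval, ReferenceElement, TruthRecord

# base encoding: A=0, G=1, C=2, T=3 so that code^1 is the transition
# partner and code^2 / code^3 are the two transversion partners
_BASE_ORDER = "AGCT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASE_ORDER):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(_BASE_ORDER.encode(), dtype="S1")

#: substitution rate used throughout the study, substitutions/site/year
DEFAULT_SUBSTITUTION_RATE = 1.5e-8


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    ``substitution_rate`` (r) is the per-site per-year rate used both to
    evolve planted copies and, downstream, to convert inter-LTR
    divergence into ages (T = K / 2r). ``tsd_length`` fixes the
    target-site duplication length; ``None`` draws uniformly from
    {4, 5, 6}, the canonical LTR-retrotransposon range.
    """

    seed: int = 0
    genome_length: int = 500_000
    gc_content: float = 0.4
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE
    kappa: float = 2.0
    tsd_length: Optional[int] = None
    noise_sd_ct: float = 0.15
    preserve_termini: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.tsd_length is not None and self.tsd_length not in (4, 5, 6):
            raise ValueError("tsd_length must be in {4, 5, 6}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.noise_sd_ct < 0:
            raise ValueError("noise_sd_ct must be >= 0")
        if self.substitution_rate <= 0:
            raise ValueError("substitution_rate must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_background_genome(length: int, gc: float = 0.4, seed=0) -> str:
    """Random i.i.d. background sequence with expected GC fraction ``gc``."""
    if length <= 0:
        raise ValueError("genome length must be > 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = _as_rng(seed)
    # order A, G, C, T to match the internal encoding
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return _DECODE[codes].tobytes().decode()


def k2p_event_probabilities(branch_length: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each single transversion)) after ``branch_length``.

    ``branch_length`` is the expected number of substitution events per
    site; ``kappa`` is the transition/transversion rate ratio alpha/beta.
    Closed-form Kimura transition probabilities of the continuous-time
    chain, so multiple hits and back-mutations are handled exactly.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    # alpha*t + 2*beta*t = branch_length
    beta_t = branch_length / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e4b = math.exp(-4.0 * beta_t)
    e2ab = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 - 0.25 * e4b
    return p_ts, p_tv_each


def evolve_sequence_k2p(
    seq: str,
    branch_length: float,
    kappa: float = 2.0,
    seed=0,
    preserve: Optional[Iterable[int]] = None,
) -> str:
    """Evolve ``seq`` along one branch of the K2P substitution process.

    Sites listed in ``preserve`` are returned unchanged; non-ACGT
    characters are never mutated.
    """
    p_ts, p_tv = k2p_event_probabilities(branch_length, kappa)
    rng = _as_rng(seed)
    codes = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    valid = codes < 4
    u = rng.random(len(codes))
    out = codes.copy()
    ts = valid & (u < p_ts)
    tv1 = valid & (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = valid & (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] ^= 1
    out[tv1] ^= 2
    out[tv2] ^= 3
    if preserve is not None:
        idx = np.asarray(list(preserve), dtype=int)
        if idx.size:
            out[idx] = codes[idx]
    result = np.frombuffer(seq.upper().encode(), dtype="S1").copy()
    result[valid] = _DECODE[out[valid]]
    return result.tobytes().decode()


def make_reference_element(
    family_name: str,
    superfamily: str = "Copia",
    lineage: str = "Ale",
    ltr_length: int = 400,
    internal_length: int = 1500,
    gc: float = 0.4,
    seed=0,
) -> ReferenceElement:
    """Random reference element with identical TG..CA LTRs."""
    if ltr_length < 10 or internal_length < 0:
        raise ValueError("implausible element dimensions")
    rng = _as_rng(seed)
    ltr = "TG" + generate_background_genome(ltr_length - 4, gc, rng) + "CA"
    internal = generate_background_genome(internal_length, gc, rng) if internal_length else ""
    seq = ltr + internal + ltr
    return ReferenceElement(
        family_name=family_name,
        superfamily=superfamily,
        lineage=lineage,
        sequence=seq,
        ltr5_interval=Interval(0, ltr_length),
        ltr3_interval=Interval(len(seq) - ltr_length, len(seq)),
    )


def plant_insertion(
    genome: str,
    reference: ReferenceElement,
    age: float,
    config: SimulationConfig,
    position: Optional[int] = None,
    seed=None,
    copy_id: str = "copy_1",
) -> tuple[str, TruthRecord]:
    """Insert one evolved copy of ``reference`` into ``genome``.

    At insertion the two LTRs are identical; each is then evolved
    independently for ``r * age`` expected substitutions/site (the
    internal region evolves at the same rate), so the expected inter-LTR
    divergence is 2rT. The insertion duplicates the target site.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if reference.ltr5_interval is None or reference.ltr3_interval is None:
        raise ValueError("reference lacks LTR annotation")
    rng = _as_rng(config.seed if seed is None else seed)
    branch = config.substitution_rate * age

    ltr_anc = reference.ltr5
    internal = reference.internal
    nl = len(ltr_anc)
    preserve = (0, 1, nl - 2, nl - 1) if config.preserve_termini else None
    ltr5 = evolve_sequence_k2p(ltr_anc, branch, config.kappa, rng, preserve)
    ltr3 = evolve_sequence_k2p(ltr_anc, branch, config.kappa, rng, preserve)
    internal_ev = evolve_sequence_k2p(internal, branch, config.kappa, rng) if internal else ""
    element = ltr5 + internal_ev + ltr3

    tsd_len = config.tsd_length or int(rng.integers(4, 7))
    if position is None:
        position = int(rng.integers(tsd_len, len(genome) - tsd_len))
    if not tsd_len <= position <= len(genome) - tsd_len:
        raise ValueError("insertion position too close to contig edge")
    tsd = genome[position : position + tsd_len]
    new_genome = genome[: position + tsd_len] + element + genome[position:]

    start = position + tsd_len
    truth = TruthRecord(
        copy_id=copy_id,
        family_name=reference.family_name,
        insertion_age=age,
        genome_interval=Interval(start, start + len(element)),
        tsd_sequence=tsd,
        ltr5_interval=Interval(start, start + nl),
        ltr3_interval=Interval(start + len(element) - nl, start + len(element)),
    )
    return new_genome, truth


def build_synthetic_genome(
    config: SimulationConfig,
    references: Sequence[ReferenceElement],
    copies_per_family: int = 10,
    ages: Optional[Sequence[float]] = None,
    min_spacing: int = 8000,
) -> tuple[str, list[TruthRecord]]:
    """Background genome with non-overlapping planted copies of each family.

    Insertion positions are drawn in the background coordinate system
    with a minimum spacing (nested insertions are out of scope) and ages
    are cycled from ``ages`` (default 0.5-3 Mya range).
    """
    rng = config.rng()
    background = generate_background_genome(config.genome_length, config.gc_content, rng)
    if ages is None:
        ages = [5e5, 1e6, 2e6, 3e6]
    n_total = copies_per_family * len(references)

    margin = 50
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_total:
        attempts += 1
        if attempts > 100 * n_total:
            raise RuntimeError("cannot place insertions with requested spacing")
        pos = int(rng.integers(margin, len(background) - margin))
        if all(abs(pos - p) >= min_spacing for p in positions):
            positions.append(pos)
    positions.sort()

    jobs = []
    k = 0
    for ref in references:
        for _ in range(copies_per_family):
            jobs.append((positions[k], ref, float(ages[k % len(ages)])))
            k += 1
    jobs.sort(key=lambda j: j[0])

    # insert left-to-right, tracking the cumulative coordinate offset
    pieces: list[str] = []
    truths: list[TruthRecord] = []
    cursor = 0
    offset = 0
    for i, (pos, ref, age) in enumerate(jobs, start=1):
        tsd_len = config.tsd_length or int(rng.integers(4, 7))
        branch = config.substitution_rate * age
        ltr_anc = ref.ltr5
        nl = len(ltr_anc)
        preserve = (0, 1, nl - 2, nl - 1) if config.preserve_termini else None
        ltr5 = evolve_sequence_k2p(ltr_anc, branch, config.kappa, rng, preserve)
        ltr3 = evolve_sequence_k2p(ltr_anc, branch, config.kappa, rng, preserve)
        internal = ref.internal
        internal_ev = (
            evolve_sequence_k2p(internal, branch, config.kappa, rng) if internal else ""
        )
        element = ltr5 + internal_ev + ltr3

        tsd = background[pos : pos + tsd_len]
        pieces.append(background[cursor : pos + tsd_len])
        pieces.append(element)
        cursor = pos  # re-emit the target site: duplication
        start = pos + tsd_len + offset
        truths.append(
            TruthRecord(
                copy_id=f"truth_{i}",
                family_name=ref.family_name,
                insertion_age=age,
                genome_interval=Interval(start, start + len(element)),
                tsd_sequence=tsd,
                ltr5_interval=Interval(start, start + nl),
                ltr3_interval=Interval(start + len(element) - nl, start + len(element)),
            )
        )
        offset += len(element) + tsd_len
    pieces.append(background[cursor:])
    return "".join(pieces), truths


# ---------------------------------------------------------------------------
# qPCR / RT-qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    design: pd.DataFrame,
    efficiencies,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed=0,
    baseline_ct: float = 30.0,
) -> pd.DataFrame:
    """Simulate a Ct table from true relative template quantities.

    ``design`` needs columns ``sample``, ``target``, ``quantity`` and may
    carry ``group`` and ``log10_conc``. ``efficiencies`` maps target to
    amplification efficiency E as a fraction in (0, 1.1]. Each design row
    yields ``replicates`` technical replicates with

        Ct = baseline_ct - log(quantity) / log(1 + E) + N(0, noise_sd).
    """
    required = {"sample", "target", "quantity"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design lacks columns {sorted(missing)}")
    if (design["quantity"] <= 0).any():
        raise ValueError("true quantities must be > 0")
    if isinstance(efficiencies, (int, float)):
        efficiencies = {t: float(efficiencies) for t in design["target"].unique()}
    for target, e in efficiencies.items():
        if not 0.0 < e <= 1.1:
            raise ValueError(f"efficiency for {target} outside (0, 1.1]")
    rng = _as_rng(seed)
    rows = []
    for _, row in design.iterrows():
        e = efficiencies[row["target"]]
        ct_true = baseline_ct - math.log(row["quantity"]) / math.log(1.0 + e)
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rec = {
                "sample": row["sample"],
                "group": row.get("group", row["sample"]),
                "target": row["target"],
                "replicate": rep,
                "ct": ct_true + noise,
            }
            if "log10_conc" in design.columns and pd.notna(row.get("log10_conc")):
                rec["log10_conc"] = row["log10_conc"]
            rows.append(rec)
    return pd.DataFrame(rows)


def dilution_series_design(
    target: str,
    concentrations: Sequence[float] = (5e-1, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6),
    reference_conc: Optional[float] = None,
) -> pd.DataFrame:
    """Design table for a standard-curve dilution series.

    Quantities are proportional to concentration (relative to the most
    concentrated point by default), mirroring a serial dilution of a
    cloned template.
    """
    if reference_conc is None:
        reference_conc = max(concentrations)
    rows = [
        {
            "sample": f"dil_{i + 1}",
            "group": "standard",
            "target": target,
            "quantity": c / reference_conc,
            "log10_conc": math.log10(c),
        }
        for i, c in enumerate(concentrations)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dominant-marker matrices
# ---------------------------------------------------------------------------


def simulate_marker_matrix(
    n_species: int,
    n_per_species: int,
    n_loci: int,
    within_species_band_freq: float = 0.9,
    between_species_divergence: float = 0.3,
    seed=0,
    primer_count: int = 1,
) -> MarkerMatrix:
    """Binary band matrix with species structure.

    Each locus is shared by all species with probability
    ``1 - between_species_divergence`` and otherwise private to a single
    random species; where a locus is "on" for a species its individuals
    carry the band with probability ``within_species_band_freq``.
    """
    if n_species <= 0 or n_per_species <= 0 or n_loci <= 0:
        raise ValueError("matrix dimensions must be positive")
    if not (0.0 <= within_species_band_freq <= 1.0 and 0.0 <= between_species_divergence <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = _as_rng(seed)
    species = [f"sp{s + 1}" for s in range(n_species)]
    individuals = [f"{sp}_ind{i + 1}" for sp in species for i in range(n_per_species)]
    sp_of_ind = np.repeat(np.arange(n_species), n_per_species)

    private = rng.random(n_loci) < between_species_divergence
    owner = rng.integers(0, n_species, size=n_loci)
    # locus "on" mask per species
    on = np.ones((n_species, n_loci), dtype=bool)
    on[:, private] = False
    on[owner[private], np.where(private)[0]] = True

    draws = rng.random((len(individuals), n_loci))
    data = (draws < within_species_band_freq) & on[sp_of_ind]

    primers = [f"P{(j % primer_count) + 1}" for j in range(n_loci)]
    loci = [f"{primers[j]}_L{j + 1:04d}" for j in range(n_loci)]
    frame = pd.DataFrame(data.astype(int), index=individuals, columns=loci)
    return MarkerMatrix(
        data=frame,
        species=pd.Series([species[s] for s in sp_of_ind], index=individuals),
        primers=pd.Series(primers, index=loci),
    )
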