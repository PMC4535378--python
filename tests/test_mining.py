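"""Copy mining: recovery of planted elements and structural filters."""

import numpy as np
import pytest

import ltrkit as lk
from ltrkit.mining import _scan_strand, delimit_ltrs, detect_ppt, detect_tsd
from ltrkit.records import (
    FULL_LENGTH,
    REJECTED_COVERAGE,
    ElementCopy,
    Interval,
    reverse_complement,
)


def _overlap_match(copy, truth, tol=5):
    return (
        abs(copy.interval.start - truth.genome_interval.start) <= tol
        and abs(copy.interval.end - truth.genome_interval.end) <= tol
    )


class TestFindCopies:
    def test_exact_copy_found_perfectly(self, reference):
        background = lk.generate_background_genome(8000, 0.4, seed=20)
        genome = background[:4000] + reference.sequence + background[4000:]
        copies = lk.find_copies(genome, reference)
        full = [c for c in copies if c.is_full_length]
        assert len(full) == 1
        assert full[0].identity == 1.0
        assert full[0].coverage == 1.0
        assert full[0].interval == Interval(4000, 4000 + len(reference))

    def test_planted_copies_recovered_with_realized_identity(self, planted_genome, reference):
        genome, truths = planted_genome
        copies = [c for c in lk.find_copies(genome, reference) if c.is_full_length]
        assert len(copies) == len(truths)
        for truth in truths:
            match = [c for c in copies if _overlap_match(c, truth)]
            assert len(match) == 1
            copy = match[0]
            # realized identity from the simulator: count substitutions directly
            planted = genome[truth.genome_interval.start : truth.genome_interval.end]
            realized = sum(
                a == b for a, b in zip(planted, reference.sequence)
            ) / len(reference)
            assert copy.identity == pytest.approx(realized, abs=0.03)
            assert copy.tsd == truth.tsd_sequence

    def test_short_fragment_rejected_for_coverage(self, reference):
        background = lk.generate_background_genome(6000, 0.4, seed=21)
        fragment = reference.sequence[: int(0.7 * len(reference))]
        genome = background[:3000] + fragment + background[3000:]
        copies = lk.find_copies(genome, reference)
        assert not any(c.is_full_length for c in copies)
        assert any(c.status == REJECTED_COVERAGE for c in copies)

    def test_empty_genome_rejected(self, reference):
        with pytest.raises(ValueError):
            lk.find_copies("", reference)

    def test_strand_symmetry(self, planted_genome, reference):
        genome, _ = planted_genome
        n = len(genome)
        fwd = [c for c in lk.find_copies(genome, reference) if c.is_full_length]
        rev = [
            c
            for c in lk.find_copies(reverse_complement(genome), reference)
            if c.is_full_length
        ]
        assert len(fwd) == len(rev)
        mirrored = sorted(
            (n - c.interval.end, n - c.interval.start, c.strand) for c in rev
        )
        original = sorted((c.interval.start, c.interval.end, c.strand) for c in fwd)
        assert [m[:2] for m in mirrored] == [o[:2] for o in original]
        assert all(c.strand == "-" for c in rev)

    def test_full_length_implies_all_filters(self, planted_genome, reference):
        genome, _ = planted_genome
        for c in lk.find_copies(genome, reference):
            if c.is_full_length:
                assert c.identity >= 0.80
                assert c.coverage >= 0.80
                assert c.termini_ok


class TestDelimitAndTermini:
    def test_exact_copy_projection_equals_truth(self, reference):
        background = lk.generate_background_genome(6000, 0.4, seed=22)
        genome = background[:3000] + reference.sequence + background[3000:]
        copies = lk.find_copies(genome, reference)
        copy = next(c for c in copies if c.is_full_length)
        nl = len(reference.ltr5)
        assert copy.ltr5_interval == Interval(3000, 3000 + nl)
        assert copy.ltr3_interval == Interval(
            3000 + len(reference) - nl, 3000 + len(reference)
        )

    def test_boundary_slippage_recovered_by_refinement(self, reference):
        """A copy whose flank mimics the element start 2 bp early still
        yields TG..CA termini at the true boundary."""
        background = lk.generate_background_genome(6000, 0.4, seed=23)
        # force a misleading flank: the 2 bp just before the element are not TG
        left = background[:3000]
        if left[-2:] == "TG":
            left = left[:-2] + "AA"
        genome = left + reference.sequence + background[3000:]
        copy = next(c for c in lk.find_copies(genome, reference) if c.is_full_length)
        assert genome[copy.ltr5_interval.start : copy.ltr5_interval.start + 2] == "TG"
        assert genome[copy.ltr3_interval.end - 2 : copy.ltr3_interval.end] == "CA"

    def test_missing_3prime_ltr_projection_fails(self, reference):
        background = lk.generate_background_genome(6000, 0.4, seed=24)
        nl = len(reference.ltr5)
        fragment = reference.sequence[: len(reference) - nl]  # 3' LTR deleted
        genome = background[:3000] + fragment + background[3000:]
        cands = _scan_strand(genome, reference, "+", 12)
        assert cands
        best = max(cands, key=lambda c: c.identity)
        with pytest.raises(ValueError):
            delimit_ltrs(best, genome)

    def test_check_termini_rejects_non_canonical(self, reference, small_config):
        cfg = lk.SimulationConfig(seed=1, tsd_length=5, preserve_termini=False)
        background = lk.generate_background_genome(6000, 0.4, seed=25)
        # mutate hard enough that termini almost surely break, then verify
        # consistency between the flag and the sequence
        genome, truth = lk.plant_insertion(background, reference, 2e8, cfg, seed=2)
        copies = lk.find_copies(genome, reference)
        for c in copies:
            if c.ltr5_interval is None:
                continue
            expect = (
                genome[c.ltr5_interval.start : c.ltr5_interval.start + 2] == "TG"
                and genome[c.ltr3_interval.end - 2 : c.ltr3_interval.end] == "CA"
            )
            assert c.termini_ok == expect


class TestDetectTsd:
    def _copy(self, start, end):
        return ElementCopy(
            copy_id="c", genome_id="g", family_name="f",
            interval=Interval(start, end), strand="+",
            identity=1.0, coverage=1.0,
        )

    def test_planted_tsd_recovered(self):
        seq = "A" * 20 + "GACCT" + "T" * 30 + "GACCT" + "A" * 20
        copy = self._copy(25, 55)
        assert detect_tsd(seq, copy) == "GACCT"

    def test_longest_match_wins(self):
        # flanks share the 6-mer TTACGT (and therefore also its 4-mer suffix)
        seq = "C" * 20 + "TTACGT" + "G" * 30 + "TTACGT" + "C" * 20
        copy = self._copy(26, 56)
        assert detect_tsd(seq, copy) == "TTACGT"

    def test_unrelated_flanks_absent(self):
        seq = "A" * 20 + "C" * 30 + "G" * 20
        copy = self._copy(20, 50)
        assert detect_tsd(seq, copy) is None

    def test_contig_edge_warns_and_returns_none(self):
        seq = "ACG" + "T" * 30 + "ACGTAA"
        copy = self._copy(3, 33)
        with pytest.warns(UserWarning):
            assert detect_tsd(seq, copy) is None

    def test_matches_brute_force_on_random_fixtures(self):
        """detect_tsd equals an all-k brute-force flank comparison."""
        rng = np.random.default_rng(99)
        bases = "ACGT"
        for _ in range(1000):
            left = "".join(rng.choice(list(bases), 10))
            right = "".join(rng.choice(list(bases), 10))
            mid = "".join(rng.choice(list(bases), 20))
            seq = left + mid + right
            copy = self._copy(10, 30)
            expected = None
            for k in range(6, 3, -1):
                if left[-k:] == right[:k]:
                    expected = left[-k:]
                    break
            assert detect_tsd(seq, copy) == expected


class TestDetectPpt:
    def _copy_with_ltr3(self, ltr3_start, ltr3_end):
        c = ElementCopy(
            copy_id="c", genome_id="g", family_name="f",
            interval=Interval(0, ltr3_end), strand="+",
            identity=1.0, coverage=1.0,
        )
        c.ltr3_interval = Interval(ltr3_start, ltr3_end)
        return c

    def test_planted_tract_found(self):
        seq = "C" * 40 + "AGAGAGAGAGAG" + "CTCTC" + "T" * 20
        copy = self._copy_with_ltr3(57, 77)
        ppt = detect_ppt(seq, copy)
        assert ppt == Interval(40, 52)

    def test_no_long_run_absent(self):
        seq = "CT" * 40
        copy = self._copy_with_ltr3(60, 80)
        assert detect_ppt(seq, copy) is None

    def test_longest_of_two_runs_wins(self):
        seq = "C" * 5 + "A" * 10 + "C" * 3 + "G" * 14 + "C" * 3 + "T" * 20
        copy = self._copy_with_ltr3(35, 55)
        assert detect_ppt(seq, copy) == Interval(18, 32)


class TestCopyDensity:
    def test_zero_copies_all_zero(self):
        table = lk.copy_density([], {"chr1": 10_000}, 1000)
        assert (table["n_copies"] == 0).all()
        assert len(table) == 10

    def test_counts_and_conservation(self, rng):
        for _ in range(25):
            length = int(rng.integers(5_000, 50_000))
            window = int(rng.integers(500, 5_000))
            n = int(rng.integers(0, 20))
            copies = []
            for i in range(n):
                s = int(rng.integers(0, length - 100))
                c = ElementCopy(
                    copy_id=f"c{i}", genome_id="g", family_name="f",
                    interval=Interval(s, s + 100), strand="+",
                    identity=1.0, coverage=1.0,
                )
                c.status = FULL_LENGTH
                copies.append(c)
            table = lk.copy_density(copies, {"g": length}, window)
            assert table["n_copies"].sum() == n

    def test_three_copies_one_window(self):
        copies = []
        for i in range(3):
            c = ElementCopy(
                copy_id=f"c{i}", genome_id="g", family_name="f",
                interval=Interval(100 + i * 10, 200 + i * 10), strand="+",
                identity=1.0, coverage=1.0,
            )
            c.status = FULL_LENGTH
            copies.append(c)
        table = lk.copy_density(copies, {"g": 5000}, 1000)
        assert table.loc[0, "n_copies"] == 3
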