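"""Variant pileup, phasing, reconstruction, de-novo assembly, validation."""

import numpy as np
import pytest

from _util import mutate, random_catalogue
from mhctyper.align import ReadRecord, reverse_complement
from mhctyper.catalogue import Allele, AlleleCatalogue
from mhctyper.novel import (
    AssemblyResult,
    PhasedVariantSet,
    VariantObservation,
    assemble_de_novo,
    phase_variants,
    pileup_variants,
    reconstruct_variant_allele,
    validate_novel,
)


@pytest.fixture
def parent(rng):
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
    return Allele("P*1", seq)


def _placements(parent, starts, subs=(), read_len=61):
    """Oriented read placements on the parent with given substitutions."""
    out = []
    for s in starts:
        seq = list(parent.sequence[s : s + read_len])
        for pos, base in subs:
            if s <= pos < s + read_len:
                seq[pos - s] = base
        out.append(("".join(seq), s))
    return out


class TestPileup:
    def test_concordant_reads_no_variant(self, parent):
        placements = _placements(parent, range(0, 240, 10))
        assert pileup_variants(parent, placements) == []

    def test_half_pileup_variant_detected(self, parent):
        alt = "G" if parent.sequence[120] != "G" else "C"
        ref_reads = _placements(parent, range(70, 121, 2))
        alt_reads = _placements(parent, range(71, 121, 2), [(120, alt)])
        variants = pileup_variants(parent, ref_reads + alt_reads, 3, 0.2)
        assert len(variants) == 1
        v = variants[0]
        assert (v.position, v.ref_base, v.alt_base) == (120, parent.sequence[120], alt)
        assert 0.3 < v.support_fraction < 0.7

    def test_single_mismatch_in_deep_pileup_rejected(self, parent):
        alt = "G" if parent.sequence[120] != "G" else "C"
        reads = _placements(parent, range(70, 120)) + _placements(
            parent, [120 - 30], [(120, alt)]
        )
        assert pileup_variants(parent, reads, 3, 0.2) == []

    def test_support_threshold_is_absolute_and_fractional(self, parent):
        alt = "G" if parent.sequence[50] != "G" else "C"
        # 2 alt reads of 4: fraction fine, support below min_support=3
        reads = _placements(parent, [10, 20], [(50, alt)]) + _placements(
            parent, [15, 25]
        )
        assert pileup_variants(parent, reads, 3, 0.2) == []
        assert len(pileup_variants(parent, reads, 2, 0.2)) == 1


def _var(parent, pos, alt, support=10, depth=20):
    return VariantObservation(parent.allele_id, pos, parent.sequence[pos], alt,
                              support, depth)


class TestPhasing:
    def test_always_co_occurring_variants_form_one_set(self, parent):
        a1 = "G" if parent.sequence[50] != "G" else "C"
        a2 = "G" if parent.sequence[80] != "G" else "C"
        variants = [_var(parent, 50, a1), _var(parent, 80, a2)]
        frags = [
            _placements(parent, [s], [(50, a1), (80, a2)]) for s in (30, 35, 40)
        ]
        sets = phase_variants(variants, frags)
        assert len(sets) == 1
        assert [v.position for v in sets[0].variants] == [50, 80]

    def test_repulsion_keeps_sibling_sets_apart(self, parent):
        a1 = "G" if parent.sequence[50] != "G" else "C"
        a2 = "G" if parent.sequence[80] != "G" else "C"
        variants = [_var(parent, 50, a1), _var(parent, 80, a2)]
        frags = (
            [_placements(parent, [s], [(50, a1)]) for s in (30, 35, 40)]
            + [_placements(parent, [s], [(80, a2)]) for s in (30, 35, 40)]
        )
        sets = phase_variants(variants, frags)
        assert len(sets) == 2
        assert all(len(s.variants) == 1 for s in sets)

    def test_no_variants_empty(self):
        assert phase_variants([], []) == []

    def test_mate_pairs_link_distant_variants(self, parent):
        a1 = "G" if parent.sequence[30] != "G" else "C"
        a2 = "G" if parent.sequence[160] != "G" else "C"
        variants = [_var(parent, 30, a1), _var(parent, 160, a2)]
        # fragments whose mate 1 covers 30 and mate 2 covers 160
        frags = [
            _placements(parent, [10], [(30, a1)]) + _placements(
                parent, [130], [(160, a2)]
            )
            for _ in range(3)
        ]
        sets = phase_variants(variants, frags)
        assert len(sets) == 1
        assert len(sets[0].variants) == 2

    def test_fixed_variants_merge_without_linkage(self, parent):
        a1 = "G" if parent.sequence[30] != "G" else "C"
        a2 = "G" if parent.sequence[250] != "G" else "C"
        # support fraction 1.0 at both, never co-observed
        variants = [
            _var(parent, 30, a1, support=20, depth=20),
            _var(parent, 250, a2, support=18, depth=18),
        ]
        frags = [_placements(parent, [s], [(30, a1)]) for s in (10, 20)] + [
            _placements(parent, [s], [(250, a2)]) for s in (230, 235)
        ]
        sets = phase_variants(variants, frags, hom_fraction=0.8)
        assert len(sets) == 1

    def test_heterozygous_unlinked_variants_stay_apart(self, parent):
        a1 = "G" if parent.sequence[30] != "G" else "C"
        a2 = "G" if parent.sequence[250] != "G" else "C"
        variants = [
            _var(parent, 30, a1, support=10, depth=20),
            _var(parent, 250, a2, support=10, depth=20),
        ]
        assert len(phase_variants(variants, [], hom_fraction=0.8)) == 2

    def test_contradictory_evidence_flags_ambiguous(self, parent):
        a1 = "G" if parent.sequence[50] != "G" else "C"
        a2 = "G" if parent.sequence[80] != "G" else "C"
        variants = [_var(parent, 50, a1), _var(parent, 80, a2)]
        frags = (
            [_placements(parent, [s], [(50, a1), (80, a2)]) for s in (30, 35)]
            + [_placements(parent, [s], [(50, a1)]) for s in (32, 38)]
        )
        sets = phase_variants(variants, frags)
        assert any(s.ambiguous for s in sets)


class TestReconstruct:
    def test_single_substitution(self):
        parent = Allele("P*1", "AAAA")
        phased = PhasedVariantSet("P*1", [VariantObservation("P*1", 1, "A", "C", 5, 9)])
        assert reconstruct_variant_allele(parent, phased) == "ACAA"

    def test_two_variants_hamming_two(self, parent):
        a1 = "G" if parent.sequence[10] != "G" else "C"
        a2 = "G" if parent.sequence[20] != "G" else "C"
        phased = PhasedVariantSet(
            parent.allele_id, [_var(parent, 10, a1), _var(parent, 20, a2)]
        )
        seq = reconstruct_variant_allele(parent, phased)
        assert sum(x != y for x, y in zip(seq, parent.sequence)) == 2

    def test_empty_set_is_error(self, parent):
        with pytest.raises(ValueError):
            reconstruct_variant_allele(parent, PhasedVariantSet(parent.allele_id, []))

    def test_reads_from_reconstruction_align_clean(self, rng, parent):
        from mhctyper.calling import call_alleles_exact

        a1 = "G" if parent.sequence[100] != "G" else "C"
        phased = PhasedVariantSet(parent.allele_id, [_var(parent, 100, a1)])
        novel = reconstruct_variant_allele(parent, phased)
        cat = AlleleCatalogue(alleles=[Allele("N*1", novel)])
        reads = [ReadRecord(f"r{s}", 0, novel[s : s + 61])
                 for s in range(0, len(novel) - 61 + 1, 10)]
        reads.append(ReadRecord("rend", 0, novel[-61:]))
        call, _ = call_alleles_exact(reads, cat)
        assert call.allele_ids == {"N*1"}


def _tiling_reads(seq, step=2, read_len=61):
    reads = [ReadRecord(f"t{i}", 0, seq[s : s + read_len])
             for i, s in enumerate(range(0, len(seq) - read_len + 1, step))]
    reads.append(ReadRecord("tend", 0, seq[-read_len:]))
    return reads


class TestAssembly:
    def test_tiled_novel_assembled_end_to_end(self, rng):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=700))
        reads = _tiling_reads(seq)
        result = assemble_de_novo(reads, reads)
        assert result.ok
        assert result.sequence in (seq, reverse_complement(seq))

    def test_mixed_orientation_reads_assemble(self, rng):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=600))
        reads = []
        for i, s in enumerate(range(0, 540, 2)):
            piece = seq[s : s + 61]
            if i % 2:
                piece = reverse_complement(piece)
            reads.append(ReadRecord(f"m{i}", 0, piece))
        reads.append(ReadRecord("mend", 0, seq[-61:]))
        result = assemble_de_novo(reads, reads)
        assert result.ok
        assert result.sequence in (seq, reverse_complement(seq))

    def test_isolated_seed_is_fragmentary(self, rng):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=61))
        seed_read = [ReadRecord("s", 0, seq)]
        result = assemble_de_novo(seed_read, seed_read)
        assert not result.ok
        assert result.reason == "fragmentary"

    def test_equal_branches_are_ambiguous(self, rng):
        stem = "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
        branch_a = stem + "".join("ACGT"[b] for b in rng.integers(0, 4, size=100))
        branch_b = stem + "".join("TGCA"[b] for b in rng.integers(0, 4, size=100))
        reads = _tiling_reads(branch_a, step=3) + _tiling_reads(branch_b, step=3)
        seeds = [r for r in reads if r.sequence in stem]
        result = assemble_de_novo(seeds, reads)
        assert result.reason == "ambiguous"

    def test_no_seeds_fragmentary(self):
        assert assemble_de_novo([], []).reason == "fragmentary"


class TestValidation:
    def _novel_setup(self, rng):
        cat = random_catalogue(rng, 4, 300)
        parent = cat.get("R01")
        novel = mutate(parent.sequence, 2, rng)
        reads = _tiling_reads(novel, step=5)
        return cat, novel, reads

    def test_reconstructed_novel_accepted_with_coverage(self, rng):
        cat, novel, reads = self._novel_setup(rng)
        ok, reason, _ = validate_novel(novel, cat, reads)
        # random sequences rarely carry an ORF: feature check drives this
        from mhctyper.catalogue import Allele, translate_allele

        report = translate_allele(Allele("c", novel))
        expected = (report.has_orf and not report.early_stop) or (
            report.nonclassical_features
        )
        assert ok == expected
        if not expected:
            assert "reading frame" in reason

    def test_duplicate_of_catalogue_rejected(self, rng):
        cat = random_catalogue(rng, 4, 300)
        seq = cat.get("R02").sequence
        ok, reason, _ = validate_novel(seq, cat, [])
        assert not ok
        assert "duplicate of R02" in reason

    def test_uncovered_candidate_rejected(self, rng):
        cat = random_catalogue(rng, 4, 300)
        novel = mutate(cat.get("R01").sequence, 2, rng)
        reads = _tiling_reads(novel[:200], step=5)  # 3' end never covered
        ok, reason, _ = validate_novel(novel, cat, reads)
        assert not ok
        assert "incomplete coverage" in reason

    def test_acceptance_implies_exact_calling(self, rng):
        """validate_novel acceptance means call_alleles_exact would call the
        candidate on the same reads."""
        from mhctyper.calling import call_alleles_exact
        from mhctyper.simulate import SimConfig, simulate_catalogue, spawn_novel_alleles

        sim_rng = np.random.default_rng(77)
        cat = simulate_catalogue(SimConfig(seed=77), sim_rng)
        nov = spawn_novel_alleles(cat, 1, (2, 2), sim_rng)[0]
        reads = _tiling_reads(nov.sequence, step=4)
        ok, _, _ = validate_novel(nov.sequence, cat, reads)
        assert ok
        probe_cat = AlleleCatalogue(alleles=[Allele("cand", nov.sequence)])
        call, _ = call_alleles_exact(reads, probe_cat)
        assert "cand" in call.allele_ids
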