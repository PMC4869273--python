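"""SNP filtering (HWE exact test), Mendelian checks, haplotype derivation
and SNP flank tracking."""

import collections
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhctyper.pedigree import (
    HaplotypeAssignment,
    Pedigree,
    PedigreeRecord,
    SnpMatrix,
    Violation,
    check_mendelian,
    check_snp_trios,
    derive_haplotypes,
    filter_snps,
    gene_copy_counts,
    hwe_exact_p,
    snp_haplotype_tracking,
)
from mhctyper.simulate import (
    SimConfig,
    simulate_catalogue,
    simulate_family,
    spawn_novel_alleles,
)


def hwe_oracle(n_aa, n_ab, n_bb):
    """Brute-force exact test: enumerate heterozygote counts conditional on
    the allele counts with explicit factorials."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a

    from fractions import Fraction

    def prob(het):
        hom_a = (n_a - het) // 2
        hom_b = n - hom_a - het
        return Fraction(
            math.factorial(n) * 2**het * math.factorial(n_a) * math.factorial(n_b),
            math.factorial(hom_a) * math.factorial(hom_b) * math.factorial(het)
            * math.factorial(2 * n),
        )

    probs = {h: prob(h) for h in range(n_a % 2, min(n_a, n_b) + 1, 2)}
    p_obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    @pytest.mark.parametrize(
        "counts", [(10, 80, 10), (25, 50, 25), (40, 20, 40), (5, 0, 5), (0, 10, 0)]
    )
    def test_matches_brute_force_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_property_matches_oracle_and_is_probability(self, aa, ab, bb):
        p = hwe_exact_p(aa, ab, bb)
        assert 0.0 <= p <= 1.0
        if aa + ab + bb > 0:
            assert p == pytest.approx(hwe_oracle(aa, ab, bb), rel=1e-9)

    def test_excess_heterozygosity_rejected(self):
        assert hwe_exact_p(0, 100, 0) < 0.001
        assert hwe_exact_p(26, 48, 26) > 0.05


def _matrix(rows):
    return SnpMatrix(pd.DataFrame(rows))


class TestFilterSnps:
    REGION = (1_000, 9_000)

    def _base_row(self, snp_id, pos, genos):
        row = {"snp_id": snp_id, "chrom": "23", "pos": pos}
        row.update(genos)
        return row

    def test_monomorphic_removed(self):
        inds = {f"i{k}": "AA" for k in range(10)}
        m = _matrix([self._base_row("s1", 5000, inds)])
        assert len(filter_snps(m, self.REGION)) == 0

    def test_position_outside_region_removed(self):
        inds = {f"i{k}": ("AB" if k % 2 else "AA") for k in range(10)}
        m = _matrix([self._base_row("s1", 20_000, inds)])
        assert len(filter_snps(m, self.REGION)) == 0

    def test_low_call_rate_removed(self):
        genos = {f"i{k}": ("AB" if k % 2 else "AA") for k in range(10)}
        genos["i0"] = "--"
        m = _matrix([self._base_row("s1", 5000, genos)])
        assert len(filter_snps(m, self.REGION, call_rate_min=0.98)) == 0

    def test_hwe_outlier_removed_on_founders(self):
        # all founders heterozygous: extreme HWE departure
        founders = [f"f{k}" for k in range(20)]
        genos = dict.fromkeys(founders, "AB")
        m = _matrix([self._base_row("s1", 5000, genos)])
        kept = filter_snps(m, self.REGION, hwe_p_min=0.001, founders=founders)
        assert len(kept) == 0

    def test_good_snp_retained_and_filter_idempotent(self):
        rng = np.random.default_rng(9)
        genos = {
            f"i{k}": np.random.default_rng(k).choice(
                ["AA", "AB", "BB"], p=[0.25, 0.5, 0.25]
            )
            for k in range(40)
        }
        m = _matrix([self._base_row("s1", 5000, genos),
                     self._base_row("s2", 6000, genos)])
        once = filter_snps(m, self.REGION)
        twice = filter_snps(once, self.REGION)
        assert len(once) == 2
        pd.testing.assert_frame_equal(once.table, twice.table)


def _family_truth(seed, n_novel=1):
    cfg = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    cat = simulate_catalogue(cfg, rng)
    novels = spawn_novel_alleles(cat, n_novel, (1, 3), rng)
    truth = simulate_family(cat, novels, cfg, rng)
    return cat, truth


class TestMendelian:
    def test_simulated_family_has_zero_violations(self):
        _, truth = _family_truth(101)
        assert check_mendelian(truth.pedigree, truth.genotypes) == []

    def test_orphan_allele_named_in_violation(self):
        _, truth = _family_truth(101)
        genotypes = {k: set(v) for k, v in truth.genotypes.items()}
        offspring = next(k for k in genotypes if k.startswith("F2"))
        genotypes[offspring].add("GHOST*999")
        violations = check_mendelian(truth.pedigree, genotypes)
        assert any("GHOST*999" in v.detail for v in violations)

    def test_injected_allele_swap_always_detected(self):
        """Replacing one offspring allele with a non-parental one must
        produce at least one violation (sensitivity)."""
        for seed in range(10):
            cat, truth = _family_truth(200 + seed)
            genotypes = {k: set(v) for k, v in truth.genotypes.items()}
            offspring = sorted(k for k in genotypes if k.startswith("F2"))[0]
            parental = genotypes["SIRE"] | genotypes["DAM1"]
            foreign = next(
                (a for a in cat.ids if a not in parental), "FOREIGN*999"
            )
            rng = np.random.default_rng(seed)
            victim = sorted(genotypes[offspring])[
                int(rng.integers(len(genotypes[offspring])))
            ]
            genotypes[offspring] = (genotypes[offspring] - {victim}) | {foreign}
            assert check_mendelian(truth.pedigree, genotypes)

    def test_snp_trio_textbook_case(self):
        ped = Pedigree([
            PedigreeRecord("S", None, None), PedigreeRecord("D", None, None),
            PedigreeRecord("O", "S", "D"),
        ])
        m = SnpMatrix(pd.DataFrame([
            {"snp_id": "s1", "chrom": "23", "pos": 100, "S": "AA", "D": "AA",
             "O": "AB"},
            {"snp_id": "s2", "chrom": "23", "pos": 200, "S": "AA", "D": "BB",
             "O": "AB"},
        ]))
        violations = check_snp_trios(ped, m)
        assert len(violations) == 1
        assert "s1" in violations[0].detail

    def test_simulated_snps_trio_clean(self):
        _, truth = _family_truth(103)
        assert check_snp_trios(truth.pedigree, truth.snps) == []


class TestDeriveHaplotypes:
    def test_recovers_founder_haplotypes_up_to_label_swap(self):
        for seed in range(8):
            _, truth = _family_truth(300 + seed)
            derived = derive_haplotypes(truth.pedigree, truth.genotypes)
            assert isinstance(derived, HaplotypeAssignment)
            assert derived.status == "resolved"
            assert {derived.paternal[0], derived.paternal[1]} == {
                truth.haplotypes["P1"], truth.haplotypes["P2"]
            }
            assert {derived.maternal[0], derived.maternal[1]} == {
                truth.haplotypes["M1"], truth.haplotypes["M2"]
            }

    def test_offspring_fall_into_at_most_four_classes(self):
        _, truth = _family_truth(301)
        derived = derive_haplotypes(truth.pedigree, truth.genotypes)
        assert len(set(derived.offspring_labels.values())) <= 4

    def test_identical_sibs_with_shared_parental_allele_unresolvable(self):
        """A cross-parent shared allele cannot be attributed to one side from
        identical sibs: every co-optimal split is reported, none chosen."""
        ped = Pedigree([
            PedigreeRecord("S", None, None), PedigreeRecord("D", None, None),
            PedigreeRecord("O1", "S", "D"), PedigreeRecord("O2", "S", "D"),
        ])
        genotypes = {
            "S": {"a", "x"}, "D": {"c", "x"},
            "O1": {"a", "x", "c"}, "O2": {"a", "x", "c"},
        }
        derived = derive_haplotypes(ped, genotypes)
        assert derived.status == "unresolvable"
        assert derived.n_solutions > 1

    def test_inconsistent_family_returns_violations(self):
        ped = Pedigree([
            PedigreeRecord("S", None, None), PedigreeRecord("D", None, None),
            PedigreeRecord("O1", "S", "D"), PedigreeRecord("O2", "S", "D"),
        ])
        genotypes = {
            "S": {"a", "b"}, "D": {"c", "d"},
            "O1": {"a", "c"}, "O2": {"x", "d"},
        }
        out = derive_haplotypes(ped, genotypes)
        assert isinstance(out, list)
        assert all(isinstance(v, Violation) for v in out)

    def test_duplicated_gene_haplotype_supported(self):
        ped = Pedigree([
            PedigreeRecord("S", None, None), PedigreeRecord("D", None, None),
            PedigreeRecord("O1", "S", "D"), PedigreeRecord("O2", "S", "D"),
            PedigreeRecord("O3", "S", "D"), PedigreeRecord("O4", "S", "D"),
        ])
        # paternal haplotype P1 carries three NC2 alleles (gene duplication)
        p1 = frozenset({"NC2*a", "NC2*b", "NC2*c", "1*a"})
        p2 = frozenset({"2*a", "NC3*a"})
        m1 = frozenset({"3*a", "NC4*a"})
        m2 = frozenset({"1*b", "NC2*d"})
        genotypes = {
            "S": set(p1 | p2), "D": set(m1 | m2),
            "O1": set(p1 | m1), "O2": set(p1 | m2),
            "O3": set(p2 | m1), "O4": set(p2 | m2),
        }
        derived = derive_haplotypes(ped, genotypes)
        assert derived.status == "resolved"
        recovered = {derived.paternal[0], derived.paternal[1]}
        assert p1 in recovered
        gene_of = {a: a.split("*")[0] for a in p1}
        assert gene_copy_counts(p1, gene_of)["NC2"] == 3

    def test_mhc_haplotype_mode_flags_unexplainable_offspring(self):
        _, truth = _family_truth(302)
        derived = derive_haplotypes(truth.pedigree, truth.genotypes)
        genotypes = {k: set(v) for k, v in truth.genotypes.items()}
        offspring = sorted(k for k in genotypes if k.startswith("F2"))[0]
        # give the offspring a chimeric mix spanning three haplotypes
        genotypes[offspring] = set(
            truth.haplotypes["P1"] | truth.haplotypes["P2"] | truth.haplotypes["M1"]
        )
        violations = check_mendelian(truth.pedigree, genotypes, derived)
        assert any(v.kind == "mhc_haplotype" for v in violations)


class TestSnpTracking:
    def test_flank_classes_match_simulated_transmissions(self):
        for seed in range(6):
            _, truth = _family_truth(400 + seed)
            filtered = filter_snps(
                truth.snps, (27_545_231, 30_222_836),
                founders=truth.pedigree.founders(),
            )
            track = snp_haplotype_tracking(filtered, truth.pedigree)
            snp_classes = collections.defaultdict(set)
            for _, row in track.iterrows():
                snp_classes[(row["paternal_flank"], row["maternal_flank"])].add(
                    row["individual"]
                )
            mhc_classes = collections.defaultdict(set)
            for ind, tr in truth.transmissions.items():
                if ind.startswith("F2"):
                    mhc_classes[tr].add(ind)
            assert sorted(map(sorted, snp_classes.values())) == sorted(
                map(sorted, mhc_classes.values())
            )

    def test_uninformative_family_yields_empty_labels(self):
        ped = Pedigree([
            PedigreeRecord("S", None, None), PedigreeRecord("D", None, None),
            PedigreeRecord("O1", "S", "D"), PedigreeRecord("O2", "S", "D"),
        ])
        m = SnpMatrix(pd.DataFrame([
            {"snp_id": "s1", "chrom": "23", "pos": 100,
             "S": "AA", "D": "AA", "O1": "AA", "O2": "AA"},
        ]))
        track = snp_haplotype_tracking(m, ped)
        assert (track["paternal_flank"] == "").all()
        assert (track["maternal_flank"] == "").all()


def test_pedigree_rejects_self_ancestry():
    with pytest.raises(ValueError, match="ancestor"):
        Pedigree([
            PedigreeRecord("A", "B", None),
            PedigreeRecord("B", "A", None),
        ])
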