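"""Generator contracts: truth consistency, determinism, mutation statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from macrosat import seqsim
from macrosat._seq import random_dna, revcomp
from macrosat.seqsim import (
    AllelicSimSpec,
    ArraySpec,
    BisulfiteSimSpec,
    SpeciesSimSpec,
    cpg_sites,
    design_monomer_template,
)


def small_array_spec(seed=0, copies=(1, 1, 1), divergence=0.0, template_len=600, unit_len=120):
    rng = np.random.default_rng(99)
    template, unit = design_monomer_template(template_len, unit_len, 200, rng)
    return ArraySpec(
        monomer_template=template,
        copy_count=len(copies),
        vntr_unit=unit,
        vntr_insert_position=200,
        vntr_copies=list(copies),
        divergence=divergence,
        seed=seed,
    )


class TestGenerateArray:
    def test_zero_mutation_identity(self):
        spec = small_array_spec(copies=(1, 1, 1))
        array, truth = seqsim.generate_array(spec)
        assert len(array) == 3 * 600
        monomers = {array[a:b] for a, b in truth.monomer_intervals}
        assert monomers == {spec.monomer_template}
        # intervals tile the array
        assert truth.monomer_intervals[0][0] == 0
        assert truth.monomer_intervals[-1][1] == len(array)
        for (a, b), (c, d) in zip(truth.monomer_intervals, truth.monomer_intervals[1:]):
            assert b == c

    def test_length_arithmetic_with_vntr_expansion(self):
        copies = [2, 1, 3, 2, 1, 2, 3]
        spec = small_array_spec(copies=copies)
        array, truth = seqsim.generate_array(spec)
        expected = sum(600 + (c - 1) * 120 for c in copies)
        assert len(array) == expected
        for (a, b), c in zip(truth.monomer_intervals, copies):
            assert b - a == 600 + (c - 1) * 120

    def test_substitution_counts_binomial(self):
        # aggregate mismatch count across 100 seeds within 3 SD of the
        # binomial expectation at rate divergence/2 per monomer
        d = 0.05
        total = 0
        n_bases = 0
        for seed in range(100):
            spec = small_array_spec(seed=seed, copies=(1,), divergence=d)
            array, truth = seqsim.generate_array(spec)
            total += sum(
                1 for a, b in zip(array, spec.monomer_template) if a != b
            )
            n_bases += len(array)
        p = d / 2
        sd = np.sqrt(n_bases * p * (1 - p))
        assert abs(total - n_bases * p) < 3 * sd

    def test_recorded_variant_positions_are_exact(self):
        spec = small_array_spec(seed=3, copies=(2, 1), divergence=0.05)
        array, truth = seqsim.generate_array(spec)
        for (a, b), subs, c in zip(
            truth.monomer_intervals, truth.variant_positions, spec.vntr_copies
        ):
            expanded = (
                spec.monomer_template[:200]
                + spec.vntr_unit * (c - 1)
                + spec.monomer_template[200:]
            )
            observed = {
                i for i, (x, y) in enumerate(zip(array[a:b], expanded)) if x != y
            }
            assert observed == set(subs.tolist())

    def test_determinism(self):
        spec = small_array_spec(seed=5, copies=(2, 1, 3), divergence=0.05)
        a1, t1 = seqsim.generate_array(spec)
        a2, t2 = seqsim.generate_array(spec)
        assert a1 == a2
        assert t1.monomer_intervals == t2.monomer_intervals
        assert all(
            (x == y).all() for x, y in zip(t1.variant_positions, t2.variant_positions)
        )

    @pytest.mark.parametrize(
        "override,field",
        [
            ({"vntr_copies": [1, 1]}, "vntr_copies"),
            ({"vntr_copies": [1, 0, 1]}, "vntr_copies"),
            ({"divergence": 1.5}, "divergence"),
            ({"vntr_insert_position": 10_000}, "vntr_insert_position"),
        ],
    )
    def test_invalid_spec_names_field(self, override, field):
        kwargs = dict(
            monomer_template=small_array_spec().monomer_template,
            copy_count=3,
            vntr_unit=small_array_spec().vntr_unit,
            vntr_insert_position=200,
            vntr_copies=[1, 1, 1],
        )
        kwargs.update(override)
        with pytest.raises(ValueError, match=field):
            ArraySpec(**kwargs)


class TestPlantFeatures:
    def test_verbatim_recovery(self):
        rng = np.random.default_rng(0)
        feature = random_dna(1000, rng)
        genome, rows = seqsim.plant_features(20_000, [(feature, 5000)], seed=1)
        assert genome[5000:6000] == feature
        assert rows == [(5000, 6000, "feature_0")]

    def test_rows_sorted_by_start(self):
        rng = np.random.default_rng(0)
        f1, f2 = random_dna(100, rng), random_dna(100, rng)
        genome, rows = seqsim.plant_features(5000, [(f2, 3000), (f1, 1000)], seed=1)
        assert [r[0] for r in rows] == [1000, 3000]
        assert len(rows) == 2

    def test_overlap_rejected_with_offenders_listed(self):
        rng = np.random.default_rng(0)
        f = random_dna(500, rng)
        with pytest.raises(ValueError, match="overlap"):
            seqsim.plant_features(5000, [(f, 1000), (f, 1200)], seed=1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            seqsim.plant_features(500, [("ACGT" * 200, 0)], seed=1)


class TestBisulfiteSim:
    def reference(self):
        from conftest import make_cpg_reference

        return make_cpg_reference(30, seed=0)

    def test_full_methylation_full_conversion(self):
        ref = self.reference()
        sites = set(cpg_sites(ref).tolist())
        sim = seqsim.simulate_bisulfite_clones(
            BisulfiteSimSpec(ref, {"g": 1.0}, clones_per_group=3, seed=0)
        )
        for clone in sim["g"]:
            for i, (r, c) in enumerate(zip(ref, clone.sequence)):
                if i in sites:
                    assert c == "C"
                elif r == "C":
                    assert c == "T"
                else:
                    assert c == r

    def test_zero_methylation_reads_t_everywhere(self):
        ref = self.reference()
        sim = seqsim.simulate_bisulfite_clones(
            BisulfiteSimSpec(ref, {"g": 0.0}, clones_per_group=3, seed=0)
        )
        for clone in sim["g"]:
            for pos in cpg_sites(ref):
                assert clone.sequence[pos] == "T"
            assert all(s == seqsim.UNMETHYLATED for s in clone.truth_states)

    def test_half_methylation_binomial(self):
        ref = self.reference()
        sim = seqsim.simulate_bisulfite_clones(
            BisulfiteSimSpec(ref, {"g": 0.5}, clones_per_group=20, seed=0)
        )
        n = 30 * 20
        meth = sum(
            c.truth_states.count(seqsim.METHYLATED) for c in sim["g"]
        )
        assert abs(meth - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_cpg_destroying_variants_are_non_cpg_after_conversion(self):
        ref = self.reference()
        sim = seqsim.simulate_bisulfite_clones(
            BisulfiteSimSpec(ref, {"g": 0.5}, clones_per_group=10, variant_prob=0.3, seed=0)
        )
        saw_variant = False
        for clone in sim["g"]:
            for pos, state in zip(cpg_sites(ref), clone.truth_states):
                if state == seqsim.ABSENT:
                    saw_variant = True
                    assert clone.sequence[pos] in "AG"
        assert saw_variant


class TestAllelicSim:
    def spec(self, **kw):
        rng = np.random.default_rng(5)
        ref = random_dna(500, rng)
        snps = [(50, ref[50], "ACGT"[("ACGT".index(ref[50]) + 1) % 4]),
                (250, ref[250], "ACGT"[("ACGT".index(ref[250]) + 2) % 4])]
        defaults = dict(reference=ref, snp_table=snps, allelic_ratio=0.5,
                        read_length=100, n_reads=200, error_rate=0.0, seed=0)
        defaults.update(kw)
        return AllelicSimSpec(**defaults)

    def test_error_free_reads_are_haplotype_substrings(self):
        hap_a, hap_b, reads = seqsim.simulate_allelic_reads(self.spec())
        for r in reads:
            src = hap_a if r.truth_label == "A" else hap_b
            assert r.sequence == src[r.start : r.start + 100]

    def test_ratio_one_gives_all_a(self):
        _, _, reads = seqsim.simulate_allelic_reads(self.spec(allelic_ratio=1.0))
        assert all(r.truth_label == "A" for r in reads)

    def test_error_rate_binomial(self):
        spec = self.spec(error_rate=0.01, n_reads=1000)
        hap_a, hap_b, reads = seqsim.simulate_allelic_reads(spec)
        total = sum(
            sum(1 for x, y in zip(r.sequence,
                                  (hap_a if r.truth_label == "A" else hap_b)[r.start:r.start+100])
                if x != y)
            for r in reads
        )
        n = 1000 * 100
        assert abs(total - n * 0.01) < 3 * np.sqrt(n * 0.01 * 0.99)

    def test_read_longer_than_reference_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            self.spec(read_length=10_000)


class TestSpeciesSim:
    def test_zero_divergence_identical(self):
        rng = np.random.default_rng(2)
        anc = random_dna(143, rng)
        out = seqsim.simulate_species_monomers(
            SpeciesSimSpec(anc, per_species_divergence=0.0, conserved_interval=(59, 93), seed=0)
        )
        assert all(s == anc for _, s in out)

    def test_conserved_core_invariant(self):
        rng = np.random.default_rng(2)
        anc = random_dna(143, rng)
        out = seqsim.simulate_species_monomers(
            SpeciesSimSpec(anc, per_species_divergence=0.4, conserved_interval=(59, 93), seed=1)
        )
        cores = {s[59:93] for _, s in out}
        assert cores == {anc[59:93]}

    def test_pairwise_identity_matches_closed_form(self):
        # identity outside the core between two copies mutated at rate q:
        # (1-q)^2 + q^2/3
        q = 0.15
        rng = np.random.default_rng(3)
        anc = random_dna(400, rng)
        out = seqsim.simulate_species_monomers(
            SpeciesSimSpec(anc, n_species=25, per_species_divergence=q,
                           conserved_interval=(0, 0), seed=2)
        )
        seqs = [s for _, s in out]
        ident = []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                ident.append(np.mean([a == b for a, b in zip(seqs[i], seqs[j])]))
        expected = (1 - q) ** 2 + q**2 / 3
        assert abs(np.mean(ident) - expected) < 0.02

    def test_core_outside_monomer_rejected(self):
        with pytest.raises(ValueError, match="conserved_interval"):
            SpeciesSimSpec("ACGT" * 10, conserved_interval=(30, 60))


@given(st.integers(0, 10_000))
def test_determinism_across_generators(seed):
    """Identical spec + seed gives byte-identical output for every generator."""
    spec = small_array_spec(seed=seed % 50, copies=(2, 1), divergence=0.05)
    assert seqsim.generate_array(spec)[0] == seqsim.generate_array(spec)[0]


def test_revcomp_involution():
    rng = np.random.default_rng(0)
    s = random_dna(500, rng)
    assert revcomp(revcomp(s)) == s
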