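"""Mutation cataloguing: coding-effect classification, hybrid-mode
catalogues, sharing classes, and outgroup/frequency polarization."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from allelecall.alignment_io import (
    AlignedHaplotype,
    GeneRegionMap,
    HaplotypeAlignment,
    Region,
)
from allelecall.alleles import SiteDifference, call_alleles
from allelecall.coding import CodingFrame
from allelecall.errors import PreconditionError
from allelecall.mutations import (
    MutationRecord,
    classify_coding_effect,
    hybrid_mode_mutations,
    polarize_with_outgroup,
    sharing_class,
)
from conftest import small_config
from allelecall.simulate import SimulationConfig, simulate

BASES = "ACGT"
NONSTOP = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if str(Seq(a + b + c).translate()) != "*"
]


def frame_for(cds):
    rm = GeneRegionMap("L", [Region("exon", 0, 0, len(cds))])
    return CodingFrame(rm, AlignedHaplotype("ref", cds, "parent_a"))


def sub_event(column, ref_base, alt_base):
    return SiteDifference(
        column=column,
        kind="substitution",
        region_type="exon",
        state_1=ref_base,
        state_2=alt_base,
    )


class TestClassifyCodingEffect:
    def test_synonymous_third_position(self):
        frame = frame_for("GAA")
        assert classify_coding_effect(sub_event(2, "A", "G"), frame) == "synonymous"

    def test_nonsense(self):
        frame = frame_for("TGG")
        assert classify_coding_effect(sub_event(1, "G", "A"), frame) == "nonsense"

    def test_frameshift_vs_inframe_indel(self):
        indel1 = SiteDifference(0, "indel", length=1, region_type="exon",
                                state_1="-", state_2="A")
        indel3 = SiteDifference(0, "indel", length=3, region_type="exon",
                                state_1="---", state_2="ACG")
        frame = frame_for("ATGAAA")
        assert classify_coding_effect(indel1, frame) == "frameshift"
        assert classify_coding_effect(indel3, frame) == "nonsynonymous"

    def test_outside_exon_is_precondition_error(self):
        event = SiteDifference(0, "substitution", region_type="intron")
        with pytest.raises(PreconditionError):
            classify_coding_effect(event, frame_for("ATG"))

    def test_matches_translation_comparison_on_all_single_edits(self):
        # every single-base change of 40 random codons vs full-translation
        # comparison through Biopython
        rng = np.random.default_rng(5)
        codons = [NONSTOP[i] for i in rng.integers(0, len(NONSTOP), 40)]
        for codon in codons:
            frame = frame_for(codon)
            ref_aa = str(Seq(codon).translate())
            for pos, alt in itertools.product(range(3), BASES):
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                alt_aa = str(Seq(mutant).translate())
                expected = (
                    "synonymous"
                    if alt_aa == ref_aa
                    else "nonsense" if alt_aa == "*" else "nonsynonymous"
                )
                got = classify_coding_effect(sub_event(pos, codon[pos], alt), frame)
                assert got == expected


class TestHybridMode:
    def test_hybrid_identical_to_parent_has_no_mutations(self):
        pa = AlignedHaplotype("pa", "ACGTAC", "parent_a")
        pb = AlignedHaplotype("pb", "ACTTAC", "parent_b")
        hyb = AlignedHaplotype("h1", "ACGTAC", "hybrid")
        aln = HaplotypeAlignment([hyb, pa, pb])
        rm = GeneRegionMap("L", [Region("five_prime", 0, 0, 6)])
        alleles = call_alleles(aln, rm)
        assert hybrid_mode_mutations(alleles, aln, rm) == []

    def test_recovers_planted_events(self):
        for seed in (1, 5):
            aln, rm, truth = simulate(
                small_config(
                    seed=seed,
                    derived_per_region={"five_prime": 1, "exon": 2},
                    derived_deletions_per_allele=1,
                )
            )
            alleles = call_alleles(aln, rm)
            catalog = hybrid_mode_mutations(alleles, aln, rm)
            truth_name_to_called = {}
            for t_name, members in truth.allele_members.items():
                truth_name_to_called[t_name] = alleles.allele_of(members[0])
            got = {
                (r.anchor_column, r.kind, frozenset(r.carrier_alleles))
                for r in catalog
            }
            want = {
                (
                    e.column,
                    e.kind,
                    frozenset(
                        truth_name_to_called[a] for a in e.carrier_alleles
                    ),
                )
                for e in truth.derived_events()
            }
            assert got == want
            # planted coding effects agree
            effect_by_col = {r.anchor_column: r.coding_effect for r in catalog}
            for e in truth.derived_events():
                if e.region_type == "exon" and e.kind == "substitution":
                    assert effect_by_col[e.column] == e.coding_effect

    def test_shared_event_counts_once_with_all_carriers(self):
        aln, rm, truth = simulate(
            small_config(seed=3, n_shared_five_prime=2, derived_per_region={})
        )
        alleles = call_alleles(aln, rm)
        catalog = hybrid_mode_mutations(alleles, aln, rm)
        shared = [r for r in catalog if len(r.carrier_alleles) == alleles.n_alleles]
        assert len(shared) == 2
        assert len(catalog) == 2

    def test_mutation_columns_have_neither_origin(self, default_sim):
        from allelecall.painting import informative_sites, paint

        aln, rm, _ = default_sim
        alleles = call_alleles(aln, rm)
        catalog = hybrid_mode_mutations(alleles, aln, rm)
        for record in catalog:
            carrier = sorted(record.carrier_alleles)[0]
            rep = aln[alleles.alleles[carrier].representative]
            informative = {
                s.column: s.origin
                for s in informative_sites(rep, aln.parent_a, aln.parent_b)
            }
            for c in range(record.anchor_column, record.anchor_column + record.length):
                if c in informative:
                    assert informative[c] == "neither"

    def test_missing_parent_is_error(self, small_sim):
        aln, rm, _ = small_sim
        no_pb = HaplotypeAlignment(
            [m for m in aln.members if m.taxon_role != "parent_b"]
        )
        alleles = call_alleles(no_pb, rm)
        with pytest.raises(PreconditionError):
            hybrid_mode_mutations(alleles, no_pb, rm)


class TestSharing:
    def record(self, carriers):
        return MutationRecord(
            id="m1",
            locus="L",
            anchor_column=0,
            kind="substitution",
            region_type="five_prime",
            carrier_alleles=frozenset(carriers),
        )

    def test_single_carrier_private(self):
        assert sharing_class(self.record({"a"}), {"a": "indica"}) == "private"

    def test_multiple_carriers_one_subgroup(self):
        got = sharing_class(
            self.record({"a", "b"}), {"a": "indica", "b": "indica"}
        )
        assert got == "shared_within_subgroup"

    def test_carriers_across_subgroups(self):
        got = sharing_class(
            self.record({"a", "b"}), {"a": "indica", "b": "japonica"}
        )
        assert got == "shared_across_subgroups"

    def test_unlabeled_carrier_is_error(self):
        with pytest.raises(PreconditionError):
            sharing_class(self.record({"a"}), {"a": None})

    def test_synthetic_catalogue_sharing_matches_truth(self):
        aln, rm, truth = simulate(small_config(seed=8, n_shared_five_prime=1))
        alleles = call_alleles(aln, rm)
        catalog = hybrid_mode_mutations(alleles, aln, rm)
        for record in catalog:
            if len(record.carrier_alleles) == 1:
                assert record.sharing == "private"
            else:
                # the shared event spans both configured subgroups
                assert record.sharing == "shared_across_subgroups"


def conspecific_config(**overrides):
    base = dict(
        seed=0,
        n_hybrid_alleles=10,
        members_per_allele=1,
        parental_divergence=0.0,
        outgroup_divergence=0.02,
        breakpoints_per_allele=0,
        derived_per_region={},
        n_recent_variants=8,
        n_ancestral_variants=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestPolarization:
    def test_monomorphic_alignment_has_no_tentative_calls(self):
        haps = [AlignedHaplotype(f"h{i}", "ACGTACGTAC") for i in range(10)]
        og = AlignedHaplotype("og", "ACGTACGTAC", "outgroup")
        result = polarize_with_outgroup(HaplotypeAlignment(haps + [og]))
        assert result.tentative == [] and result.error_rate is None

    def test_trap_fixture_excludes_only_ancestral_variant(self, fixtures):
        fx = fixtures["polarization_trap"]
        result = polarize_with_outgroup(
            fx["alignment"], region_map=fx["region_map"]
        )
        expected = fx["expected"]
        assert len(result.tentative) == expected["n_tentative"]
        assert len(result.excluded) == expected["n_excluded"]
        assert result.excluded[0].anchor_column == expected["excluded_column"]
        assert result.error_rate == pytest.approx(expected["error_rate"])

    def test_planted_verdicts_recovered_across_seeds(self):
        for seed in range(20):
            aln, rm, truth = simulate(conspecific_config(seed=seed))
            result = polarize_with_outgroup(aln, region_map=rm)
            recent = {e.column for e in truth.planted if e.status == "recent"}
            ancestral = {
                e.column for e in truth.planted if e.status == "ancestral"
            }
            assert {r.anchor_column for r in result.tentative} == recent | ancestral
            assert {r.anchor_column for r in result.excluded} == ancestral
            assert {r.anchor_column for r in result.retained} == recent

    def test_error_rate_invariant_under_reordering(self):
        aln, rm, _ = simulate(conspecific_config(seed=4))
        result = polarize_with_outgroup(aln, region_map=rm)
        shuffled = HaplotypeAlignment(list(reversed(aln.members)))
        result2 = polarize_with_outgroup(shuffled, region_map=rm)
        assert result.error_rate == result2.error_rate

    def test_few_haplotypes_warns_but_proceeds(self):
        haps = [AlignedHaplotype(f"h{i}", "ACGTACGTAC") for i in range(4)]
        haps[0] = AlignedHaplotype("h0", "AGGTACGTAC")
        og = AlignedHaplotype("og", "ACGTACGTAC", "outgroup")
        with pytest.warns(UserWarning, match="conspecific"):
            result = polarize_with_outgroup(HaplotypeAlignment(haps + [og]))
        assert len(result.tentative) == 1

    def test_outgroup_gap_leaves_call_unresolved(self):
        haps = [AlignedHaplotype(f"h{i}", "ACGTACGTAC") for i in range(10)]
        haps[0] = AlignedHaplotype("h0", "AGGTACGTAC")
        og = AlignedHaplotype("og", "A-GTACGTAC", "outgroup")
        result = polarize_with_outgroup(HaplotypeAlignment(haps + [og]))
        assert len(result.tentative) == 1
        assert result.unresolved == result.tentative
        assert result.tentative[0].flags == ("outgroup_unresolved",)
        # unresolved calls are retained, not excluded
        assert result.excluded == [] and result.error_rate == 0.0

    def test_threshold_strictness(self):
        # minor state at exactly 30%: rejected under strict <, kept under <=
        haps = [
            AlignedHaplotype(f"h{i}", "AAA" if i < 7 else "ATA")
            for i in range(10)
        ]
        og = AlignedHaplotype("og", "AAA", "outgroup")
        aln = HaplotypeAlignment(haps + [og])
        assert polarize_with_outgroup(aln).tentative == []
        assert len(polarize_with_outgroup(aln, strict=False).tentative) == 1
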