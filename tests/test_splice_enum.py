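"""Splice-isoform enumeration: junction rule, censuses, naming,
assembly/translation."""

import pytest

from conftest import (
    brute_force_skip_census,
    brute_force_skip_chains,
    closed_form_count,
    fibonacci,
)
from hirusplice.gene_model import build_architecture, builtin_hman_genes
from hirusplice.splice_enum import (
    RETAIN_ONLY,
    SKIP_AND_RETAIN,
    SKIP_ONLY,
    EnumerationConfig,
    GrammarError,
    Mechanism,
    SpliceProduct,
    Termination,
    assemble_and_translate,
    count_by_multimericity,
    enumerate_isoforms,
    junction_valid,
    monomeric_motif_variants,
    motif_census,
)
from hirusplice.synthetic_data import SynthConfig, generate_gene


class TestJunctionRule:
    def test_even_to_downstream_odd_is_valid(self, dv3):
        assert junction_valid(dv3.exon(2), dv3.exon(7), dv3)

    def test_same_parity_is_invalid(self, dv3):
        assert not junction_valid(dv3.exon(2), dv3.exon(4), dv3)

    def test_upstream_acceptor_is_invalid(self, dv3):
        assert not junction_valid(dv3.exon(5), dv3.exon(3), dv3)

    def test_tail_never_donates(self, dv3):
        assert not junction_valid(dv3.exon(14), dv3.exon(13), dv3)

    def test_exons_from_another_gene_rejected(self, dv3, guan_genes):
        other = guan_genes["Hman_DV1"]
        with pytest.raises(ValueError, match="does not belong"):
            junction_valid(dv3.exon(2), other.exon(3), dv3)


class TestEnumeration:
    def test_dv3_skip_only_matches_brute_force(self, dv3):
        ours = count_by_multimericity(enumerate_isoforms(dv3, SKIP_ONLY))
        oracle = brute_force_skip_census(6, has_tail=True)
        assert ours == oracle

    def test_dv3_chains_equal_brute_force_chains(self, dv3):
        ours = {p.chain for p in enumerate_isoforms(dv3, SKIP_ONLY)}
        oracle = {
            c for c in brute_force_skip_chains(6, has_tail=True)
            if any(i % 2 == 0 and i != 14 for i in c)
        }
        assert ours == oracle

    def test_toy_two_repeat_tail_gene_counts(self, toy_gene):
        counts = count_by_multimericity(enumerate_isoforms(toy_gene, SKIP_ONLY))
        assert counts == {1: 3, 2: 1}
        assert counts == brute_force_skip_census(2, has_tail=True)

    def test_single_repeat_gene_has_one_chain(self):
        gene = build_architecture("mono", n_repeats=1, has_tail=True, motifs={3: "RGD"})
        counts = count_by_multimericity(enumerate_isoforms(gene, SKIP_ONLY))
        assert counts == {1: 1}

    def test_include_zero_repeat_adds_exactly_one_skip_product(self, dv3):
        base = enumerate_isoforms(dv3, SKIP_ONLY)
        with_zero = enumerate_isoforms(
            dv3,
            EnumerationConfig(
                mechanisms=frozenset({Mechanism.EXON_SKIPPING}), include_zero_repeat=True
            ),
        )
        extra = [p for p in with_zero if p.k_repeats == 0]
        assert len(with_zero) == len(base) + 1
        assert extra[0].chain == (1, 14)

    @pytest.mark.parametrize("n,tail", [(1, True), (3, True), (5, True), (8, True)])
    def test_closed_form_and_fibonacci_totals(self, n, tail):
        gene = build_architecture("g", n_repeats=n, has_tail=tail)
        counts = count_by_multimericity(enumerate_isoforms(gene, SKIP_ONLY))
        for k in range(1, n + 1):
            assert counts[k] == closed_form_count(n, k)
        assert sum(counts.values()) == fibonacci(2 * n + 1) - 1

    @pytest.mark.parametrize("n", [1, 2, 4, 6])
    def test_retention_doubles_every_class(self, n):
        gene = build_architecture("g", n_repeats=n, has_tail=True)
        skip = count_by_multimericity(enumerate_isoforms(gene, SKIP_ONLY))
        both = count_by_multimericity(enumerate_isoforms(gene, SKIP_AND_RETAIN))
        assert both == {k: 2 * v for k, v in skip.items()}

    def test_tail_retention_bijection(self, dv3):
        products = enumerate_isoforms(dv3, SKIP_AND_RETAIN)
        tails = {
            p.chain[:-1]
            for p in products
            if p.termination is Termination.TAIL_SPLICE
        }
        retained = {
            p.chain for p in products if p.termination is Termination.INTRON_RETENTION
        }
        assert tails == retained

    def test_retention_only_walks_adjacent_junctions(self, toy_gene):
        products = enumerate_isoforms(toy_gene, RETAIN_ONLY)
        assert all(
            p.termination is Termination.INTRON_RETENTION for p in products
        )
        assert {p.chain for p in products} == {(1, 2, 3), (1, 2, 3, 4, 5)}

    def test_products_are_unique_and_junction_valid(self, dv3):
        products = enumerate_isoforms(dv3, SKIP_AND_RETAIN)
        keys = {(p.chain, p.termination, p.retained_intron) for p in products}
        assert len(keys) == len(products)
        for p in products:
            for a, b in zip(p.chain, p.chain[1:]):
                assert junction_valid(dv3.exon(a), dv3.exon(b))

    def test_enumeration_order_is_deterministic(self, dv3):
        a = enumerate_isoforms(dv3, SKIP_AND_RETAIN)
        b = enumerate_isoforms(dv3, SKIP_AND_RETAIN)
        assert a == b
        chains = [p.chain for p in a]
        assert chains == sorted(chains)

    def test_grammar_breaking_gene_rejected(self):
        liu = {g.name: g for g in builtin_hman_genes("liu")}
        with pytest.raises(GrammarError, match="violates the splice grammar"):
            enumerate_isoforms(liu["Hman_DV5"], SKIP_ONLY)

    def test_max_products_guard(self, dv3):
        cfg = EnumerationConfig(
            mechanisms=frozenset({Mechanism.EXON_SKIPPING}), max_products=10
        )
        with pytest.raises(ValueError, match="limit exceeded"):
            enumerate_isoforms(dv3, cfg)

    def test_empty_mechanisms_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            EnumerationConfig(mechanisms=frozenset())


class TestMotifCensus:
    def test_full_length_products(self, guan_genes):
        for name, expected in (("Hman_DV3", 2), ("Hman_DV5", 1)):
            gene = guan_genes[name]
            products = enumerate_isoforms(gene, SKIP_ONLY)
            full = max(products, key=lambda p: len(p.chain))
            assert full.chain == tuple(range(1, 15))
            assert full.motif_count == expected

    def test_chain_without_motif_exons(self, dv3):
        products = enumerate_isoforms(dv3, SKIP_ONLY)
        skips_both = [p for p in products if 3 not in p.chain and 7 not in p.chain]
        assert skips_both and all(p.motif_count == 0 for p in skips_both)

    def test_census_sums_to_product_count(self, dv3):
        products = enumerate_isoforms(dv3, SKIP_ONLY)
        census = motif_census(products, dv3)
        assert sum(census.values()) == len(products)

    def test_empty_product_list(self, dv3):
        assert motif_census([], dv3) == {}

    def test_foreign_products_rejected(self, dv3, guan_genes):
        products = enumerate_isoforms(guan_genes["Hman_DV1"], SKIP_ONLY)
        with pytest.raises(ValueError, match="passed with gene"):
            motif_census(products, dv3)


class TestMonomericVariants:
    def test_sixteen_variants_from_four_genes(self, guan_genes):
        genes = [guan_genes[n] for n in ("Hman_DV1", "Hman_DV2", "Hman_DV3", "Hman_DV5")]
        variants = monomeric_motif_variants(genes)
        assert len(variants) == 16
        assert all(v.k_repeats == 1 and v.motif_count >= 1 for v in variants)

    def test_dv3_yields_eight_named_variants(self, dv3):
        variants = monomeric_motif_variants([dv3])
        names = [v.name for v in variants]
        assert len(names) == 8
        by_name = {v.name: v for v in variants}
        v1a = by_name["Hman_DV3s-1a"]
        assert v1a.chain == (1, 2, 3)
        assert v1a.termination is Termination.INTRON_RETENTION
        assert v1a.retained_intron == 3
        v1b = by_name["Hman_DV3s-1b"]
        assert v1b.chain == (1, 2, 3, 14)
        assert v1b.termination is Termination.TAIL_SPLICE

    def test_dv1_yields_single_variant(self, guan_genes):
        variants = monomeric_motif_variants([guan_genes["Hman_DV1"]])
        assert [v.name for v in variants] == ["Hman_DV1s"]
        assert variants[0].chain == (1, 2, 3)

    def test_dv2_variants_terminate_at_final_exon(self, guan_genes):
        variants = monomeric_motif_variants([guan_genes["Hman_DV2"]])
        names = [v.name for v in variants]
        assert names == [f"Hman_DV2s-{i}" for i in range(1, 6)]
        e9 = [v for v in variants if v.chain[-1] == 9]
        assert len(e9) == 4 and all(v.termination is Termination.FINAL_EXON for v in e9)

    def test_monomeric_gene_skipped_with_warning(self, guan_genes):
        with pytest.warns(UserWarning, match="already monomeric"):
            out = monomeric_motif_variants([guan_genes["Hman_DV4"]])
        assert out == []


class TestAssembly:
    @pytest.fixture()
    def syn(self):
        cfg = SynthConfig(
            n_repeats=3, motif_repeats=((1, "RGD"),), has_tail=True, seed=11, name="asm"
        )
        model, _, _ = generate_gene(cfg)
        return model

    def test_retention_product_shorter_than_tail_twin(self, syn):
        products = enumerate_isoforms(syn, SKIP_AND_RETAIN)
        by_key = {(p.chain, p.termination): p for p in products}
        ret = by_key[((1, 2, 3), Termination.INTRON_RETENTION)]
        tail = by_key[((1, 2, 3, syn.n_exons), Termination.TAIL_SPLICE)]
        p_ret = assemble_and_translate(syn, ret)
        p_tail = assemble_and_translate(syn, tail)
        assert p_ret.length_aa < p_tail.length_aa

    def test_invalid_chain_rejected_before_assembly(self):
        with pytest.raises(ValueError, match="alternating parity"):
            SpliceProduct("x", (1, 2, 4), Termination.FINAL_EXON)

    def test_architecture_only_model_refused(self, dv3):
        product = enumerate_isoforms(dv3, SKIP_ONLY)[0]
        with pytest.raises(ValueError, match="architecture-only"):
            assemble_and_translate(dv3, product)

    def test_stop_falls_inside_retained_intron(self, syn):
        products = [
            p
            for p in enumerate_isoforms(syn, SKIP_AND_RETAIN)
            if p.termination is Termination.INTRON_RETENTION
        ]
        for p in products:
            rec = assemble_and_translate(syn, p)
            exon_aa = sum(len(syn.exon(i).sequence) for i in p.chain) // 3
            assert rec.length_aa >= exon_aa - 1  # stop is not inside any exon

    def test_dedupe_by_protein_sequence_never_increases(self, syn):
        by_chain = enumerate_isoforms(syn, SKIP_ONLY)
        by_seq = enumerate_isoforms(
            syn,
            EnumerationConfig(
                mechanisms=frozenset({Mechanism.EXON_SKIPPING}),
                dedupe="by_protein_sequence",
            ),
        )
        assert 0 < len(by_seq) <= len(by_chain)
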