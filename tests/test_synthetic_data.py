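"""Synthetic gene generation and the end-to-end pipeline guarantee."""

import pytest

from conftest import closed_form_count, fibonacci
from hirusplice.domain_annot import classify_architecture
from hirusplice.gene_model import (
    Orientation,
    intron_has_inframe_stop,
    validate_gene_model,
)
from hirusplice.splice_enum import (
    SKIP_AND_RETAIN,
    SKIP_ONLY,
    assemble_and_translate,
    count_by_multimericity,
    enumerate_isoforms,
)
from hirusplice.synthetic_data import SynthConfig, generate_cluster, generate_gene


@pytest.mark.parametrize("phase", [1, 2])
@pytest.mark.parametrize("tail", [True, False])
def test_generated_genes_are_grammar_conformant(phase, tail):
    cfg = SynthConfig(
        n_repeats=3, motif_repeats=((2, "KGD"),), has_tail=tail,
        even_end_phase=phase, seed=99,
    )
    model, _, _ = generate_gene(cfg)
    assert validate_gene_model(model) == []
    assert model.n_repeats == 3
    assert model.has_tail is tail
    assert model.motif_exons == {5}


def test_dv3_like_architecture():
    cfg = SynthConfig(
        n_repeats=6, motif_repeats=((1, "RGD"), (3, "RGD")), has_tail=True, seed=42
    )
    model, _, _ = generate_gene(cfg)
    assert model.n_exons == 14
    assert sorted(model.motif_exons) == [3, 7]


def test_monomer_architecture():
    model, _, _ = generate_gene(SynthConfig(n_repeats=1, has_tail=False, seed=1))
    assert model.n_exons == 3


def test_same_seed_gives_byte_identical_output():
    cfg = SynthConfig(n_repeats=2, motif_repeats=((1, "RGD"),), seed=5)
    out1 = generate_gene(cfg)
    out2 = generate_gene(cfg)
    assert out1[1] == out2[1] and out1[2] == out2[2]
    assert out1[0] == out2[0]


def test_different_seeds_differ_in_sequence_but_not_grammar():
    a, _, _ = generate_gene(SynthConfig(n_repeats=2, seed=1))
    b, _, _ = generate_gene(SynthConfig(n_repeats=2, seed=2))
    assert a.n_exons == b.n_exons
    assert [e.role for e in a.exons] == [e.role for e in b.exons]
    assert any(x.sequence != y.sequence for x, y in zip(a.exons, b.exons))


def test_odd_introns_carry_an_early_inframe_stop():
    model, _, _ = generate_gene(SynthConfig(n_repeats=3, seed=3))
    for intron in model.introns:
        if intron.index % 2 == 1:
            assert intron.has_inframe_stop
            head = intron.sequence[:30]
            assert intron_has_inframe_stop(head, model.exon(intron.index).end_phase)


def test_translated_full_length_product_has_all_repeats():
    cfg = SynthConfig(n_repeats=4, motif_repeats=((1, "RGD"), (4, "KGD")), seed=8)
    model, _, _ = generate_gene(cfg)
    full = max(enumerate_isoforms(model, SKIP_ONLY), key=lambda p: len(p.chain))
    rec = assemble_and_translate(model, full)
    rep = classify_architecture(rec.id, rec.sequence)
    assert rep.n_repeats == 4
    assert rep.motifs == ((1, "RGD"), (4, "KGD"))


def test_generated_genes_obey_the_enumeration_oracle():
    for n in (1, 2, 4):
        model, _, _ = generate_gene(SynthConfig(n_repeats=n, has_tail=True, seed=n))
        counts = count_by_multimericity(enumerate_isoforms(model, SKIP_ONLY))
        assert counts == {k: closed_form_count(n, k) for k in range(1, n + 1)}
        assert sum(counts.values()) == fibonacci(2 * n + 1) - 1


def test_infeasible_exon_length_ranges_rejected():
    cfg = SynthConfig(n_repeats=2, exon_length_ranges={"domain_even": (1, 5)}, seed=0)
    with pytest.raises(ValueError, match="infeasible config"):
        generate_gene(cfg)


def test_motif_ordinal_outside_repeats_rejected():
    with pytest.raises(ValueError, match="motif repeat ordinal"):
        SynthConfig(n_repeats=2, motif_repeats=((5, "RGD"),))


def test_cluster_orientations_and_round_trip(tmp_path):
    from hirusplice.gene_model import load_gene_models

    cfgs = [SynthConfig(n_repeats=2, seed=i, name=f"g{i}") for i in range(5)]
    models, gff3, fasta = generate_cluster(
        cfgs, orientations=[Orientation.RE_CO] * 5, seed=77
    )
    assert all(m.interval.orientation is Orientation.RE_CO for m in models)
    strands = [
        line.split("\t")[6]
        for line in gff3.splitlines()
        if "\tgene\t" in line or "\texon\t" in line
    ]
    assert set(strands) == {"-"}
    (tmp_path / "c.gff3").write_text(gff3)
    (tmp_path / "c.fa").write_text(fasta)
    loaded = load_gene_models(tmp_path / "c.gff3", tmp_path / "c.fa")
    assert loaded == models


def test_single_gene_cluster_span():
    models, _, _ = generate_cluster([SynthConfig(n_repeats=1, seed=4)], seed=4)
    assert len(models) == 1
    assert models[0].interval.start > 1  # flanked


def test_cluster_seed_changes_spacing_not_grammar():
    cfgs = [SynthConfig(n_repeats=2, seed=0, name="a"), SynthConfig(n_repeats=3, seed=0, name="b")]
    m1, _, _ = generate_cluster(cfgs, seed=1)
    m2, _, _ = generate_cluster(cfgs, seed=2)
    assert [m.n_exons for m in m1] == [m.n_exons for m in m2]
    assert [m.interval.start for m in m1] != [m.interval.start for m in m2]


def test_retention_products_shorter_than_tail_twins():
    model, _, _ = generate_gene(SynthConfig(n_repeats=2, motif_repeats=((1, "RGD"),), seed=21))
    products = enumerate_isoforms(model, SKIP_AND_RETAIN)
    by_key = {(p.chain, p.termination.value): p for p in products}
    for (chain, term), p in by_key.items():
        if term == "intron_retention":
            twin = by_key.get((chain + (model.n_exons,), "tail_splice"))
            assert twin is not None
            short = assemble_and_translate(model, p)
            long = assemble_and_translate(model, twin)
            assert short.length_aa < long.length_aa
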