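"""Gene architecture types, validation, fixtures and GFF3/FASTA I/O."""

import pytest

from hirusplice.gene_model import (
    ExonRole,
    ExonUnit,
    GeneModel,
    GenomicInterval,
    IntronUnit,
    Orientation,
    build_architecture,
    builtin_hman_genes,
    load_gene_models,
    validate_gene_model,
    write_gff3,
)
from hirusplice.synthetic_data import SynthConfig, generate_gene

EXPECTED_EXONS = {"Hman_DV1": 13, "Hman_DV2": 9, "Hman_DV3": 14, "Hman_DV4": 3, "Hman_DV5": 14}
EXPECTED_REPEATS = {"Hman_DV1": 6, "Hman_DV2": 4, "Hman_DV3": 6, "Hman_DV4": 1, "Hman_DV5": 6}


@pytest.mark.parametrize("source", ["guan", "zheng", "liu"])
def test_fixture_intervals_positive_and_consistent(source):
    genes = builtin_hman_genes(source)
    assert len(genes) == 10
    for g in genes:
        assert g.interval is not None
        assert g.interval.length == g.interval.end - g.interval.start + 1 > 0


@pytest.mark.parametrize("source", ["guan", "zheng"])
def test_decorsin_architectures(source):
    genes = {g.name: g for g in builtin_hman_genes(source)}
    for name, n in EXPECTED_EXONS.items():
        assert genes[name].n_exons == n
        assert genes[name].n_repeats == EXPECTED_REPEATS[name]
        assert genes[name].grammar_ok


def test_guan_dv4_interval_and_orientation(guan_genes):
    iv = guan_genes["Hman_DV4"].interval
    assert (iv.start, iv.end, iv.orientation) == (1431197, 1432077, Orientation.RE_CO)
    assert guan_genes["Hman_DV4"].n_exons == 3


def test_motif_placements(guan_genes):
    assert dict.fromkeys(guan_genes["Hman_DV2"].motif_exons) == {3: None, 9: None}
    assert set(guan_genes["Hman_DV3"].motif_exons) == {3, 7}
    assert guan_genes["Hman_DV1"].exon(3).motif.value == "KGD"


def test_zheng_orientations_flip_relative_to_guan():
    zheng = {g.name: g for g in builtin_hman_genes("zheng")}
    for name in EXPECTED_EXONS:
        assert zheng[name].interval.orientation is Orientation.FW
    for name in ("Hman_HV1", "Hman_HV2", "Hman_HV3", "Hman_HV4", "Hman_TH"):
        assert zheng[name].interval.orientation is Orientation.RE_CO


def test_liu_dv5_is_flagged_as_grammar_breaking():
    liu = {g.name: g for g in builtin_hman_genes("liu")}
    dv5 = liu["Hman_DV5"]
    assert dv5.n_exons == 11
    assert not dv5.grammar_ok
    messages = [v.message for v in validate_gene_model(dv5)]
    assert "first domain exon after signal is domain_odd" in messages


def test_unknown_source_rejected():
    with pytest.raises(ValueError, match="unknown genome source"):
        builtin_hman_genes("nonexistent")


def test_validation_is_empty_for_conformant_gene(dv3):
    assert validate_gene_model(dv3) == []


def test_validation_idempotent_and_side_effect_free(dv3):
    before = [(e.index, e.role, e.motif) for e in dv3.exons]
    v1 = validate_gene_model(dv3)
    v2 = validate_gene_model(dv3)
    assert v1 == v2
    assert [(e.index, e.role, e.motif) for e in dv3.exons] == before


def test_tail_in_the_middle_is_a_violation():
    gene = build_architecture("bad", n_repeats=2, has_tail=True)
    gene.exons[2].role = ExonRole.TAIL  # E3 becomes a tail exon
    rules = {v.rule for v in validate_gene_model(gene)}
    assert "tail_position" in rules
    assert any("tail not terminal" in v.message for v in validate_gene_model(gene))


def test_motif_on_even_exon_is_a_violation():
    from hirusplice.gene_model import Motif

    gene = build_architecture("bad", n_repeats=2, has_tail=False)
    gene.exons[1].motif = Motif.RGD  # E2 is a domain_even exon
    rules = {v.rule for v in validate_gene_model(gene)}
    assert "motif_placement" in rules


def test_signal_only_gene_fails_grammar():
    gene = GeneModel("solo", exons=[ExonUnit(1, ExonRole.SIGNAL)], introns=[])
    assert not gene.grammar_ok
    assert gene.n_repeats == 0


def test_odd_intron_without_stop_is_a_violation(toy_gene):
    toy_gene.introns[0].has_inframe_stop = False  # I1
    rules = {v.rule for v in validate_gene_model(toy_gene)}
    assert "odd_intron_stop" in rules


@pytest.mark.parametrize("seed,phase,tail", [(1, 1, True), (2, 2, True), (3, 1, False), (4, 2, False)])
def test_gff3_fasta_round_trip(tmp_path, seed, phase, tail):
    cfg = SynthConfig(
        n_repeats=3, motif_repeats=((1, "RGD"), (2, "KGD")), has_tail=tail,
        even_end_phase=phase, seed=seed, name="rt",
    )
    model, gff3, fasta = generate_gene(cfg)
    (tmp_path / "g.gff3").write_text(gff3)
    (tmp_path / "g.fa").write_text(fasta)
    loaded = load_gene_models(tmp_path / "g.gff3", tmp_path / "g.fa")
    assert len(loaded) == 1
    assert loaded[0] == model

    # write what was loaded, re-parse, and the model is unchanged again
    write_gff3(loaded, tmp_path / "g2.gff3", tmp_path / "g2.fa")
    again = load_gene_models(tmp_path / "g2.gff3", tmp_path / "g2.fa")
    assert again[0] == loaded[0]


def _write_toy_gff3(tmp_path, role_line="role=domain_even", coords=((10, 30), (40, 60))):
    lines = [
        "##gff-version 3",
        "ctg\tx\tgene\t10\t60\t.\t+\t.\tID=g1",
        f"ctg\tx\texon\t{coords[0][0]}\t{coords[0][1]}\t.\t+\t.\tID=g1.e1;Parent=g1;role=signal",
        f"ctg\tx\texon\t{coords[1][0]}\t{coords[1][1]}\t.\t+\t.\tID=g1.e2;Parent=g1;{role_line}",
    ]
    p = tmp_path / "toy.gff3"
    p.write_text("\n".join(lines) + "\n")
    return p


def test_loader_rejects_unknown_role(tmp_path):
    p = _write_toy_gff3(tmp_path, role_line="role=mystery")
    with pytest.raises(ValueError, match="unknown role"):
        load_gene_models(p)


def test_loader_rejects_overlapping_exons(tmp_path):
    p = _write_toy_gff3(tmp_path, coords=((10, 45), (40, 60)))
    with pytest.raises(ValueError, match="overlapping exons"):
        load_gene_models(p)


def test_loader_rejects_seq_id_missing_from_fasta(tmp_path):
    p = _write_toy_gff3(tmp_path)
    fa = tmp_path / "wrong.fa"
    fa.write_text(">other\n" + "A" * 80 + "\n")
    with pytest.raises(ValueError, match="not present in FASTA"):
        load_gene_models(p, fa)


def test_writer_refuses_architecture_only_models(tmp_path, dv3):
    with pytest.raises(ValueError, match="architecture-only"):
        write_gff3([dv3], tmp_path / "x.gff3")


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("c", 10, 5)
    assert GenomicInterval("c", 10, 19).length == 10
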