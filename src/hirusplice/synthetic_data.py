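"""Generation of grammar-conformant synthetic genes with sequences.

The generator emulates the hirudin-superfamily gene grammar: one
signal-peptide exon, ``n`` repeats of (even exon, odd exon) pairs each
encoding a six-cysteine globular domain, exon-overlapping codons at
even->odd junctions and codon-boundary junctions at odd->even
junctions, in-frame stop codons placed in every odd intron, and an
optional C-terminal tail exon.  RGD/KGD motifs can be requested for
chosen repeats; they are placed between the fifth and sixth cysteines
of the repeat, inside the odd exon.

Design constraints that make the generated genes fully analyzable:

* All repeats of one gene share a single seeded domain template (same
  cysteine layout, same exon split point, and an identical Ala/GCT
  codon at the split position).  Any exon-skipping junction therefore
  produces a hybrid domain that is again conformant and stop-free, so
  every enumerated product translates cleanly and the domain scanner
  recovers exactly the enumerator's repeat and motif counts.
* Filler residues are drawn from an alphabet without cysteine and
  without glycine, so no spurious six-cysteine scaffolds or RGD/KGD
  tripeptides can arise by chance.
* Stop codons in odd introns are guaranteed by construction (placed
  within the first 30 nt), not by rejection sampling.

Sequence composition outside constrained positions is seeded-random
(optionally GC-biased for introns/UTRs).  Signal peptides are
plausible-looking but not validated against any predictor; no attempt
is made to imitate real leech codon usage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .gene_model import (
    ExonRole,
    ExonUnit,
    GeneModel,
    GenomicInterval,
    IntronUnit,
    Motif,
    Orientation,
    intron_has_inframe_stop,
    render_annotation,
    validate_gene_model,
)

__all__ = ["SynthConfig", "generate_gene", "generate_cluster"]

# residues that can never create a cysteine scaffold or an R/K-G-D motif
_FILLER = "ALSTNQIEVHFP"
_SIGNAL_FILLER = "ALIVFST"

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic gene.

    ``motif_repeats`` maps repeat ordinals (1-based) to "RGD"/"KGD".
    ``even_end_phase`` is the number of nucleotides of the junction
    codon carried by even exons (1 or 2; both splits are grammatical).
    ``exon_length_ranges`` optionally constrains per-role exon lengths
    in nt (keys "signal", "domain_even", "domain_odd"); generation
    fails with the violated constraint if the ranges cannot be met.
    """

    n_repeats: int = 2
    motif_repeats: tuple[tuple[int, str], ...] = ()
    has_tail: bool = True
    even_end_phase: int = 1
    signal_len_range: tuple[int, int] = (36, 60)
    intron_length_range: tuple[int, int] = (60, 180)
    exon_length_ranges: Optional[Mapping[str, tuple[int, int]]] = None
    seed: int = 0
    gc_bias: float = 0.5
    name: str = "syngene"

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.even_end_phase not in (1, 2):
            raise ValueError("even_end_phase must be 1 or 2")
        motifs = tuple((int(r), str(Motif(m).value)) for r, m in dict(self.motif_repeats).items())
        object.__setattr__(self, "motif_repeats", motifs)
        for r, _ in motifs:
            if not 1 <= r <= self.n_repeats:
                raise ValueError(f"motif repeat ordinal {r} outside 1..{self.n_repeats}")
        if not 0.0 <= self.gc_bias <= 1.0:
            raise ValueError("gc_bias must lie in [0, 1]")
        for lo, hi in (self.signal_len_range, self.intron_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")


@dataclass(frozen=True)
class _DomainTemplate:
    """Per-gene repeat layout, shared by every repeat of the gene."""

    prefix: int
    gaps: tuple[int, int, int, int, int]
    suffix: int
    split_res: int          # residues in the even-exon part
    motif_offset: int       # motif start, residues after C5

    @property
    def cys(self) -> tuple[int, ...]:
        pos = [self.prefix + 1]
        for g in self.gaps:
            pos.append(pos[-1] + g + 1)
        return tuple(pos)

    @property
    def length(self) -> int:
        return self.cys[-1] + self.suffix


def _sample_template(rng: random.Random, cfg: SynthConfig) -> _DomainTemplate:
    ranges = dict(cfg.exon_length_ranges or {})
    p = cfg.even_end_phase
    for _ in range(300):
        prefix = rng.randint(2, 5)
        gaps = (
            rng.randint(2, 8),
            rng.randint(1, 8),
            rng.randint(1, 8),
            rng.randint(1, 10),
            rng.randint(7, 12),
        )
        suffix = rng.randint(2, 5)
        tpl = _DomainTemplate(prefix, gaps, suffix, 0, rng.randint(1, gaps[4] - 2))
        c = tpl.cys
        lo, hi = c[1], c[2] - 2  # split strictly between C2 and C3
        if lo > hi:
            continue
        split = rng.randint(lo, hi)
        tpl = replace(tpl, split_res=split)
        even_len = 3 * split + p
        odd_len = 3 * (tpl.length - split) - p
        if "domain_even" in ranges and not (
            ranges["domain_even"][0] <= even_len <= ranges["domain_even"][1]
        ):
            continue
        if "domain_odd" in ranges and not (
            ranges["domain_odd"][0] <= odd_len <= ranges["domain_odd"][1]
        ):
            continue
        return tpl
    raise ValueError(
        "infeasible config: exon_length_ranges cannot be satisfied together with "
        "the cysteine-spacing and codon-phase constraints"
    )


def _rand_nt(rng: random.Random, n: int, gc: float) -> str:
    pool = "ACGT"
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices(pool, weights=w, k=n))


def _repeat_peptide(
    rng: random.Random, tpl: _DomainTemplate, motif: Optional[str]
) -> str:
    res = [rng.choice(_FILLER) for _ in range(tpl.length)]
    for pos in tpl.cys:
        res[pos - 1] = "C"
    res[tpl.split_res] = "A"  # invariant split codon (GCT) across repeats
    if motif is not None:
        start = tpl.cys[4] + tpl.motif_offset  # 1-based, strictly after C5
        for k, aa in enumerate(motif):
            res[start - 1 + k] = aa
    return "".join(res)


def _encode(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


def _build_gene(cfg: SynthConfig) -> GeneModel:
    rng = random.Random(cfg.seed)
    p = cfg.even_end_phase
    tpl = _sample_template(rng, cfg)

    # signal exon: ATG + filler codons, ends on a codon boundary
    lo, hi = cfg.signal_len_range
    sig_len = rng.randint(lo // 3, hi // 3) * 3
    sig_len = max(sig_len, 6)
    sig_pep = "M" + "".join(rng.choice(_SIGNAL_FILLER) for _ in range(sig_len // 3 - 1))
    if "signal" in dict(cfg.exon_length_ranges or {}):
        slo, shi = dict(cfg.exon_length_ranges)["signal"]
        if not slo <= sig_len <= shi:
            raise ValueError("infeasible config: signal exon length range excludes multiples of 3")
    exon_seqs: list[tuple[ExonRole, str, Optional[Motif]]] = [
        (ExonRole.SIGNAL, _encode(sig_pep), None)
    ]

    motifs = dict(cfg.motif_repeats)
    split_nt = 3 * tpl.split_res + p
    for r in range(1, cfg.n_repeats + 1):
        pep = _repeat_peptide(rng, tpl, motifs.get(r))
        nt = _encode(pep)
        exon_seqs.append((ExonRole.DOMAIN_EVEN, nt[:split_nt], None))
        odd_seq = nt[split_nt:]
        if not cfg.has_tail and r == cfg.n_repeats:
            # tail-less gene: stop codon and a short 3'UTR live in the final exon
            odd_seq += "TAA" + _rand_nt(rng, rng.randint(5, 12), cfg.gc_bias)
        exon_seqs.append(
            (ExonRole.DOMAIN_ODD, odd_seq, Motif(motifs[r]) if r in motifs else None)
        )
    if cfg.has_tail:
        tail_pep = "".join(rng.choice(_FILLER) for _ in range(rng.randint(3, 8)))
        tail_seq = _encode(tail_pep) + "TAA" + _rand_nt(rng, rng.randint(5, 12), cfg.gc_bias)
        exon_seqs.append((ExonRole.TAIL, tail_seq, None))

    ilo, ihi = cfg.intron_length_range
    exons: list[ExonUnit] = []
    introns: list[IntronUnit] = []
    phase = 0
    for k, (role, seq, motif) in enumerate(exon_seqs, start=1):
        phase = (phase + len(seq)) % 3
        exons.append(
            ExonUnit(index=k, role=role, end_phase=phase, motif=motif, sequence=seq)
        )
        if k < len(exon_seqs):
            n = rng.randint(max(ilo, 10), max(ihi, 10))
            if k % 2 == 1:
                # guaranteed in-frame stop within the first 30 nt: odd exons
                # end on codon boundaries, so intron frame-0 codons are
                # GTA (splice donor + 1 nt) then TAA
                iseq = "GTATAA" + _rand_nt(rng, n - 8, cfg.gc_bias) + "AG"
            else:
                iseq = "GT" + _rand_nt(rng, n - 4, cfg.gc_bias) + "AG"
            introns.append(
                IntronUnit(
                    index=k,
                    has_inframe_stop=intron_has_inframe_stop(iseq, phase),
                    sequence=iseq,
                )
            )

    body_len = sum(len(s) for _, s, _ in exon_seqs) + sum(len(i.sequence) for i in introns)
    model = GeneModel(
        name=cfg.name,
        exons=exons,
        introns=introns,
        interval=GenomicInterval(f"ctg_{cfg.name}", 41, 40 + body_len),
        even_end_phase=p,
    )
    violations = validate_gene_model(model)
    if violations:  # pragma: no cover - generator self-check
        raise AssertionError(f"generator produced a non-conformant gene: {violations}")
    return model


def _header(cfg: SynthConfig, extra: str = "") -> list[str]:
    motifs = ",".join(f"{r}:{m}" for r, m in cfg.motif_repeats) or "-"
    return [
        "synthetic hirudin-superfamily gene"
        + (f" ({extra})" if extra else ""),
        f"config: name={cfg.name} n_repeats={cfg.n_repeats} motifs={motifs} "
        f"tail={cfg.has_tail} even_end_phase={cfg.even_end_phase} seed={cfg.seed}",
    ]


def generate_gene(config: SynthConfig) -> tuple[GeneModel, str, str]:
    """One synthetic gene: (GeneModel with sequences, GFF3 text, FASTA
    text).  Deterministic for a fixed config (byte-identical output)."""
    model = _build_gene(config)
    gff3, fasta = render_annotation([model], header_comments=_header(config))
    return model, gff3, fasta


def generate_cluster(
    gene_configs: Sequence[SynthConfig],
    spacing_bp: tuple[int, int] = (200, 600),
    orientations: Optional[Sequence[Orientation | str]] = None,
    seed: int = 0,
) -> tuple[list[GeneModel], str, str]:
    """Several synthetic genes on one contig with random intergenic
    spacers.  Gene grammar depends only on each gene's config; the
    cluster seed varies spacers and per-gene sequence composition."""
    if not gene_configs:
        raise ValueError("at least one gene config required")
    rng = random.Random(seed)
    if orientations is None:
        orientations = [Orientation.FW] * len(gene_configs)
    orientations = [Orientation(o) for o in orientations]
    if len(orientations) != len(gene_configs):
        raise ValueError("one orientation per gene config required")

    models: list[GeneModel] = []
    pos = 40  # 5' flank
    used_names: set[str] = set()
    for i, (cfg, orient) in enumerate(zip(gene_configs, orientations)):
        name = cfg.name if cfg.name not in used_names else f"{cfg.name}_{i + 1}"
        used_names.add(name)
        child = replace(cfg, name=name, seed=(seed * 1_000_003 + 7919 * i + cfg.seed) % 2**31)
        model = _build_gene(child)
        body_len = model.interval.length
        iv = GenomicInterval("syncluster", pos + 1, pos + body_len, orient)
        model = replace(model, interval=iv)
        models.append(model)
        pos += body_len + rng.randint(*spacing_bp)

    span = max(m.interval.end for m in models) - min(m.interval.start for m in models) + 1
    total = sum(m.interval.length for m in models)
    assert span >= total  # spacers only add distance

    header = [
        f"synthetic gene cluster: {len(models)} genes, seed={seed}",
    ]
    gff3, fasta = render_annotation(models, header_comments=header)
    return models, gff3, fasta
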