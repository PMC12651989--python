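"""Gene-architecture types and I/O for hirudin-superfamily genes.

Genes of the hirudin superfamily (hirudins, hirudin-like factors,
tandem-hirudin, decorsins/ornatins) share a common layout: a first exon
encoding the signal peptide, followed by one or more two-exon repeats
that each encode a six-cysteine globular domain, optionally closed by a
short C-terminal tail exon.  Even-indexed exons end mid-codon
("exon-overlapping" junction codons) while odd-indexed exons end on
codon boundaries, and every odd-indexed intron carries a stop codon in
frame with the odd exons -- the property that makes terminal intron
retention a productive splicing outcome.

This module provides the domain types (:class:`ExonUnit`,
:class:`IntronUnit`, :class:`GenomicInterval`, :class:`GeneModel`),
grammar validation, GFF3/FASTA readers and writers, and the packaged
architecture/coordinate fixtures for the ten *Hirudinaria manillensis*
genes (five decorsin variants, four hirudin variants and the
tandem-hirudin) across the three published genome assemblies.

Coordinates are 1-based inclusive throughout; conversion to other
conventions happens only inside format readers/writers.  Exon order in a
:class:`GeneModel` is transcriptional (5'->3' of the mRNA), not genomic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "ExonRole",
    "Motif",
    "Orientation",
    "ExonUnit",
    "IntronUnit",
    "GenomicInterval",
    "GeneModel",
    "Violation",
    "validate_gene_model",
    "load_gene_models",
    "write_gff3",
    "render_annotation",
    "builtin_hman_genes",
    "fixture_table",
    "GENOME_SOURCES",
    "intron_has_inframe_stop",
]

GENOME_SOURCES = ("guan", "zheng", "liu")

_STOP_CODONS = {"TAA", "TAG", "TGA"}


class ExonRole(str, enum.Enum):
    SIGNAL = "signal"
    DOMAIN_EVEN = "domain_even"
    DOMAIN_ODD = "domain_odd"
    TAIL = "tail"


class Motif(str, enum.Enum):
    RGD = "RGD"
    KGD = "KGD"


class Orientation(str, enum.Enum):
    FW = "fw"          # forward
    RE_CO = "re_co"    # reverse and complementary


@dataclass
class ExonUnit:
    """A single exon: 1-based ordinal, grammar role, optional sequence.

    ``length_nt == 0`` marks an architecture-only exon (no sequence and
    no known length); sequence-requiring operations must refuse such
    exons rather than fabricate sequence.  ``end_phase`` is the number
    of nucleotides of the junction codon contributed by this exon's 3'
    end (0 = the exon ends on a codon boundary).
    """

    index: int
    role: ExonRole
    length_nt: int = 0
    end_phase: int = 0
    motif: Optional[Motif] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.role = ExonRole(self.role)
        if self.motif is not None:
            self.motif = Motif(self.motif)
        if self.index < 1:
            raise ValueError(f"exon index must be >= 1, got {self.index}")
        if self.end_phase not in (0, 1, 2):
            raise ValueError(f"end_phase must be in 0..2, got {self.end_phase}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.length_nt == 0:
                self.length_nt = len(self.sequence)
            elif len(self.sequence) != self.length_nt:
                raise ValueError(
                    f"E{self.index}: sequence length {len(self.sequence)} "
                    f"!= length_nt {self.length_nt}"
                )

    @property
    def label(self) -> str:
        return f"E{self.index}"


@dataclass
class IntronUnit:
    """Intron I(k) follows exon E(k); flagged if it contains a stop codon
    in the reading frame established by the upstream exons."""

    index: int
    has_inframe_stop: bool = False
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"intron index must be >= 1, got {self.index}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()

    @property
    def label(self) -> str:
        return f"I{self.index}"


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval with orientation."""

    seq_id: str
    start: int
    end: int
    orientation: Orientation = Orientation.FW

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.seq_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """Ordered exon/intron architecture of one gene.

    Exons are in transcriptional order.  ``even_end_phase`` is the
    shared 3' phase of all domain_even exons (1 by default: one
    nucleotide of the junction codon lies in the even exon, two in the
    odd exon).  Derived quantities (``has_tail``, ``n_repeats``,
    ``motif_exons``, ``grammar_ok``) are computed from the exon list.
    """

    name: str
    exons: list[ExonUnit] = field(default_factory=list)
    introns: list[IntronUnit] = field(default_factory=list)
    interval: Optional[GenomicInterval] = None
    even_end_phase: int = 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def has_tail(self) -> bool:
        return bool(self.exons) and self.exons[-1].role is ExonRole.TAIL

    @property
    def n_repeats(self) -> int:
        """Number of adjacent (domain_even, domain_odd) exon pairs."""
        return sum(
            1
            for a, b in zip(self.exons, self.exons[1:])
            if a.role is ExonRole.DOMAIN_EVEN and b.role is ExonRole.DOMAIN_ODD
        )

    @property
    def motif_exons(self) -> frozenset[int]:
        return frozenset(e.index for e in self.exons if e.motif is not None)

    @property
    def grammar_ok(self) -> bool:
        return not validate_gene_model(self)

    @property
    def last_domain_odd_index(self) -> int:
        return 1 + 2 * self.n_repeats

    @property
    def tail_index(self) -> Optional[int]:
        return self.n_exons if self.has_tail else None

    def exon(self, index: int) -> ExonUnit:
        e = self.exons[index - 1]
        if e.index != index:
            raise KeyError(f"{self.name}: exon indices are not contiguous")
        return e

    def intron(self, index: int) -> IntronUnit:
        i = self.introns[index - 1]
        if i.index != index:
            raise KeyError(f"{self.name}: intron indices are not contiguous")
        return i

    @property
    def has_sequences(self) -> bool:
        return bool(self.exons) and all(e.sequence for e in self.exons)


@dataclass(frozen=True)
class Violation:
    """One grammar violation: which unit broke which rule."""

    unit: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.unit}] {self.rule}: {self.message}"


def validate_gene_model(gene: GeneModel) -> list[Violation]:
    """Check a gene against the superfamily grammar.

    The grammar is ``signal, (domain_even, domain_odd) x n, [tail]``
    with motifs confined to odd (domain_odd) exons, the tail exon
    terminal, stop codons in every odd intron, and -- when lengths are
    known -- a consistent codon phase pattern (signal and odd exons end
    on codon boundaries; even exons all share ``even_end_phase``).

    Never raises; returns an empty list iff the gene is conformant.
    """
    v: list[Violation] = []
    exons = gene.exons
    if not exons:
        return [Violation("gene", "empty", f"{gene.name} has no exons")]

    for pos, e in enumerate(exons, start=1):
        if e.index != pos:
            v.append(
                Violation(e.label, "indexing", f"exon at position {pos} has index {e.index}")
            )

    if exons[0].role is not ExonRole.SIGNAL:
        v.append(Violation("E1", "role_order", "first exon is not the signal-peptide exon"))
    for e in exons[1:]:
        if e.role is ExonRole.SIGNAL:
            v.append(Violation(e.label, "role_order", "signal role outside exon 1"))

    for e in exons[:-1]:
        if e.role is ExonRole.TAIL:
            v.append(Violation(e.label, "tail_position", "tail not terminal"))

    # Parity alternation of roles over the body of the gene.
    body = exons[1:-1] if gene.has_tail else exons[1:]
    for e in body:
        expected = ExonRole.DOMAIN_EVEN if e.index % 2 == 0 else ExonRole.DOMAIN_ODD
        if e.role in (ExonRole.SIGNAL, ExonRole.TAIL):
            continue  # reported above
        if e.role is not expected:
            if e.index == 2 and e.role is ExonRole.DOMAIN_ODD:
                msg = "first domain exon after signal is domain_odd"
            else:
                msg = f"{e.label} is {e.role.value}, expected {expected.value}"
            v.append(Violation(e.label, "parity_alternation", msg))

    if gene.n_repeats == 0:
        v.append(Violation("gene", "no_repeats", "no (domain_even, domain_odd) exon pair"))

    for e in exons:
        if e.motif is not None and e.role is not ExonRole.DOMAIN_ODD:
            v.append(
                Violation(e.label, "motif_placement", "motif on a non-domain_odd exon")
            )

    if len(gene.introns) != max(len(exons) - 1, 0):
        v.append(
            Violation(
                "gene",
                "intron_count",
                f"{len(gene.introns)} introns for {len(exons)} exons",
            )
        )
    else:
        for i in gene.introns:
            if i.index % 2 == 1 and not i.has_inframe_stop:
                v.append(
                    Violation(i.label, "odd_intron_stop", "odd intron lacks an in-frame stop")
                )

    # Phase consistency, only when lengths are known.  The final exon is
    # exempt (it may carry a stop codon and 3'UTR beyond the coding frame).
    if all(e.length_nt > 0 for e in exons):
        phase = 0
        for e in exons[:-1]:
            phase = (phase + e.length_nt) % 3
            if e.role in (ExonRole.SIGNAL, ExonRole.DOMAIN_ODD) and phase != 0:
                v.append(
                    Violation(e.label, "phase", f"{e.label} does not end on a codon boundary")
                )
            elif e.role is ExonRole.DOMAIN_EVEN and phase != gene.even_end_phase:
                v.append(
                    Violation(
                        e.label,
                        "phase",
                        f"{e.label} ends with phase {phase}, expected {gene.even_end_phase}",
                    )
                )
    return v


def intron_has_inframe_stop(sequence: str, donor_end_phase: int) -> bool:
    """True if the intron contains a stop codon in the reading frame
    carried over from the upstream exon chain.

    ``donor_end_phase`` nucleotides of the junction codon were already
    contributed by the donor exon, so codons lying fully inside the
    intron start at offset ``(3 - donor_end_phase) % 3``.
    """
    seq = sequence.upper()
    off = (3 - donor_end_phase) % 3
    return any(
        seq[i : i + 3] in _STOP_CODONS for i in range(off, len(seq) - 2, 3)
    )


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------

_GFF_SOURCE = "hirusplice"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _exon_offsets(gene: GeneModel) -> list[tuple[int, int]]:
    """(start, end) offsets of each exon within the gene body, 0-based,
    transcriptional order; introns fill the gaps."""
    offs = []
    pos = 0
    for k, e in enumerate(gene.exons):
        offs.append((pos, pos + e.length_nt - 1))
        pos += e.length_nt
        if k < len(gene.introns):
            intron = gene.introns[k]
            if intron.sequence is None:
                raise ValueError(
                    f"{gene.name}: architecture-only model (intron {intron.label} "
                    "has no sequence); cannot lay out genomic coordinates"
                )
            pos += len(intron.sequence)
    return offs


def _gene_body(gene: GeneModel) -> str:
    parts = []
    for k, e in enumerate(gene.exons):
        if e.sequence is None:
            raise ValueError(
                f"{gene.name}: architecture-only model (exon {e.label} has no sequence)"
            )
        parts.append(e.sequence)
        if k < len(gene.introns):
            parts.append(gene.introns[k].sequence or "")
    return "".join(parts)


def render_annotation(
    genes: Sequence[GeneModel],
    header_comments: Sequence[str] = (),
    flank: int = 40,
) -> tuple[str, str]:
    """Render genes with full sequences as (GFF3 text, FASTA text).

    Genes sharing an ``interval.seq_id`` are placed on one contig at
    their recorded coordinates; regions not covered by a gene body are
    N-filled.  Genes without an interval get one contig each.
    """
    placed: dict[str, list[tuple[GeneModel, GenomicInterval]]] = {}
    for g in genes:
        body_len = len(_gene_body(g))
        iv = g.interval
        if iv is None:
            iv = GenomicInterval(f"ctg_{g.name}", flank + 1, flank + body_len)
        elif iv.end - iv.start + 1 != body_len:
            iv = GenomicInterval(iv.seq_id, iv.start, iv.start + body_len - 1, iv.orientation)
        placed.setdefault(iv.seq_id, []).append((g, iv))

    gff_lines = ["##gff-version 3"]
    gff_lines += [f"# {c}" for c in header_comments]
    fasta_chunks = []
    for seq_id in sorted(placed):
        members = sorted(placed[seq_id], key=lambda t: t[1].start)
        contig_len = max(iv.end for _, iv in members) + flank
        contig = ["N"] * contig_len
        gff_lines.append(f"##sequence-region {seq_id} 1 {contig_len}")
        for g, iv in members:
            body = _gene_body(g)
            if iv.orientation is Orientation.RE_CO:
                body = _revcomp(body)
            contig[iv.start - 1 : iv.end] = list(body)
        for g, iv in members:
            strand = "-" if iv.orientation is Orientation.RE_CO else "+"
            gff_lines.append(
                "\t".join(
                    [
                        seq_id,
                        _GFF_SOURCE,
                        "gene",
                        str(iv.start),
                        str(iv.end),
                        ".",
                        strand,
                        ".",
                        f"ID={g.name};even_end_phase={g.even_end_phase}",
                    ]
                )
            )
            feats = []
            for e, (o1, o2) in zip(g.exons, _exon_offsets(g)):
                if iv.orientation is Orientation.FW:
                    gs, ge = iv.start + o1, iv.start + o2
                else:
                    gs, ge = iv.end - o2, iv.end - o1
                attrs = f"ID={g.name}.e{e.index};Parent={g.name};role={e.role.value}"
                if e.motif is not None:
                    attrs += f";motif={e.motif.value}"
                feats.append((gs, ge, strand, attrs))
            for gs, ge, strand, attrs in sorted(feats):
                gff_lines.append(
                    "\t".join(
                        [seq_id, _GFF_SOURCE, "exon", str(gs), str(ge), ".", strand, ".", attrs]
                    )
                )
        seq = "".join(contig)
        wrapped = "\n".join(seq[i : i + 70] for i in range(0, len(seq), 70))
        fasta_chunks.append(f">{seq_id}\n{wrapped}\n")
    return "\n".join(gff_lines) + "\n", "".join(fasta_chunks)


def write_gff3(
    genes: Sequence[GeneModel],
    gff3_path: str | Path,
    fasta_path: Optional[str | Path] = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Write genes (with sequences) to GFF3 and optionally genomic FASTA.

    Refuses architecture-only models: emitting exon features requires
    known exon/intron lengths, and fabricating sequence would be worse
    than failing.
    """
    gff, fasta = render_annotation(genes, header_comments=header_comments)
    Path(gff3_path).write_text(gff)
    if fasta_path is not None:
        Path(fasta_path).write_text(fasta)


def load_gene_models(
    annotation_path: str | Path,
    fasta_path: Optional[str | Path] = None,
) -> list[GeneModel]:
    """Read gene models from GFF3 (+ optional genomic FASTA).

    Exon features must carry ``role=signal|domain_even|domain_odd|tail``
    attributes (optional ``motif=RGD|KGD``) and share a ``Parent`` gene
    feature.  Exons are returned in transcriptional order; for
    minus-strand genes sequences are reverse-complemented.  Introns are
    inferred from the gaps between consecutive exons.
    """
    import gffutils

    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    fasta = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    models: list[GeneModel] = []
    gene_feats = sorted(
        db.features_of_type("gene"), key=lambda f: (f.seqid, f.start, f.id or "")
    )
    for gf in gene_feats:
        name = gf.id
        exon_feats = sorted(
            db.children(gf, featuretype="exon"), key=lambda f: f.start
        )
        if not exon_feats:
            raise ValueError(f"gene {name}: no exon features")
        for a, b in zip(exon_feats, exon_feats[1:]):
            if b.start <= a.end:
                raise ValueError(f"gene {name}: overlapping exons at {a.start}-{a.end}/{b.start}-{b.end}")
        minus = gf.strand == "-"
        if fasta is not None and gf.seqid not in fasta:
            raise ValueError(f"gene {name}: seq_id {gf.seqid!r} not present in FASTA")
        ordered = list(reversed(exon_feats)) if minus else exon_feats

        even_phase = 1
        if "even_end_phase" in gf.attributes:
            even_phase = int(gf.attributes["even_end_phase"][0])

        exons: list[ExonUnit] = []
        introns: list[IntronUnit] = []
        phase = 0
        for k, ef in enumerate(ordered, start=1):
            role_vals = ef.attributes.get("role")
            if not role_vals:
                raise ValueError(f"gene {name}: exon {ef.start}-{ef.end} lacks a role attribute")
            try:
                role = ExonRole(role_vals[0])
            except ValueError:
                raise ValueError(
                    f"gene {name}: unknown role {role_vals[0]!r} on exon {ef.start}-{ef.end}"
                ) from None
            motif_vals = ef.attributes.get("motif")
            motif = Motif(motif_vals[0]) if motif_vals else None
            seq = None
            if fasta is not None:
                raw = str(fasta[gf.seqid][ef.start - 1 : ef.end])
                seq = _revcomp(raw) if minus else raw
            length = ef.end - ef.start + 1
            phase = (phase + length) % 3
            exons.append(
                ExonUnit(
                    index=k,
                    role=role,
                    length_nt=length,
                    end_phase=phase,
                    motif=motif,
                    sequence=seq,
                )
            )
            if k < len(ordered):
                nf = ordered[k]
                if minus:
                    i_start, i_end = nf.end + 1, ef.start - 1
                else:
                    i_start, i_end = ef.end + 1, nf.start - 1
                iseq = None
                if fasta is not None:
                    raw = str(fasta[gf.seqid][i_start - 1 : i_end])
                    iseq = _revcomp(raw) if minus else raw
                if iseq is not None:
                    stop = intron_has_inframe_stop(iseq, phase)
                else:
                    # architecture default: the superfamily grammar puts
                    # in-frame stops in every odd intron
                    stop = k % 2 == 1
                introns.append(IntronUnit(index=k, has_inframe_stop=stop, sequence=iseq))
        interval = GenomicInterval(
            gf.seqid, gf.start, gf.end, Orientation.RE_CO if minus else Orientation.FW
        )
        models.append(
            GeneModel(
                name=name,
                exons=exons,
                introns=introns,
                interval=interval,
                even_end_phase=even_phase,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Packaged H. manillensis fixtures
# ---------------------------------------------------------------------------

# Architectures of the five decorsin-variant genes (shared by all three
# genome assemblies, except Hman_DV5 in the liu assembly -- see below).
_DV_ARCHITECTURE: dict[str, dict] = {
    "Hman_DV1": dict(n_repeats=6, has_tail=False, motifs={3: Motif.KGD}),
    "Hman_DV2": dict(n_repeats=4, has_tail=False, motifs={3: Motif.KGD, 9: Motif.RGD}),
    "Hman_DV3": dict(n_repeats=6, has_tail=True, motifs={3: Motif.RGD, 7: Motif.RGD}),
    "Hman_DV4": dict(n_repeats=1, has_tail=False, motifs={3: Motif.RGD}),
    "Hman_DV5": dict(n_repeats=6, has_tail=True, motifs={3: Motif.RGD}),
}

_HIRUDIN_GENES = ("Hman_HV1", "Hman_HV2", "Hman_HV3", "Hman_HV4", "Hman_TH")


def build_architecture(
    name: str,
    n_repeats: int,
    has_tail: bool,
    motifs: Mapping[int, Motif] | Mapping[int, str] = (),
    interval: Optional[GenomicInterval] = None,
    even_end_phase: int = 1,
) -> GeneModel:
    """Build an architecture-only gene model (length_nt=0, no sequences)."""
    motifs = {int(k): Motif(v) for k, v in dict(motifs).items()}
    exons = [ExonUnit(1, ExonRole.SIGNAL)]
    for r in range(n_repeats):
        exons.append(ExonUnit(2 * r + 2, ExonRole.DOMAIN_EVEN, end_phase=even_end_phase))
        idx = 2 * r + 3
        exons.append(ExonUnit(idx, ExonRole.DOMAIN_ODD, motif=motifs.get(idx)))
    if has_tail:
        exons.append(ExonUnit(len(exons) + 1, ExonRole.TAIL))
    introns = [
        IntronUnit(index=k, has_inframe_stop=(k % 2 == 1))
        for k in range(1, len(exons))
    ]
    return GeneModel(
        name=name, exons=exons, introns=introns, interval=interval,
        even_end_phase=even_end_phase,
    )


def _liu_dv5(interval: GenomicInterval) -> GeneModel:
    """The liu-assembly Hman_DV5 gene, which lacks exons 2-4 (large
    deletion) and is retained verbatim as an 11-exon, grammar-breaking
    fixture: signal, then the remnant starting with an odd (domain_odd)
    exon, then alternating roles up to the tail."""
    roles = [ExonRole.SIGNAL]
    # remnant of original E5..E13 (odd, even, ..., odd), then tail E14
    for k in range(9):
        roles.append(ExonRole.DOMAIN_ODD if k % 2 == 0 else ExonRole.DOMAIN_EVEN)
    roles.append(ExonRole.TAIL)
    exons = [ExonUnit(i + 1, role) for i, role in enumerate(roles)]
    introns = [
        IntronUnit(
            index=k,
            has_inframe_stop=exons[k - 1].role in (ExonRole.SIGNAL, ExonRole.DOMAIN_ODD),
        )
        for k in range(1, len(exons))
    ]
    return GeneModel(name="Hman_DV5", exons=exons, introns=introns, interval=interval)


def fixture_table(source: str):
    """Packaged Table-1 coordinates for one genome source as a DataFrame
    with columns gene, start, end, orientation (plus the seq_id attr)."""
    import pandas as pd

    if source not in GENOME_SOURCES:
        raise ValueError(f"unknown genome source {source!r}; choose from {GENOME_SOURCES}")
    ref = resources.files("hirusplice.data") / f"hman_coords_{source}.tsv"
    with resources.as_file(ref) as path:
        text = Path(path).read_text()
    seq_id = None
    for line in text.splitlines():
        if line.startswith("# seq_id:"):
            seq_id = line.split(":", 1)[1].strip()
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    df.attrs["seq_id"] = seq_id
    return df


def builtin_hman_genes(source: str) -> list[GeneModel]:
    """The ten *H. manillensis* gene fixtures for one genome source.

    Decorsin genes (Hman_DV1-5) come with full exon architectures but no
    sequences or exon lengths (the underlying study publishes only gene
    ranges); hirudin-cluster genes (Hman_HV1-4, Hman_TH) are
    coordinate-only entries used for cluster geometry.  For
    ``source="liu"`` the Hman_DV5 model reflects the deletion of exons
    2-4 and fails grammar validation.
    """
    df = fixture_table(source)
    seq_id = df.attrs["seq_id"]
    coords = {
        row.gene: GenomicInterval(seq_id, int(row.start), int(row.end), Orientation(row.orientation))
        for row in df.itertuples()
    }
    genes: list[GeneModel] = []
    for name, arch in _DV_ARCHITECTURE.items():
        if name == "Hman_DV5" and source == "liu":
            genes.append(_liu_dv5(coords[name]))
        else:
            genes.append(build_architecture(name, interval=coords[name], **arch))
    for name in _HIRUDIN_GENES:
        genes.append(GeneModel(name=name, interval=coords[name]))
    return genes
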