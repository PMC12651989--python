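"""Exhaustive splice-isoform enumeration under the parity junction rule.

Because even-indexed exons of hirudin-superfamily genes end mid-codon
and odd-indexed exons end on codon boundaries, a splice junction
preserves the reading frame only when it joins exons of opposite index
parity: odd exons splice to even exons and vice versa.  Combined with
two alternative-splicing mechanisms -- exon skipping (joining
non-adjacent exons) and terminal intron retention (every odd intron
carries an in-frame stop codon) -- this yields a finite, enumerable set
of splice products per gene.

For a tail-bearing gene with ``n`` globular-domain repeats, skip-only
enumeration produces exactly ``C(n+k, 2k)`` products with ``k`` domain
repeats and ``Fibonacci(2n+1) - 1`` products in total (excluding the
single zero-repeat chain); adding intron retention doubles every
multimericity class.

Products are identified by (exon chain, termination mode, retained
intron): sequence-identical products arising from distinct exon
combinations are distinct by default, since diversity is counted over
exon combinations.  Enumeration order is deterministic (lexicographic
by chain).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .gene_model import (
    ExonRole,
    ExonUnit,
    GeneModel,
    Violation,
    validate_gene_model,
)
from .protein_props import ProteinRecord

__all__ = [
    "Mechanism",
    "Termination",
    "EnumerationConfig",
    "SpliceProduct",
    "GrammarError",
    "junction_valid",
    "enumerate_isoforms",
    "count_by_multimericity",
    "motif_census",
    "monomeric_motif_variants",
    "assemble_and_translate",
    "products_to_table",
]


class Mechanism(str, enum.Enum):
    EXON_SKIPPING = "exon_skipping"
    INTRON_RETENTION = "intron_retention"


class Termination(str, enum.Enum):
    TAIL_SPLICE = "tail_splice"
    INTRON_RETENTION = "intron_retention"
    FINAL_EXON = "final_exon"


class Dedupe(str, enum.Enum):
    BY_CHAIN = "by_chain"
    BY_PROTEIN_SEQUENCE = "by_protein_sequence"


class GrammarError(ValueError):
    """Raised when an operation is asked to act on a grammar-breaking gene."""

    def __init__(self, gene: GeneModel, violations: Sequence[Violation]):
        self.violations = list(violations)
        msgs = "; ".join(str(v) for v in violations)
        super().__init__(f"gene {gene.name} violates the splice grammar: {msgs}")


@dataclass(frozen=True)
class EnumerationConfig:
    mechanisms: frozenset[Mechanism] = frozenset(
        {Mechanism.EXON_SKIPPING, Mechanism.INTRON_RETENTION}
    )
    include_zero_repeat: bool = False
    dedupe: Dedupe = Dedupe.BY_CHAIN
    max_products: Optional[int] = None

    def __post_init__(self) -> None:
        mechs = frozenset(Mechanism(m) for m in self.mechanisms)
        if not mechs:
            raise ValueError("mechanisms must be nonempty")
        object.__setattr__(self, "mechanisms", mechs)
        object.__setattr__(self, "dedupe", Dedupe(self.dedupe))


SKIP_ONLY = EnumerationConfig(mechanisms=frozenset({Mechanism.EXON_SKIPPING}))
RETAIN_ONLY = EnumerationConfig(mechanisms=frozenset({Mechanism.INTRON_RETENTION}))
SKIP_AND_RETAIN = EnumerationConfig()


@dataclass(frozen=True)
class SpliceProduct:
    """One splice isoform: an exon chain plus how translation terminates.

    ``k_repeats`` counts (even, odd) exon pairs in the chain, i.e. the
    multimericity of the encoded factor; ``motif_count`` is the number
    of chain exons that carry an RGD/KGD motif.
    """

    gene_name: str
    chain: tuple[int, ...]
    termination: Termination
    retained_intron: Optional[int] = None
    k_repeats: int = 0
    motif_count: int = 0
    motif_exons_present: frozenset[int] = frozenset()
    name: Optional[str] = None
    protein: Optional[ProteinRecord] = None

    def __post_init__(self) -> None:
        if not self.chain or self.chain[0] != 1:
            raise ValueError("chain must start at exon 1")
        for a, b in zip(self.chain, self.chain[1:]):
            if b <= a or (b - a) % 2 == 0:
                raise ValueError(
                    f"invalid chain {self.chain}: indices must strictly increase "
                    "with alternating parity"
                )
        if self.termination is Termination.INTRON_RETENTION:
            if self.retained_intron != self.chain[-1] or self.retained_intron % 2 == 0:
                raise ValueError(
                    "intron_retention products must retain the odd intron directly "
                    "after the last chain exon"
                )

    @property
    def chain_label(self) -> str:
        return "-".join(f"E{i}" for i in self.chain)


def junction_valid(
    donor: ExonUnit, acceptor: ExonUnit, gene: Optional[GeneModel] = None
) -> bool:
    """Frame-preserving junction test: the acceptor must lie downstream
    of the donor and differ in index parity; a tail exon never donates.

    If ``gene`` is given, both exons must be members of that gene.
    """
    if gene is not None:
        for e in (donor, acceptor):
            if e.index > gene.n_exons or gene.exons[e.index - 1] is not e:
                raise ValueError(
                    f"exon E{e.index} does not belong to gene {gene.name}"
                )
    if donor.role is ExonRole.TAIL:
        return False
    return acceptor.index > donor.index and (acceptor.index - donor.index) % 2 == 1


def enumerate_isoforms(
    gene: GeneModel, config: EnumerationConfig = SKIP_AND_RETAIN
) -> list[SpliceProduct]:
    """All splice products of a grammar-conformant gene.

    Chains start at exon 1 and extend through frame-compatible junctions
    (restricted to adjacent junctions when exon skipping is not among
    the mechanisms).  A chain terminates by (a) splicing an odd exon to
    the tail exon (tail_splice, exon skipping only), (b) retaining the
    in-frame-stop-bearing intron after an odd exon (intron_retention),
    or (c) ending at the gene's final exon when that is an odd exon
    (final_exon; the unspliced 3' end of tail-less genes).  Zero-repeat
    products are excluded unless requested.
    """
    violations = validate_gene_model(gene)
    if violations:
        raise GrammarError(gene, violations)

    mechs = config.mechanisms
    skip = Mechanism.EXON_SKIPPING in mechs
    retain = Mechanism.INTRON_RETENTION in mechs
    n_exons = gene.n_exons
    last_odd = gene.last_domain_odd_index
    tail_idx = gene.tail_index
    motif_exons = gene.motif_exons

    products: list[SpliceProduct] = []

    def emit(chain: tuple[int, ...], term: Termination, retained: Optional[int]) -> None:
        domain_members = [i for i in chain if 2 <= i <= last_odd]
        k = sum(1 for i in domain_members if i % 2 == 0)
        if k == 0 and not config.include_zero_repeat:
            return
        present = frozenset(i for i in chain if i in motif_exons)
        products.append(
            SpliceProduct(
                gene_name=gene.name,
                chain=chain,
                termination=term,
                retained_intron=retained,
                k_repeats=k,
                motif_count=len(present),
                motif_exons_present=present,
            )
        )
        if config.max_products is not None and len(products) > config.max_products:
            raise ValueError(
                f"product limit exceeded: more than {config.max_products} isoforms"
            )

    def extend(chain: tuple[int, ...]) -> None:
        i = chain[-1]
        if i % 2 == 1:  # chain currently ends on an odd exon (or E1)
            if retain and i < n_exons and gene.intron(i).has_inframe_stop:
                emit(chain, Termination.INTRON_RETENTION, i)
            if i == n_exons and tail_idx is None:
                emit(chain, Termination.FINAL_EXON, None)
            if tail_idx is not None and skip:
                emit(chain + (tail_idx,), Termination.TAIL_SPLICE, None)
        succ = range(i + 1, last_odd + 1) if skip else range(i + 1, min(i + 2, last_odd + 1))
        for j in succ:
            if (j - i) % 2 == 1:
                extend(chain + (j,))

    extend((1,))
    products.sort(key=lambda p: (p.chain, p.termination.value))

    if config.dedupe is Dedupe.BY_PROTEIN_SEQUENCE:
        if not gene.has_sequences:
            raise ValueError(
                f"{gene.name}: dedupe by protein sequence requires exon sequences"
            )
        seen: dict[str, SpliceProduct] = {}
        for p in products:
            prot = assemble_and_translate(gene, p)
            seen.setdefault(prot.sequence, p)
        products = sorted(seen.values(), key=lambda p: (p.chain, p.termination.value))
    return products


def count_by_multimericity(products: Iterable[SpliceProduct]) -> dict[int, int]:
    """Histogram of products over multimericity k (number of repeats)."""
    counts: dict[int, int] = {}
    for p in products:
        counts[p.k_repeats] = counts.get(p.k_repeats, 0) + 1
    return dict(sorted(counts.items()))


def motif_census(
    products: Iterable[SpliceProduct], gene: GeneModel
) -> dict[int, int]:
    """Histogram of products over the number of RGD/KGD motif exons
    present in the chain."""
    counts: dict[int, int] = {}
    for p in products:
        if p.gene_name != gene.name:
            raise ValueError(
                f"product from gene {p.gene_name!r} passed with gene {gene.name!r}"
            )
        counts[p.motif_count] = counts.get(p.motif_count, 0) + 1
    return dict(sorted(counts.items()))


def monomeric_motif_variants(genes: Iterable[GeneModel]) -> list[SpliceProduct]:
    """Deduce and name all monomeric, motif-bearing splice variants of
    multimeric genes.

    For each gene with at least two repeats, every k=1 product whose odd
    exon carries an RGD/KGD motif is emitted once per available
    termination: intron retention after the motif exon (or final_exon
    when the motif exon is the gene's last exon), plus splicing to the
    tail exon for tail-bearing genes.  Names follow the convention
    gene + "s" ("short"), with an ordinal when a gene yields more than
    one (motif exon, even partner) combination and an "a"/"b" suffix
    when both the retention and tail-splice variants exist.
    """
    out: list[SpliceProduct] = []
    for gene in genes:
        if gene.n_repeats < 2:
            warnings.warn(
                f"{gene.name}: fewer than two repeats, nothing to deduce "
                "(the gene is already monomeric)",
                stacklevel=2,
            )
            continue
        products = [
            p
            for p in enumerate_isoforms(gene, SKIP_AND_RETAIN)
            if p.k_repeats == 1 and p.motif_count >= 1
        ]
        # group by (motif exon, even partner); chain is (1, even, odd[, tail])
        combos: dict[tuple[int, int], list[SpliceProduct]] = {}
        for p in products:
            even, odd = p.chain[1], p.chain[2]
            combos.setdefault((odd, even), []).append(p)
        ordered = sorted(combos)
        multi = len(ordered) > 1
        for ordinal, key in enumerate(ordered, start=1):
            variants = sorted(combos[key], key=lambda p: p.termination is Termination.TAIL_SPLICE)
            lettered = len(variants) > 1
            for letter, p in zip("ab", variants):
                name = f"{gene.name}s"
                if multi:
                    name += f"-{ordinal}"
                if lettered:
                    name += letter
                out.append(replace(p, name=name))
    return out


def _stop_scan(protein: str) -> int:
    """Index of the first stop in a translated string, or -1."""
    return protein.find("*")


def assemble_and_translate(
    gene: GeneModel, product: SpliceProduct, genetic_code: int = 1
) -> ProteinRecord:
    """Concatenate the product's exon sequences (plus the retained
    intron, if any), translate from the start of exon 1's reading frame,
    and stop at the first stop codon.

    For intron-retention products the stop must fall inside the retained
    intron; a stop inside any exon other than the chain's final exon is
    an assembly error.  Refuses architecture-only models.
    """
    segments: list[tuple[str, str]] = []  # (label, sequence)
    phase = 0
    prev: Optional[ExonUnit] = None
    for idx in product.chain:
        exon = gene.exon(idx)
        if exon.sequence is None:
            raise ValueError(
                f"{gene.name}: architecture-only model (exon {exon.label} has no "
                "sequence); cannot assemble"
            )
        if prev is not None and not junction_valid(prev, exon):
            raise ValueError(
                f"{gene.name}: invalid junction {prev.label}->{exon.label} in chain"
            )
        segments.append((exon.label, exon.sequence))
        prev = exon
    if product.termination is Termination.INTRON_RETENTION:
        intron = gene.intron(product.retained_intron)
        if intron.sequence is None:
            raise ValueError(
                f"{gene.name}: architecture-only model (intron {intron.label} has no "
                "sequence); cannot assemble"
            )
        segments.append((intron.label, intron.sequence))

    # frame consistency at junctions: non-final exons must end on the
    # phase their role dictates
    phase = 0
    for label, seq in segments[:-1]:
        phase = (phase + len(seq)) % 3
        exon = gene.exon(int(label[1:])) if label.startswith("E") else None
        if exon is not None:
            expected = (
                gene.even_end_phase if exon.role is ExonRole.DOMAIN_EVEN else 0
            )
            if phase != expected:
                raise ValueError(
                    f"{gene.name}: frame mismatch at {label} junction "
                    f"(phase {phase}, expected {expected})"
                )

    nt = "".join(seq for _, seq in segments)
    trimmed = nt[: len(nt) - len(nt) % 3]
    protein = str(Seq(trimmed).translate(table=genetic_code))
    stop = _stop_scan(protein)

    final_label, final_seq = segments[-1]
    final_start_nt = len(nt) - len(final_seq)
    if stop >= 0:
        stop_nt = stop * 3
        if stop_nt < final_start_nt:
            # find the offending segment for the error message
            pos = 0
            for label, seq in segments:
                if pos <= stop_nt < pos + len(seq):
                    raise ValueError(
                        f"{gene.name}: internal stop codon inside {label} at "
                        f"transcript position {stop_nt + 1}"
                    )
                pos += len(seq)
        protein = protein[:stop]
    elif product.termination is Termination.INTRON_RETENTION:
        raise ValueError(
            f"{gene.name}: retained intron {final_label} contains no in-frame stop"
        )

    pid = product.name or f"{gene.name}:{product.chain_label}:{product.termination.value}"
    return ProteinRecord(pid, protein)


def products_to_table(products: Sequence[SpliceProduct]):
    """Products as a DataFrame with fixed column order (gene, chain,
    termination, retained_intron, k, motif_count, name)."""
    import pandas as pd

    rows = [
        {
            "gene": p.gene_name,
            "chain": p.chain_label,
            "termination": p.termination.value,
            "retained_intron": f"I{p.retained_intron}" if p.retained_intron else "",
            "k": p.k_repeats,
            "motif_count": p.motif_count,
            "name": p.name or "",
        }
        for p in products
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "chain", "termination", "retained_intron", "k", "motif_count", "name"],
    )
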