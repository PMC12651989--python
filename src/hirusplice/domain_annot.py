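"""Detection of hirudin-superfamily globular domains in proteins.

The globular domain is a six-cysteine scaffold stabilized by three
disulfide bonds; in platelet-aggregation inhibitors of the
decorsin/ornatin type an RGD (or KGD) integrin-binding tripeptide lies
between the fifth and the sixth cysteine.  Scanning is greedy from the
N-terminus: at each unconsumed cysteine we try to grow a six-cysteine
window whose consecutive gaps satisfy a configurable spacing envelope,
always taking the nearest admissible next cysteine (earliest-start,
shortest-hit).  This is a stated convention for resolving ambiguity
when cysteines cluster, not a claim about true domain boundaries.

The default spacing envelope accepts repeats of roughly 39-51 residues,
consistent with the lengths of monomeric decorsins; it is fully
configurable because real spacing varies across the superfamily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "CysSpacing",
    "DEFAULT_SPACING",
    "MotifHit",
    "DomainHit",
    "ArchitectureReport",
    "find_globular_domains",
    "annotate_motifs",
    "classify_architecture",
    "scan_fasta",
]

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")  # X tolerated, never matches C


@dataclass(frozen=True)
class CysSpacing:
    """Minimum/maximum residue counts between consecutive cysteines
    (gap = number of residues strictly between C_i and C_{i+1})."""

    gaps: tuple[tuple[int, int], ...] = (
        (2, 12),   # C1-C2
        (1, 12),   # C2-C3
        (1, 12),   # C3-C4
        (1, 15),   # C4-C5
        (3, 20),   # C5-C6
    )

    def __post_init__(self) -> None:
        if len(self.gaps) != 5:
            raise ValueError("exactly five C-C gap ranges required")
        for lo, hi in self.gaps:
            if lo < 0 or hi < lo:
                raise ValueError(f"bad gap range ({lo}, {hi})")


DEFAULT_SPACING = CysSpacing()


@dataclass(frozen=True)
class MotifHit:
    kind: str  # "RGD" or "KGD"
    position: int  # 1-based start of the tripeptide

    def __post_init__(self) -> None:
        if self.kind not in ("RGD", "KGD"):
            raise ValueError(f"motif kind must be RGD or KGD, got {self.kind!r}")


@dataclass(frozen=True)
class DomainHit:
    """One six-cysteine globular-domain match (1-based inclusive)."""

    start: int
    end: int
    cys_positions: tuple[int, ...]
    motif: Optional[MotifHit] = None

    def __post_init__(self) -> None:
        if len(self.cys_positions) != 6:
            raise ValueError("a domain hit needs exactly six cysteines")
        if list(self.cys_positions) != sorted(set(self.cys_positions)):
            raise ValueError("cysteine positions must be strictly increasing")


@dataclass(frozen=True)
class ArchitectureReport:
    sequence_id: str
    n_repeats: int
    motifs: tuple[tuple[int, str], ...]  # (repeat ordinal, kind)
    length_aa: int


def _check(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in protein sequence")
    return seq


def find_globular_domains(
    sequence: str, spacing: CysSpacing = DEFAULT_SPACING
) -> list[DomainHit]:
    """Maximal non-overlapping set of six-cysteine scaffold hits,
    scanned greedily left to right; deterministic."""
    seq = _check(sequence)
    if not seq:
        return []
    cys = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
    hits: list[DomainHit] = []
    i = 0
    while i < len(cys):
        chosen = [cys[i]]
        j = i
        ok = True
        for lo, hi in spacing.gaps:
            # nearest admissible next cysteine
            nxt_idx = None
            for k in range(j + 1, len(cys)):
                gap = cys[k] - chosen[-1] - 1
                if gap < lo:
                    continue
                if gap > hi:
                    break
                nxt_idx = k
                break
            if nxt_idx is None:
                ok = False
                break
            chosen.append(cys[nxt_idx])
            j = nxt_idx
        if ok:
            hits.append(
                DomainHit(start=chosen[0], end=chosen[-1], cys_positions=tuple(chosen))
            )
            i = j + 1
        else:
            i += 1
    return hits


def annotate_motifs(hit: DomainHit, sequence: str) -> DomainHit:
    """Attach the RGD/KGD motif lying strictly between C5 and C6, if
    any; when both occur, the leftmost wins and a warning is recorded."""
    import warnings

    seq = _check(sequence)
    c5, c6 = hit.cys_positions[4], hit.cys_positions[5]
    found: list[MotifHit] = []
    # tripeptide must lie strictly between the two cysteines
    for pos in range(c5 + 1, c6 - 2):  # 1-based start; end pos+2 <= c6-1
        tri = seq[pos - 1 : pos + 2]
        if tri in ("RGD", "KGD"):
            found.append(MotifHit(tri, pos))
    if not found:
        return hit
    if len(found) > 1:
        warnings.warn(
            f"multiple RGD/KGD motifs between C5 and C6 at {[m.position for m in found]}; "
            "taking the leftmost",
            stacklevel=2,
        )
    return DomainHit(hit.start, hit.end, hit.cys_positions, motif=found[0])


def classify_architecture(
    sequence_id: str, sequence: str, spacing: CysSpacing = DEFAULT_SPACING
) -> ArchitectureReport:
    """Repeat count and per-repeat motif annotation for one protein."""
    seq = _check(sequence)
    hits = [annotate_motifs(h, seq) for h in find_globular_domains(seq, spacing)]
    motifs = tuple(
        (ordinal, h.motif.kind)
        for ordinal, h in enumerate(hits, start=1)
        if h.motif is not None
    )
    return ArchitectureReport(
        sequence_id=sequence_id,
        n_repeats=len(hits),
        motifs=motifs,
        length_aa=len(seq),
    )


def scan_fasta(
    path: str | Path, spacing: CysSpacing = DEFAULT_SPACING
) -> list[ArchitectureReport]:
    """One architecture report per FASTA record, order preserved."""
    from Bio import SeqIO

    reports = []
    for k, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ValueError(f"malformed FASTA: record {k} has no identifier")
        try:
            reports.append(classify_architecture(rec.id, str(rec.seq), spacing))
        except ValueError as exc:
            raise ValueError(f"record {k} ({rec.id}): {exc}") from exc
    return reports


def reports_to_table(reports: Sequence[ArchitectureReport]):
    """TSV-shaped table: id, length_aa, n_repeats, motifs ('ordinal:kind')."""
    import pandas as pd

    rows = [
        {
            "id": r.sequence_id,
            "length_aa": r.length_aa,
            "n_repeats": r.n_repeats,
            "motifs": ",".join(f"{o}:{k}" for o, k in r.motifs),
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=["id", "length_aa", "n_repeats", "motifs"])
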