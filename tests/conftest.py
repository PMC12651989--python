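import math

import pytest

from hirusplice.gene_model import build_architecture, builtin_hman_genes


@pytest.fixture(scope="session")
def guan_genes():
    return {g.name: g for g in builtin_hman_genes("guan")}


@pytest.fixture(scope="session")
def dv3(guan_genes):
    return guan_genes["Hman_DV3"]


@pytest.fixture
def toy_gene():
    """Tail-bearing gene with two repeats and one motif."""
    return build_architecture("toy", n_repeats=2, has_tail=True, motifs={3: "RGD"})


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive: they enumerate subsets and
# apply the junction rule directly, sharing no code with the package).
# ---------------------------------------------------------------------------


def brute_force_skip_chains(n_repeats: int, has_tail: bool):
    """All exon chains reachable by exon skipping alone.

    Exons are 1..N with N = 1 + 2*n_repeats (+1 for a tail).  A chain is
    any subset containing exon 1 whose sorted members alternate index
    parity, terminating at the final exon (the tail for tail-bearing
    genes, the last odd exon otherwise).  Returns a list of tuples.
    """
    n_exons = 1 + 2 * n_repeats + (1 if has_tail else 0)
    middle = list(range(2, n_exons))
    chains = []
    for mask in range(1 << len(middle)):
        chain = [1] + [middle[i] for i in range(len(middle)) if mask >> i & 1] + [n_exons]
        if all((b - a) % 2 == 1 for a, b in zip(chain, chain[1:])):
            chains.append(tuple(chain))
    return chains


def brute_force_skip_census(n_repeats: int, has_tail: bool):
    """Multimericity histogram over the brute-force chains, excluding
    the zero-repeat chain."""
    counts: dict[int, int] = {}
    tail_idx = 1 + 2 * n_repeats + 1 if has_tail else None
    for chain in brute_force_skip_chains(n_repeats, has_tail):
        k = sum(1 for i in chain if i % 2 == 0 and i != tail_idx)
        if k > 0:
            counts[k] = counts.get(k, 0) + 1
    return counts


def closed_form_count(n: int, k: int) -> int:
    """C(n+k, 2k): skip-only products of multimericity k for a
    tail-bearing gene with n repeats."""
    return math.comb(n + k, 2 * k)


def fibonacci(m: int) -> int:
    a, b = 0, 1
    for _ in range(m):
        a, b = b, a + b
    return a
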