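"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written as brute-force enumerations or
direct recounts, independent of the production code paths they check.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pytest

from relicscan import formats as fio
from relicscan import lesions as les
from relicscan import reconstruct as rec
from relicscan import simulate as sim


# ---------------------------------------------------------------------------
# Spliced-alignment enumeration oracle (criterion: oracle equivalence)


def oracle_spliced_score(protein: str, dna: str, params: rec.ScoringParams) -> float:
    """Best local alignment score by memoized enumeration over op paths.

    Mirrors the aligner's move set (match/frameshift codons, affine
    protein/codon gaps, flat-penalty introns, start+end on a match) but is
    a top-down recursion with an explicit previous-op state rather than a
    layered forward DP.
    """
    m, n = len(protein), len(dna)
    mat = params.matrix()
    alphabet = mat.alphabet

    def S(a: str, b: str) -> float:
        return float(mat[a if a in alphabet else "X", b if b in alphabet else "X"])

    aa = [rec.translate(dna[j : j + 3]) for j in range(max(n - 2, 0))]
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def g(i: int, j: int, prev: str) -> float:
        best = 0.0 if prev == "M" else NEG
        for k in (1, 2, 3, 4, 5):
            if i < m and j + k <= n:
                sc = S(protein[i], aa[j]) if k == 3 else params.frameshift
                tail = g(i + 1, j + k, "M")
                if tail > NEG:
                    best = max(best, sc + tail)
        if prev != "NONE":
            if i < m:
                pen = params.gap_extend if prev == "A" else params.gap_open
                tail = g(i + 1, j, "A")
                if tail > NEG:
                    best = max(best, pen + tail)
            if j + 3 <= n:
                pen = params.gap_extend if prev == "B" else params.gap_open
                tail = g(i, j + 3, "B")
                if tail > NEG:
                    best = max(best, pen + tail)
            if prev != "I":
                for intron_len in range(params.min_intron, n - j + 1):
                    tail = g(i, j + intron_len, "I")
                    if tail > NEG:
                        best = max(best, params.intron_open + tail)
        return best

    best = 0.0
    for i in range(m):
        for j in range(n):
            best = max(best, g(i, j, "NONE"))
    return best


# ---------------------------------------------------------------------------
# Synteny brute force


def oracle_chain_length(ref_ids: list[str], query_ids: list[str]) -> int:
    """Maximum common-subsequence length by subset enumeration (n small)."""
    qpos = {g: i for i, g in enumerate(query_ids)}
    shared = [g for g in ref_ids if g in qpos]
    best = 0
    for r in range(len(shared), 0, -1):
        for combo in itertools.combinations(shared, r):
            positions = [qpos[g] for g in combo]
            if all(a < b for a, b in zip(positions, positions[1:])):
                return r
    return best


# ---------------------------------------------------------------------------
# Back-translation helper (one fixed codon per amino acid)


_CODON_OF = {}
for _codon, _aa in rec.CODON_TABLE.items():
    _CODON_OF.setdefault(_aa, _codon)


def back_translate(protein: str) -> str:
    return "".join(_CODON_OF[aa] for aa in protein)


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def two_exon_gene():
    bp = sim.GeneBlueprint(
        n_exons=2, exon_lengths=(123, 120), intron_lengths=(90,), seed=1
    )
    model, locus = sim.make_gene(bp, gene_id="gene")
    return model, locus


@pytest.fixture(scope="session")
def three_exon_gene():
    bp = sim.GeneBlueprint(
        n_exons=3, exon_lengths=(123, 120, 120), intron_lengths=(90, 75), seed=3
    )
    model, locus = sim.make_gene(bp, gene_id="gene3")
    return model, locus


@pytest.fixture(scope="session")
def reference(two_exon_gene):
    model, locus = two_exon_gene
    return les.ReferenceGene.from_genome({model.chrom: locus}, model)


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Session-scoped demo dataset (generated once; used by several tests)."""
    from relicscan import pipeline as pipe

    outdir = tmp_path_factory.mktemp("demo")
    configs = pipe.demo_dataset(outdir, seed=0)
    return configs


def random_marker_panel(seed: int, target: tuple):
    """Marker genes flanking a target entry, ready for assemble_genome."""
    entries = []
    for i, mid in enumerate(["mk_l2", "mk_l1"]):
        m, s = sim.make_marker_gene(mid, seed=seed + 10 + i)
        entries.append((mid, m, s))
    entries.append(target)
    for i, mid in enumerate(["mk_r1", "mk_r2"]):
        m, s = sim.make_marker_gene(mid, seed=seed + 20 + i)
        entries.append((mid, m, s))
    return entries
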