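"""Synteny anchoring: locate a candidate locus by chaining shared markers.

Markers are matched by identical gene_id; the chain is the longest subset
of shared markers appearing in the same relative order in both genomes
(a longest increasing subsequence over the query positions of the
reference-ordered shared markers).  Inversions are not chained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .formats import GeneModel, Interval

__all__ = [
    "MarkerOrder",
    "AnchorChain",
    "AnchoringError",
    "find_anchor_chain",
    "candidate_interval",
]


class AnchoringError(RuntimeError):
    """The requested anchors cannot bracket a candidate interval."""


@dataclass
class MarkerOrder:
    """Gene order of one genome: (gene_id, span interval), sorted by start."""

    genome_id: str
    markers: list[tuple[str, Interval]]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.markers]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.genome_id}: duplicate marker gene_ids")
        self.markers = sorted(self.markers, key=lambda m: (m[1].chrom, m[1].start))

    @classmethod
    def from_gene_models(cls, genome_id: str,
                         models: Sequence[GeneModel]) -> "MarkerOrder":
        return cls(genome_id, [(m.gene_id, m.span) for m in models])

    def index(self) -> dict[str, int]:
        return {g: i for i, (g, _) in enumerate(self.markers)}

    def interval_of(self, gene_id: str) -> Interval:
        for g, iv in self.markers:
            if g == gene_id:
                return iv
        raise KeyError(gene_id)


@dataclass
class AnchorChain:
    """Maximal collinear run of shared markers (gene_ids, reference order)."""

    pairs: list[str]
    collinear: bool

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def find_anchor_chain(reference: MarkerOrder, query: MarkerOrder) -> AnchorChain:
    """Longest run of shared markers in the same order in both genomes.

    Among equal-length chains the one earliest in reference order wins
    (lexicographically smallest reference positions).  No shared markers
    yields an empty, non-collinear chain.
    """
    qindex = query.index()
    shared = [(g, qindex[g]) for g, _ in reference.markers if g in qindex]
    if not shared:
        return AnchorChain(pairs=[], collinear=False)

    n = len(shared)
    # f[i] = length of the longest increasing (in query position) chain
    # starting at i
    f = [1] * n
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            if shared[j][1] > shared[i][1] and f[j] + 1 > f[i]:
                f[i] = f[j] + 1
    best = max(f)

    chain: list[str] = []
    prev_q = -1
    need = best
    start = 0
    for _ in range(best):
        for i in range(start, n):
            if f[i] == need and shared[i][1] > prev_q:
                chain.append(shared[i][0])
                prev_q = shared[i][1]
                start = i + 1
                need -= 1
                break
    return AnchorChain(pairs=chain, collinear=len(chain) == len(shared))


def candidate_interval(
    chain: AnchorChain,
    query: MarkerOrder,
    left_anchor: str,
    right_anchor: str,
) -> Interval:
    """Span between two anchor gene bodies on the query genome.

    Strand-agnostic arithmetic: the interval runs from the end of the
    left anchor to the start of the right anchor and excludes both gene
    bodies.  Anchors absent from the chain signal broken synteny.
    """
    for anchor in (left_anchor, right_anchor):
        if anchor not in chain:
            raise AnchoringError(
                f"anchor {anchor!r} not in the collinear chain: synteny not "
                "conserved around the locus"
            )
    left = query.interval_of(left_anchor)
    right = query.interval_of(right_anchor)
    if left.chrom != right.chrom:
        raise AnchoringError("anchors lie on different query chromosomes")
    if left.start > right.start:
        left, right = right, left
    if left.end >= right.start:
        raise AnchoringError(
            f"no intergenic space between {left_anchor!r} and {right_anchor!r}"
        )
    return Interval(left.chrom, left.end, right.start, "+")
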