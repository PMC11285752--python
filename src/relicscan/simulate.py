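"""Synthetic genomes, diverged orthologs, implanted lesions and read sets.

Everything is seeded: the same seed yields byte-identical FASTA/GTF/BED
output.  Lesion implantation records a truth set whose coordinates use the
same left-aligned convention as the classifier, and lesion sites are chosen
in unambiguous sequence context (an indel is never placed where it could
slide), so truth and detection coordinates are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .formats import (
    GeneModel,
    Interval,
    ReadSet,
    SeqRecordSet,
)
from .lesions import Lesion, reconstruct_orf
from .reconstruct import STOP_CODONS

__all__ = [
    "GeneBlueprint",
    "EvolutionParams",
    "LesionSpec",
    "ReadSimParams",
    "EvolveResult",
    "make_gene",
    "evolve",
    "implant_lesions",
    "assemble_genome",
    "make_marker_gene",
    "simulate_reads",
    "random_dna",
]

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Gene construction


@dataclass(frozen=True)
class GeneBlueprint:
    """Architecture of a synthetic gene: exon/intron lengths plus a seed."""

    n_exons: int
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_lengths", tuple(self.exon_lengths))
        object.__setattr__(self, "intron_lengths", tuple(self.intron_lengths))
        if self.n_exons < 1 or len(self.exon_lengths) != self.n_exons:
            raise ValueError("exon_lengths must match n_exons")
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValueError("need n_exons - 1 intron lengths")
        if any(l < 1 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        if any(l < 4 for l in self.intron_lengths):
            raise ValueError("intron lengths must be >= 4 (GT..AG)")
        total = sum(self.exon_lengths)
        if total % 3 != 0:
            raise ValueError("total CDS length must be a multiple of 3")
        if total < 9:
            raise ValueError("CDS must hold start, one codon and stop")


_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def make_gene(
    blueprint: GeneBlueprint,
    gene_id: str = "gene",
    chrom: str = "locus",
) -> tuple[GeneModel, str]:
    """Realize a blueprint as a locus sequence plus its gene model.

    The spliced CDS starts with ATG, ends with exactly one stop codon and
    contains none internally; every intron is GT...AG.  Coordinates are
    relative to the returned locus string (gene starts at 0, + strand).
    """
    rng = np.random.default_rng(blueprint.seed)
    total = sum(blueprint.exon_lengths)
    n_codons = total // 3
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    middle = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 2)
    cds = "ATG" + "".join(_NON_STOP_CODONS[i] for i in middle) + stop

    introns = []
    for length in blueprint.intron_lengths:
        introns.append("GT" + random_dna(rng, length - 4) + "AG")

    parts: list[str] = []
    exons: list[Interval] = []
    pos = 0
    offset = 0
    for i, elen in enumerate(blueprint.exon_lengths):
        parts.append(cds[offset : offset + elen])
        exons.append(Interval(chrom, pos, pos + elen, "+"))
        offset += elen
        pos += elen
        if i < blueprint.n_exons - 1:
            parts.append(introns[i])
            pos += len(introns[i])
    locus = "".join(parts)
    model = GeneModel(gene_id=gene_id, transcript_id=f"{gene_id}.t1", exons=exons)
    return model, locus


def make_marker_gene(gene_id: str, seed: int, chrom: str = "locus"
                     ) -> tuple[GeneModel, str]:
    """A small single-exon gene used as a synteny marker."""
    rng = np.random.default_rng(seed)
    n_codons = int(rng.integers(60, 140))
    bp = GeneBlueprint(n_exons=1, exon_lengths=(3 * n_codons,), seed=seed + 1)
    return make_gene(bp, gene_id=gene_id, chrom=chrom)


# ---------------------------------------------------------------------------
# Sequence edits with coordinate remapping


@dataclass(frozen=True)
class _Edit:
    pos: int          # original coordinate
    del_len: int
    ins: str

    @property
    def delta(self) -> int:
        return len(self.ins) - self.del_len


def _apply_edits(seq: str, edits: Sequence[_Edit]) -> tuple[str, Callable[[int], int]]:
    """Apply non-overlapping ascending edits; return new seq and a remapper
    for coordinates outside the edited spans."""
    for a, b in zip(edits, edits[1:]):
        if a.pos + a.del_len > b.pos:
            raise ValueError("overlapping edits")
    out: list[str] = []
    cursor = 0
    breakpoints: list[tuple[int, int]] = []  # (orig coordinate, cumulative delta)
    delta = 0
    for e in edits:
        out.append(seq[cursor : e.pos])
        out.append(e.ins)
        cursor = e.pos + e.del_len
        delta += e.delta
        breakpoints.append((cursor, delta))
    out.append(seq[cursor:])
    new_seq = "".join(out)

    def remap(x: int) -> int:
        d = 0
        for bp, bd in breakpoints:
            if x >= bp:
                d = bd
            else:
                break
        return x + d

    return new_seq, remap


def _remap_model(model: GeneModel, remap: Callable[[int], int]) -> GeneModel:
    exons = [
        Interval(e.chrom, remap(e.start), remap(e.end), e.strand)
        for e in model.exons
    ]
    return GeneModel(
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        exons=exons,
        cds_phase=[],
    )


# ---------------------------------------------------------------------------
# Neutral / purifying evolution


@dataclass(frozen=True)
class EvolutionParams:
    """Per-site substitution and indel-initiation probabilities.

    ``constrained=True`` is the purifying regime: whole mutation sets that
    would inactivate the gene (frameshift, premature stop, broken splice
    dinucleotide, lost start) are rejected and resampled.
    """

    sub_rate: float
    indel_rate: float = 0.0
    indel_mean: float = 2.0
    constrained: bool = False
    seed: int = 0
    max_tries: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.indel_mean < 1:
            raise ValueError("indel_mean must be >= 1")


@dataclass(frozen=True)
class MutationEvent:
    kind: str        # sub | ins | del
    position: int    # original coordinate
    length: int
    detail: str


@dataclass
class EvolveResult:
    sequence: str
    events: list[MutationEvent]
    model: GeneModel | None


def _draw_mutations(
    seq: str, params: EvolutionParams, rng: np.random.Generator
) -> tuple[list[MutationEvent], list[_Edit]]:
    n = len(seq)
    events: list[MutationEvent] = []
    edits: list[_Edit] = []

    sub_sites = np.flatnonzero(rng.random(n) < params.sub_rate)
    arr = np.array(list(seq))
    for pos in sub_sites:
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(0, 3)]
        arr[pos] = new
        events.append(MutationEvent("sub", int(pos), 1, f"{old}>{new}"))
    mutated = "".join(arr)

    indel_sites = np.flatnonzero(rng.random(n) < params.indel_rate)
    last_end = -1
    for pos in indel_sites:
        pos = int(pos)
        if pos <= last_end:
            continue  # drop overlapping initiations
        length = int(rng.geometric(1.0 / params.indel_mean))
        if rng.random() < 0.5:
            ins = random_dna(rng, length)
            edits.append(_Edit(pos, 0, ins))
            events.append(MutationEvent("ins", pos, length, ins))
            last_end = pos
        else:
            length = min(length, n - pos)
            if length == 0:
                continue
            edits.append(_Edit(pos, length, ""))
            events.append(MutationEvent("del", pos, length, mutated[pos : pos + length]))
            last_end = pos + length - 1
    return events, edits


def _is_intact(seq: str, model: GeneModel, events: Sequence[MutationEvent]) -> bool:
    for ev in events:
        if ev.kind == "sub":
            continue
        if ev.length % 3 == 0:
            continue
        span = Interval(model.chrom, ev.position, max(ev.position + ev.length, ev.position + 1), "+")
        if any(e.overlaps(span) for e in model.exons):
            return False  # frame-disrupting exonic indel
    try:
        report = reconstruct_orf({model.chrom: seq}, model)
    except ValueError:
        return False
    return report.intact and report.premature_stop is None


def evolve(sequence: str, gene_model: GeneModel | None,
           params: EvolutionParams) -> EvolveResult:
    """Mutate a sequence under the neutral or purifying regime.

    Returns the mutated sequence, the full event log (original
    coordinates) and the coordinate-remapped gene model (when given).
    Zero rates return the input unchanged with an empty log.
    """
    if params.constrained and gene_model is None:
        raise ValueError("constrained evolution requires a gene model")
    rng = np.random.default_rng(params.seed)
    for _ in range(params.max_tries if params.constrained else 1):
        events, edits = _draw_mutations(sequence, params, rng)
        # substitutions applied on original coordinates, then indels
        arr = list(sequence)
        for ev in events:
            if ev.kind == "sub":
                arr[ev.position] = ev.detail[-1]
        subbed = "".join(arr)
        new_seq, remap = _apply_edits(subbed, sorted(edits, key=lambda e: e.pos))
        new_model = _remap_model(gene_model, remap) if gene_model else None
        if not params.constrained:
            return EvolveResult(new_seq, events, new_model)
        if new_model is not None and _is_intact(new_seq, new_model, events):
            return EvolveResult(new_seq, events, new_model)
    raise RuntimeError(
        f"constrained evolution: no intact mutation set in {params.max_tries} tries"
    )


# ---------------------------------------------------------------------------
# Lesion implantation


@dataclass(frozen=True)
class LesionSpec:
    """Request for one implanted lesion.

    ``exon_index`` is 1-based; ``None`` lets the implanter choose.
    ``offset`` is a genome coordinate for explicit placement (frameshift /
    nonsense only); ``None`` draws a valid position.  Frameshifts take
    ``op`` ("del"/"ins") and ``length`` (1 or 2).
    """

    kind: str
    exon_index: int | None = None
    offset: int | None = None
    op: str = "del"
    length: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("frameshift", "nonsense", "splice_donor",
                             "splice_acceptor", "start_loss"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.kind == "frameshift":
            if self.op not in ("del", "ins"):
                raise ValueError("frameshift op must be del or ins")
            if self.length not in (1, 2):
                raise ValueError("frameshift length must be 1 or 2")


class LesionPlacementError(ValueError):
    """No valid, unambiguous site satisfies a lesion spec."""


def _cds_layout(model: GeneModel) -> list[tuple[int, int, int]]:
    """Per exon: (cds_offset_of_exon_start, genome_start, genome_end)."""
    out = []
    off = 0
    for e in model.exons:
        out.append((off, e.start, e.end))
        off += e.length
    return out


def _genome_to_cds(model: GeneModel, pos: int) -> int:
    off = 0
    for e in model.exons:
        if e.start <= pos < e.end:
            return off + (pos - e.start)
        off += e.length
    raise ValueError(f"position {pos} not exonic")


def implant_lesions(
    sequence: str,
    gene_model: GeneModel,
    specs: Sequence[LesionSpec],
    seed: int = 0,
) -> tuple[str, list[Lesion], GeneModel]:
    """Implant inactivating lesions; return (sequence, truth set, model).

    Truth coordinates are post-edit and left-aligned.  Constraints applied
    when drawing random positions: edits keep a 4 nt margin from exon
    boundaries, frameshift contexts are slide-proof, and nonsense codons
    are placed 5' of every frameshift so the stop remains in frame.
    Overlapping (closer than 4 nt) specs raise :class:`LesionPlacementError`.
    """
    if gene_model.strand != "+":
        raise ValueError("implant_lesions expects a + strand model")
    rng = np.random.default_rng(seed)
    cds_len = gene_model.exon_union_length
    n_codons = cds_len // 3
    taken: list[tuple[int, int]] = []  # genome spans already claimed

    def claim(lo: int, hi: int, explicit: bool) -> bool:
        for a, b in taken:
            if lo < b + 4 and a < hi + 4:
                if explicit:
                    raise LesionPlacementError(
                        f"lesion spec at [{lo},{hi}) overlaps another lesion"
                    )
                return False
        taken.append((lo, hi))
        return True

    # concrete edits: (Edit, spec, meta) resolved in two passes so nonsense
    # can be constrained 5' of every frameshift
    resolved: list[tuple[_Edit, LesionSpec, dict]] = []

    def exon_candidates(spec: LesionSpec) -> list[int]:
        if spec.exon_index is not None:
            if not (1 <= spec.exon_index <= len(gene_model.exons)):
                raise LesionPlacementError(
                    f"exon_index {spec.exon_index} out of range"
                )
            return [spec.exon_index - 1]
        return list(range(len(gene_model.exons)))

    ordered = sorted(
        enumerate(specs),
        key=lambda kv: (kv[1].kind != "frameshift", kv[0]),
    )

    min_fs_cds: int | None = None

    for _, spec in ordered:
        if spec.kind == "frameshift":
            placed = False
            positions: list[int]
            if spec.offset is not None:
                positions = [spec.offset]
            else:
                cands = []
                for ei in exon_candidates(spec):
                    e = gene_model.exons[ei]
                    lo = max(e.start + 4, gene_model.exons[0].start + 6)
                    hi = e.end - 4 - spec.length
                    cands.extend(range(lo, hi))
                rng.shuffle(cands := np.array(cands, dtype=int))
                positions = [int(p) for p in cands]
            for p in positions:
                if spec.op == "del":
                    block = sequence[p : p + spec.length]
                    # slide-proof: block cannot shift left or right
                    if sequence[p - 1] == block[-1] or sequence[p + spec.length] == block[0]:
                        if spec.offset is not None:
                            raise LesionPlacementError(
                                f"deletion at {p} is ambiguous (slideable)"
                            )
                        continue
                    if not claim(p, p + spec.length, spec.offset is not None):
                        continue
                    edit = _Edit(p, spec.length, "")
                    meta = {"truth_span": 1}
                else:
                    left, right = sequence[p - 1], sequence[p]
                    ins_first = [b for b in "ACGT" if b != left and b != right]
                    ins_last = [b for b in "ACGT" if b != left and b != right]
                    if not ins_first:
                        continue
                    if spec.length == 1:
                        ins = ins_first[int(rng.integers(0, len(ins_first)))]
                    else:
                        ins = (
                            ins_first[int(rng.integers(0, len(ins_first)))]
                            + ins_last[int(rng.integers(0, len(ins_last)))]
                        )
                    if not claim(p, p, spec.offset is not None):
                        continue
                    edit = _Edit(p, 0, ins)
                    meta = {"truth_span": spec.length}
                cds_off = _genome_to_cds(gene_model, p)
                meta.update(kind="frameshift", cds_off=cds_off)
                resolved.append((edit, spec, meta))
                min_fs_cds = cds_off if min_fs_cds is None else min(min_fs_cds, cds_off)
                placed = True
                break
            if not placed:
                raise LesionPlacementError("no unambiguous frameshift site found")

    for _, spec in ordered:
        if spec.kind == "frameshift":
            continue
        if spec.kind == "nonsense":
            hi_codon = int(0.9 * n_codons) - 1
            if min_fs_cds is not None:
                hi_codon = min(hi_codon, (min_fs_cds - 3) // 3 - 1)
            codons = []
            for ei in exon_candidates(spec):
                off0, gs, ge = _cds_layout(gene_model)[ei]
                first = -(-off0 // 3)  # first codon fully in exon
                last = (off0 + (ge - gs)) // 3 - 1
                for c in range(max(first, 1), min(last, hi_codon) + 1):
                    # codon fully inside exon with margin
                    g0 = gene_model.cds_to_genome(3 * c)
                    g2 = gene_model.cds_to_genome(3 * c + 2)
                    if g0 >= gs + 1 and g2 < ge - 1 and g2 == g0 + 2:
                        codons.append(c)
            if spec.offset is not None:
                codons = [c for c in codons
                          if gene_model.cds_to_genome(3 * c) == spec.offset]
            if not codons:
                raise LesionPlacementError("no valid nonsense codon available")
            order = np.array(codons, dtype=int)
            rng.shuffle(order)
            placed = False
            for c in (int(x) for x in order):
                g0 = gene_model.cds_to_genome(3 * c)
                current = sequence[g0 : g0 + 3]
                # substitution-created stop: require <= 2 changed bases so the
                # edit reads as mismatches, never as an indel pair
                ranked = sorted(
                    (sum(a != b for a, b in zip(s, current)), s)
                    for s in STOP_CODONS
                    if s != current
                )
                dist, stop = ranked[0]
                if dist > 2:
                    continue
                if not claim(g0, g0 + 3, spec.offset is not None):
                    continue
                resolved.append(
                    (_Edit(g0, 3, stop), spec,
                     {"kind": "nonsense", "codon": c, "stop": stop})
                )
                placed = True
                break
            if not placed:
                raise LesionPlacementError("nonsense site overlaps other lesions")
        elif spec.kind in ("splice_donor", "splice_acceptor"):
            introns = gene_model.introns()
            if not introns:
                raise LesionPlacementError("single-exon gene has no splice sites")
            if spec.kind == "splice_donor":
                idx = (spec.exon_index or 1) - 1
                if not (0 <= idx < len(introns)):
                    raise LesionPlacementError("donor exon_index out of range")
                intron = introns[idx]
                p = intron.start  # the G of GT
                new = "ACT"[int(rng.integers(0, 3))]
                claim(p, p + 2, True)
                resolved.append(
                    (_Edit(p, 1, new), spec,
                     {"kind": "splice_donor", "intron": idx + 1,
                      "site": (intron.start, intron.start + 2)})
                )
            else:
                idx = (spec.exon_index or 2) - 2
                if not (0 <= idx < len(introns)):
                    raise LesionPlacementError("acceptor exon_index out of range")
                intron = introns[idx]
                p = intron.end - 2  # the A of AG
                new = "CGT"[int(rng.integers(0, 3))]
                claim(p, p + 2, True)
                resolved.append(
                    (_Edit(p, 1, new), spec,
                     {"kind": "splice_acceptor", "intron": idx + 1,
                      "site": (intron.end - 2, intron.end)})
                )
        elif spec.kind == "start_loss":
            p = gene_model.cds_to_genome(0)
            # one substitution in ATG; none of the single-sub neighbours is a stop
            choice = int(rng.integers(0, 3))
            if choice == 0:
                edit = _Edit(p, 1, "CGT"[int(rng.integers(0, 3))])
            elif choice == 1:
                edit = _Edit(p + 1, 1, "ACG"[int(rng.integers(0, 3))])
            else:
                edit = _Edit(p + 2, 1, "ACT"[int(rng.integers(0, 3))])
            claim(p, p + 3, True)
            resolved.append((edit, spec, {"kind": "start_loss", "codon_start": p}))

    edits = sorted((e for e, _, _ in resolved), key=lambda e: e.pos)
    new_seq, remap = _apply_edits(sequence, edits)
    new_model = _remap_model(gene_model, remap)

    truth: list[Lesion] = []
    for edit, spec, meta in resolved:
        kind = meta["kind"]
        chrom = gene_model.chrom
        if kind == "frameshift":
            if edit.del_len:  # deletion: junction base after removed block
                np_pos = remap(edit.pos + edit.del_len)
                iv = Interval(chrom, np_pos, np_pos + 1, "+")
            else:
                # remap() at the insertion point includes the edit's own
                # shift; the inserted block itself starts before that
                np_pos = remap(edit.pos) - edit.delta
                iv = Interval(chrom, np_pos, np_pos + len(edit.ins), "+")
            exon_idx = new_model.exon_index_at(iv.start) or 1
            truth.append(
                Lesion(
                    kind="frameshift",
                    interval=iv,
                    exon_index=exon_idx,
                    cds_offset=_genome_to_cds(new_model, iv.start),
                    detail=f"implanted {spec.length} nt {spec.op}",
                )
            )
        elif kind == "nonsense":
            g0 = remap(edit.pos)
            iv = Interval(chrom, g0, g0 + 3, "+")
            truth.append(
                Lesion(
                    kind="nonsense",
                    interval=iv,
                    exon_index=new_model.exon_index_at(g0) or 1,
                    cds_offset=3 * meta["codon"],
                    detail=f"implanted stop {meta['stop']}",
                )
            )
        elif kind in ("splice_donor", "splice_acceptor"):
            s0, s1 = meta["site"]
            iv = Interval(chrom, remap(s0), remap(s0) + 2, "+")
            truth.append(
                Lesion(
                    kind=kind,
                    interval=iv,
                    exon_index=(meta["intron"] if kind == "splice_donor"
                                else meta["intron"] + 1),
                    detail="implanted splice-site edit",
                )
            )
        else:  # start_loss
            g0 = remap(meta["codon_start"])
            truth.append(
                Lesion(
                    kind="start_loss",
                    interval=Interval(chrom, g0, g0 + 3, "+"),
                    exon_index=1,
                    cds_offset=0,
                    detail="implanted start-codon edit",
                )
            )
    truth.sort(key=lambda l: (l.interval.start, l.interval.end, l.kind))
    return new_seq, truth, new_model


# ---------------------------------------------------------------------------
# Genome assembly


def assemble_genome(
    genes: Sequence[tuple[str, GeneModel, str]],
    intergenic_mean: int = 600,
    intergenic_min: int = 200,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[SeqRecordSet, list[GeneModel]]:
    """Concatenate gene loci in order with random intergenic spacers.

    ``genes`` are (gene_id, model-with-locus-local-coordinates, locus
    sequence); annotation order on the chromosome follows input order.
    """
    if intergenic_min < 1 or intergenic_mean <= intergenic_min:
        raise ValueError("need intergenic_mean > intergenic_min >= 1")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    models: list[GeneModel] = []
    pos = 0

    def spacer() -> str:
        length = int(rng.integers(intergenic_min, 2 * intergenic_mean - intergenic_min))
        return random_dna(rng, length)

    sp = spacer()
    parts.append(sp)
    pos += len(sp)
    for gene_id, model, locus in genes:
        shifted = GeneModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            exons=[e.shifted(pos, chrom) for e in model.exons],
            cds_phase=list(model.cds_phase),
        )
        models.append(shifted)
        parts.append(locus)
        pos += len(locus)
        sp = spacer()
        parts.append(sp)
        pos += len(sp)
    genome = SeqRecordSet({chrom: "".join(parts)})
    return genome, models


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class ReadSimParams:
    """Mixture of transcript-derived reads and uniform genomic noise."""

    expression: Mapping[str, float]
    noise_rate: float
    read_length: int
    n_reads: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise_rate <= 1):
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("read_length and n_reads must be positive")
        if any(w < 0 for w in self.expression.values()):
            raise ValueError("expression weights must be nonnegative")


def simulate_reads(
    genome: SeqRecordSet,
    annotations: Sequence[GeneModel],
    params: ReadSimParams,
) -> ReadSet:
    """Simulate one tissue library of mapped single-end reads.

    ``(1 - noise_rate) * n_reads`` reads are drawn from transcripts with
    probability proportional to weight x exon-union length and placed
    uniformly along the transcript (truncated at exon boundaries);
    the rest start uniformly on the genome.  ``library_total = n_reads``.
    """
    rng = np.random.default_rng(params.seed)
    n_noise = int(round(params.noise_rate * params.n_reads))
    n_tx = params.n_reads - n_noise

    by_id = {m.gene_id: m for m in annotations}
    weights = []
    genes = []
    for gene_id, w in params.expression.items():
        if gene_id not in by_id:
            raise ValueError(f"expression weight for unknown gene {gene_id!r}")
        if w > 0:
            genes.append(by_id[gene_id])
            weights.append(w * by_id[gene_id].exon_union_length)
    if n_tx > 0 and not genes:
        raise ValueError(
            "no positive expression weight but noise_rate < 1: nothing to sample"
        )

    reads: list[Interval] = []
    if n_tx > 0:
        probs = np.array(weights, dtype=float)
        probs /= probs.sum()
        counts = rng.multinomial(n_tx, probs)
        for model, count in zip(genes, counts):
            tx_len = model.exon_union_length
            starts = rng.integers(0, tx_len, size=count)
            for s in sorted(int(x) for x in starts):
                g = model.cds_to_genome(s)
                if model.strand == "+":
                    exon = model.exons[model.exon_index_at(g) - 1]
                    end = min(g + params.read_length, exon.end)
                    reads.append(Interval(model.chrom, g, end, "+"))
                else:
                    exon = model.exons[model.exon_index_at(g) - 1]
                    start = max(g + 1 - params.read_length, exon.start)
                    reads.append(Interval(model.chrom, start, g + 1, "-"))

    if n_noise > 0:
        chroms = list(genome.entries)
        lengths = np.array([len(genome.entries[c]) for c in chroms], dtype=float)
        if any(l <= params.read_length for l in lengths):
            raise ValueError("read_length exceeds a chromosome length")
        picks = rng.choice(len(chroms), size=n_noise, p=lengths / lengths.sum())
        for ci in picks:
            chrom = chroms[int(ci)]
            limit = len(genome.entries[chrom]) - params.read_length
            s = int(rng.integers(0, limit + 1))
            reads.append(Interval(chrom, s, s + params.read_length, "+"))

    return ReadSet(reads=reads, library_total=params.n_reads)


def write_truth_json(truth: Sequence[Lesion], path: str | Path) -> Path:
    from .lesions import write_lesions_json

    return write_lesions_json(truth, path)
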