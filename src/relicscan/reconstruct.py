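"""Motif scanning, frameshift-aware spliced alignment and exon-model inference.

The aligner is a local (Smith-Waterman-style) protein-vs-DNA dynamic
programme whose move set is:

* ``MATCH``  — one residue against k nucleotides, k in {1,2,3,5,4}; k == 3 is
  a scored (mis)match, any other k is a frameshift of k-3 charged a flat
  frameshift penalty;
* ``DELP``   — an unaligned protein residue (affine gap);
* ``DELC``   — an extra query codon, 3 nt (affine gap);
* ``INTRON`` — a skip of >= ``min_intron`` nt charged a flat intron-open
  penalty; two introns may not be adjacent.

Alignments must start and end with a ``MATCH``.  Traceback ties prefer
match > frameshift > protein gap > codon gap > intron, and shorter
frameshifts before longer ones, which pins frameshifts to the 5'-most
codon of any equivalence run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .formats import Interval, GeneModel, reverse_complement

__all__ = [
    "ScoringParams",
    "FrameTrack",
    "MotifHit",
    "AlignedBlock",
    "Frameshift",
    "SplicedAlignment",
    "ReconstructedModel",
    "ReconstructionFailure",
    "translate",
    "six_frame_translate",
    "motif_scan",
    "spliced_align",
    "infer_exon_model",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = tuple(_STANDARD.stop_codons)


def translate(dna: str) -> str:
    """Translate a nucleotide string codon-by-codon; ambiguous codons -> X."""
    dna = dna.upper()
    return "".join(
        CODON_TABLE.get(dna[i : i + 3], "X") for i in range(0, len(dna) - 2, 3)
    )


@dataclass(frozen=True)
class ScoringParams:
    """Scoring scheme for motif scans and spliced alignment.

    All penalties are <= 0; the frameshift penalty must be strictly below
    one gap extension so shifts are never free relative to gaps.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    frameshift: float = -15.0
    intron_open: float = -20.0
    min_intron: int = 30

    def __post_init__(self) -> None:
        for name in ("gap_open", "gap_extend", "frameshift", "intron_open"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be <= 0")
        if self.frameshift >= self.gap_extend:
            raise ValueError("frameshift penalty must be < gap_extend")
        if self.min_intron < 1:
            raise ValueError("min_intron must be positive")

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


def _scorer(params: ScoringParams):
    mat = params.matrix()
    alphabet = mat.alphabet

    def score(a: str, b: str) -> float:
        x = a if a in alphabet else "X"
        y = b if b in alphabet else "X"
        return float(mat[x, y])

    return score


# ---------------------------------------------------------------------------
# Six-frame translation


@dataclass(frozen=True)
class FrameTrack:
    """One of the six translation frames with its genome coordinate map."""

    frame: int  # 0-2 forward, 3-5 reverse-complement
    peptide: str
    dna_length: int
    chrom: str = "query"

    def codon_interval(self, pep_index: int) -> Interval:
        """Genome footprint (forward coordinates) of peptide position."""
        if not (0 <= pep_index < len(self.peptide)):
            raise IndexError(pep_index)
        if self.frame < 3:
            start = self.frame + 3 * pep_index
            return Interval(self.chrom, start, start + 3, "+")
        offset = (self.frame - 3) + 3 * pep_index
        end = self.dna_length - offset
        return Interval(self.chrom, end - 3, end, "-")

    def peptide_index(self, genome_pos: int) -> int:
        """Inverse of :meth:`codon_interval` (codon containing the position)."""
        if self.frame < 3:
            idx = (genome_pos - self.frame) // 3
        else:
            idx = (self.dna_length - (self.frame - 3) - genome_pos - 1) // 3
        if not (0 <= idx < len(self.peptide)):
            raise IndexError(genome_pos)
        return idx


def six_frame_translate(dna: str, chrom: str = "query") -> list[FrameTrack]:
    """Translate all six frames; stops are ``*``, ambiguous codons ``X``."""
    if len(dna) < 3:
        raise ValueError("dna shorter than one codon")
    dna = dna.upper()
    rc = reverse_complement(dna)
    tracks = []
    for f in range(3):
        tracks.append(FrameTrack(f, translate(dna[f:]), len(dna), chrom))
    for f in range(3):
        tracks.append(FrameTrack(3 + f, translate(rc[f:]), len(dna), chrom))
    return tracks


# ---------------------------------------------------------------------------
# Motif scanning


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    frame: int
    interval: Interval
    score: float


def motif_scan(
    tracks: Sequence[FrameTrack],
    motifs: Mapping[str, str],
    params: ScoringParams | None = None,
    min_score: float = 0.0,
) -> list[MotifHit]:
    """Score every ungapped window of each frame against each peptide motif.

    Returns hits with score >= ``min_score`` sorted by score descending,
    then genome position.
    """
    params = params or ScoringParams()
    score = _scorer(params)
    hits: list[MotifHit] = []
    for motif_id, motif in motifs.items():
        if len(motif) < 4:
            raise ValueError(f"motif {motif_id!r} shorter than 4 aa")
        m = len(motif)
        for track in tracks:
            pep = track.peptide
            for i in range(len(pep) - m + 1):
                window = pep[i : i + m]
                if "*" in window:
                    continue
                s = sum(score(a, b) for a, b in zip(motif, window))
                if s >= min_score:
                    first = track.codon_interval(i)
                    last = track.codon_interval(i + m - 1)
                    iv = Interval(
                        track.chrom,
                        min(first.start, last.start),
                        max(first.end, last.end),
                        first.strand,
                    )
                    hits.append(MotifHit(motif_id, track.frame, iv, s))
    hits.sort(key=lambda h: (-h.score, h.interval.start, h.frame, h.motif_id))
    return hits


# ---------------------------------------------------------------------------
# Frameshift-aware spliced alignment


@dataclass(frozen=True)
class AlignedBlock:
    """One gapless-in-genome block: protein [pstart,pend) vs dna [gstart,gend)."""

    pstart: int
    pend: int
    gstart: int
    gend: int
    identity_pct: float = 0.0


@dataclass(frozen=True)
class Frameshift:
    genome_pos: int  # start of the anomalous codon in query coordinates
    shift: int       # in {-2,-1,+1,+2}
    cds_offset: int  # offset of the event in the aligned protein (residues)


@dataclass
class SplicedAlignment:
    blocks: list[AlignedBlock]
    frameshifts: list[Frameshift]
    score: float
    identity_pct: float | None
    ops: list[tuple] = field(default_factory=list, repr=False)

    @property
    def empty(self) -> bool:
        return not self.blocks

    def genome_span(self) -> tuple[int, int] | None:
        if self.empty:
            return None
        return self.blocks[0].gstart, self.blocks[-1].gend

    def recompute_score(self, protein: str, dna: str,
                        params: ScoringParams) -> float:
        """Re-derive the score from the op list (self-consistency check)."""
        score_fn = _scorer(params)
        total = 0.0
        prev = None
        for op in self.ops:
            kind = op[0]
            if kind == "M":
                _, i, j, k = op
                if k == 3:
                    total += score_fn(protein[i], translate(dna[j : j + 3]))
                else:
                    total += params.frameshift
            elif kind == "DELP":
                total += params.gap_open if prev != "DELP" else params.gap_extend
            elif kind == "DELC":
                total += params.gap_open if prev != "DELC" else params.gap_extend
            elif kind == "INTRON":
                total += params.intron_open
            prev = kind
        return total


_NEG = float("-inf")

# MATCH consumption order encodes traceback preference: in-frame first,
# then +/-1 shifts, then +/-2.
_K_ORDER = (3, 2, 4, 1, 5)


def spliced_align(protein: str, dna: str,
                  params: ScoringParams | None = None) -> SplicedAlignment:
    """Optimal local spliced alignment of ``protein`` against ``dna``.

    Dynamic programme over four state layers (match, protein gap, codon
    gap, intron) with deterministic traceback; returns an empty alignment
    when nothing scores above zero.
    """
    params = params or ScoringParams()
    if len(protein) < 1 or len(dna) < 3:
        raise ValueError("need at least 1 residue and 3 nt")
    protein = protein.upper()
    dna = dna.upper()
    score_fn = _scorer(params)
    m, n = len(protein), len(dna)
    mi = params.min_intron

    # Precompute substitution scores: sub[i][j] = S(protein[i], codon at j).
    aa_at = [CODON_TABLE.get(dna[j : j + 3], "X") for j in range(max(n - 2, 0))]
    uniq_aa = set(aa_at)
    sub = [
        {aa: score_fn(res, aa) for aa in uniq_aa} for res in protein
    ]

    # Layers: M ends in MATCH, A in DELP, B in DELC, I in INTRON.
    M = [[_NEG] * (n + 1) for _ in range(m + 1)]
    A = [[_NEG] * (n + 1) for _ in range(m + 1)]
    B = [[_NEG] * (n + 1) for _ in range(m + 1)]
    I = [[_NEG] * (n + 1) for _ in range(m + 1)]
    # Parallel traceback pointers: (layer, i, j) of predecessor or None=start.
    Mp = [[None] * (n + 1) for _ in range(m + 1)]
    Ap = [[None] * (n + 1) for _ in range(m + 1)]
    Bp = [[None] * (n + 1) for _ in range(m + 1)]
    Ip = [[None] * (n + 1) for _ in range(m + 1)]

    best_score, best_cell = 0.0, None

    for i in range(m + 1):
        Mi, Ai, Bi, Ii = M[i], A[i], B[i], I[i]
        for j in range(n + 1):
            if i > 0:
                # MATCH layer: predecessor is best of {start, M, A, B, I}
                # at (i-1, j-k).
                best, ptr = _NEG, None
                for k in _K_ORDER:
                    jp = j - k
                    if jp < 0:
                        continue
                    if k == 3:
                        if jp >= len(aa_at):
                            continue
                        opscore = sub[i - 1][aa_at[jp]]
                    else:
                        opscore = params.frameshift
                    # start-fresh predecessor
                    cand = opscore
                    cptr = ("S", i - 1, jp, k)
                    row = i - 1
                    for layer, mat in (("M", M), ("A", A), ("B", B), ("I", I)):
                        v = mat[row][jp]
                        if v != _NEG and v + opscore > cand:
                            cand = v + opscore
                            cptr = (layer, row, jp, k)
                    if cand > best:
                        best, ptr = cand, cptr
                Mi[j] = best
                Mp[i][j] = ptr

                # DELP layer (consume 1 residue, 0 nt).
                best, ptr = _NEG, None
                for layer, mat, pen in (
                    ("M", M, params.gap_open),
                    ("B", B, params.gap_open),
                    ("I", I, params.gap_open),
                    ("A", A, params.gap_extend),
                ):
                    v = mat[i - 1][j]
                    if v != _NEG and v + pen > best:
                        best, ptr = v + pen, (layer, i - 1, j, None)
                Ai[j] = best
                Ap[i][j] = ptr

            if j >= 3:
                # DELC layer (consume 3 nt, 0 residues).
                best, ptr = _NEG, None
                for layer, mat, pen in (
                    ("M", M, params.gap_open),
                    ("A", A, params.gap_open),
                    ("I", I, params.gap_open),
                    ("B", B, params.gap_extend),
                ):
                    v = mat[i][j - 3]
                    if v != _NEG and v + pen > best:
                        best, ptr = v + pen, (layer, i, j - 3, None)
                Bi[j] = best
                Bp[i][j] = ptr

            # INTRON layer: open from {M,A,B} at j-min_intron, or extend.
            best, ptr = _NEG, None
            if j >= mi:
                for layer, mat in (("M", M), ("A", A), ("B", B)):
                    v = mat[i][j - mi]
                    if v != _NEG and v + params.intron_open > best:
                        best = v + params.intron_open
                        ptr = (layer, i, j - mi, None)
            if j >= 1 and Ii[j - 1] != _NEG:
                # extending the intron costs nothing further
                if Ii[j - 1] > best:
                    best, ptr = Ii[j - 1], ("I", i, j - 1, None)
            Ii[j] = best
            Ip[i][j] = ptr

            if Mi[j] != _NEG and Mi[j] > best_score:
                best_score, best_cell = Mi[j], (i, j)

    if best_cell is None:
        return SplicedAlignment([], [], 0.0, None, [])

    # Traceback (alignments end in the M layer).
    ops: list[tuple] = []
    layer, i, j = "M", *best_cell
    pointers = {"M": Mp, "A": Ap, "B": Bp, "I": Ip}
    while True:
        ptr = pointers[layer][i][j]
        if layer == "M":
            plyr, pi, pj, k = ptr
            ops.append(("M", pi, pj, k))
        elif layer == "A":
            plyr, pi, pj, _ = ptr
            ops.append(("DELP", pi, pj))
        elif layer == "B":
            plyr, pi, pj, _ = ptr
            ops.append(("DELC", pi, pj))
        else:  # intron: collapse extension chain into one op
            plyr, pi, pj, _ = ptr
            while plyr == "I":
                ptr = pointers["I"][pi][pj]
                plyr, pi, pj, _ = ptr
            ops.append(("INTRON", pi, pj, j - pj))
        if plyr == "S":
            break
        layer, i, j = plyr, pi, pj
    ops.reverse()

    # Assemble blocks (split at introns) and frameshifts.
    blocks: list[AlignedBlock] = []
    shifts: list[Frameshift] = []
    cur = None  # [pstart, pend, gstart, gend]
    identical = columns = 0
    blk_identical = blk_columns = 0

    def close_block() -> None:
        nonlocal cur, blk_identical, blk_columns
        if cur:
            pct = 100.0 * blk_identical / blk_columns if blk_columns else 0.0
            blocks.append(AlignedBlock(*cur, identity_pct=pct))
        cur = None
        blk_identical = blk_columns = 0

    for op in ops:
        kind = op[0]
        if kind == "INTRON":
            close_block()
            continue
        if kind == "M":
            _, i0, j0, k = op
            pe, ge = i0 + 1, j0 + k
            columns += 1
            blk_columns += 1
            if k == 3:
                if aa_at[j0] == protein[i0]:
                    identical += 1
                    blk_identical += 1
            else:
                shifts.append(Frameshift(j0, k - 3, i0))
        elif kind == "DELP":
            _, i0, j0 = op
            pe, ge = i0 + 1, j0
            columns += 1
            blk_columns += 1
        else:  # DELC
            _, i0, j0 = op
            pe, ge = i0, j0 + 3
            columns += 1
            blk_columns += 1
        if cur is None:
            cur = [op[1], pe, op[2], ge]
        else:
            cur[1] = max(cur[1], pe)
            cur[3] = ge
    close_block()

    identity = 100.0 * identical / columns if columns else None
    return SplicedAlignment(blocks, shifts, best_score, identity, ops)


# ---------------------------------------------------------------------------
# Exon model inference


class ReconstructionFailure(RuntimeError):
    """No motif hits and no alignment blocks to seed an exon model."""


@dataclass
class ReconstructedModel:
    model: GeneModel
    exon_confidence: list[str]  # "high" | "low" per exon
    notes: list[str] = field(default_factory=list)


def _snap(seq: str, pos: int, dinuc: str, side: str, window: int) -> int | None:
    """Nearest position where the splice dinucleotide sits.

    ``side`` = "donor": intron starts at returned pos (seq[pos:pos+2]==GT).
    ``side`` = "acceptor": intron ends at returned pos (seq[pos-2:pos]==AG).
    The search is wider on the intron-interior side (2x window): local
    alignments overhang *into* introns past the end of real homology, so
    the true site is more often found by retracting the boundary.  Ties
    prefer the 5'-most candidate.
    """
    if side == "donor":
        lo, hi = -2 * window, window
    else:
        lo, hi = -window, 2 * window
    candidates = []
    for delta in range(lo, hi + 1):
        p = pos + delta
        if side == "donor":
            if 0 <= p <= len(seq) - 2 and seq[p : p + 2] == dinuc:
                candidates.append((abs(delta), p))
        else:
            if 2 <= p <= len(seq) and seq[p - 2 : p] == dinuc:
                candidates.append((abs(delta), p))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][1]


def infer_exon_model(
    hits: Sequence[MotifHit],
    alignment: SplicedAlignment | None,
    expected_exon_count: int,
    average_exon_lengths: Sequence[int] | None,
    candidate: Interval,
    candidate_seq: str,
    gene_id: str = "reconstructed",
    snap_window: int = 12,
) -> ReconstructedModel:
    """Infer an exon model inside ``candidate`` from alignment blocks/hits.

    Alignment blocks seed exons; absent an alignment, overlapping motif
    hits are merged into seeds.  Seeds are grown toward the expected
    average exon lengths, then internal boundaries are snapped to the
    nearest GT donor / AG acceptor within ``snap_window`` nt (window 0
    disables snapping).  Exons that fail to snap are flagged low
    confidence.
    """
    notes: list[str] = []
    seeds: list[list[int]] = []  # [start, end) relative to candidate_seq
    seed_identity: dict[tuple[int, int], float] = {}
    if alignment is not None and not alignment.empty:
        for blk in alignment.blocks:
            seeds.append([blk.gstart, blk.gend])
            seed_identity[(blk.gstart, blk.gend)] = blk.identity_pct
    elif hits:
        ivs = sorted((h.interval.start, h.interval.end) for h in hits)
        cur = list(ivs[0])
        for s, e in ivs[1:]:
            if s <= cur[1]:
                cur[1] = max(cur[1], e)
            else:
                seeds.append(cur)
                cur = [s, e]
        seeds.append(cur)
        notes.append("seeded from motif hits only (no alignment)")
    if not seeds:
        raise ReconstructionFailure(
            "no alignment blocks and no motif hits inside candidate interval"
        )

    # Merge seeds closer than a plausible intron, then cap at expected count.
    merged: list[list[int]] = []
    for s, e in sorted(seeds):
        if merged and s - merged[-1][1] < 4:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if len(merged) < expected_exon_count:
        notes.append(
            f"only {len(merged)} of {expected_exon_count} expected exons "
            "seeded; remainder unrecoverable (low confidence)"
        )
    if len(merged) > expected_exon_count:
        keep = sorted(
            sorted(merged, key=lambda se: se[1] - se[0], reverse=True)[
                :expected_exon_count
            ]
        )
        notes.append(
            f"{len(merged)} seeds reduced to expected exon count "
            f"{expected_exon_count}"
        )
        merged = keep

    # Grow seeds toward the expected average lengths.  Terminal exons grow
    # outward first: a local alignment trims unalignable 5'/3' overhangs
    # (e.g. beyond a near-terminal frameshift), so the missing sequence
    # lies on the outer side.
    if average_exon_lengths:
        for idx, seed in enumerate(merged):
            target = (
                average_exon_lengths[idx]
                if idx < len(average_exon_lengths)
                else average_exon_lengths[-1]
            )
            deficit = target - (seed[1] - seed[0])
            if deficit <= 0:
                continue
            lo = 0 if idx == 0 else merged[idx - 1][1] + 4
            hi = len(candidate_seq) if idx == len(merged) - 1 else merged[idx + 1][0] - 4
            if idx == 0:
                grow_left = min(deficit, seed[0] - lo)
            elif idx == len(merged) - 1:
                grow_left = min(deficit - min(deficit, hi - seed[1]), seed[0] - lo)
            else:
                grow_left = min(deficit // 2, seed[0] - lo)
            seed[0] -= grow_left
            grow_right = min(deficit - grow_left, hi - seed[1])
            seed[1] += grow_right

    confidence: list[str] = []
    exons: list[Interval] = []
    for idx, (s, e) in enumerate(merged):
        conf = "high" if alignment is not None and not alignment.empty else "low"
        if conf == "high":
            # short or low-identity blocks are likely chance matches in
            # degraded sequence, not real exon remnants
            overlapping = [
                ((be - bs), pct) for (bs, be), pct in seed_identity.items()
                if bs < e and s < be
            ]
            if overlapping:
                span = sum(w for w, _ in overlapping)
                pct = min(p for _, p in overlapping)
                if pct < 60.0 or span < 30:
                    conf = "low"
                    notes.append(
                        f"exon {idx + 1}: weak support "
                        f"(identity {pct:.0f}%, {span} nt aligned)"
                    )
        if snap_window > 0:
            if idx < len(merged) - 1:  # donor after this exon
                snapped = _snap(candidate_seq, e, "GT", "donor", snap_window)
                if snapped is None:
                    conf = "low"
                    notes.append(f"exon {idx + 1}: no GT donor within window")
                else:
                    e = snapped
            if idx > 0:  # acceptor before this exon
                snapped = _snap(candidate_seq, s, "AG", "acceptor", snap_window)
                if snapped is None:
                    conf = "low"
                    notes.append(f"exon {idx + 1}: no AG acceptor within window")
                else:
                    s = snapped
            if idx == 0:  # CDS start: nearest ATG
                best = None
                for delta in sorted(range(-snap_window, snap_window + 1), key=abs):
                    p = s + delta
                    if 0 <= p <= len(candidate_seq) - 3 and (
                        candidate_seq[p : p + 3] == "ATG"
                    ):
                        best = p
                        break
                if best is None:
                    conf = "low"
                    notes.append("exon 1: no ATG start within window")
                else:
                    s = best
        exons.append(
            Interval(candidate.chrom, candidate.start + s, candidate.start + e, "+")
        )
        confidence.append(conf)

    model = GeneModel(gene_id=gene_id, transcript_id=f"{gene_id}.t1", exons=exons)
    return ReconstructedModel(model=model, exon_confidence=confidence, notes=notes)


# Stand-in conserved peptide motifs for NK-class homeodomain scanning; users
# supply their own FASTA for real analyses.
DEFAULT_MOTIFS: dict[str, str] = {
    "nk_helix3": "WFQNRRYKCKR",
    "nk_helix1": "RRKPRVLFSQAQ",
    "nk_tn": "FSVSHLL",
}
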