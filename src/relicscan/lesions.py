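"""ORF reconstruction, inactivating-lesion classification and identity.

A gene is *intact* when its spliced CDS starts with ATG, contains no
premature in-frame stop, and every intron retains canonical GT/AG splice
dinucleotides.  Lesion kinds: ``frameshift`` (exonic indel of length not
divisible by 3), ``nonsense`` (premature in-frame stop), ``splice_donor``
/ ``splice_acceptor`` (lost GT/AG), ``start_loss`` (first codon not ATG).

A premature stop that lies downstream of a frameshift is folded into the
frameshift lesion's detail rather than reported twice: the shifted frame,
not the substitution, is the inactivating event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .formats import GeneModel, Interval, SeqRecordSet
from .reconstruct import SplicedAlignment, translate

__all__ = [
    "Lesion",
    "OrfReport",
    "ReferenceGene",
    "reconstruct_orf",
    "classify_lesions",
    "percent_identity",
    "identity_matrix",
    "left_align_deletion",
    "left_align_insertion",
    "write_lesions_json",
]

LESION_KINDS = ("frameshift", "nonsense", "splice_donor", "splice_acceptor",
                "start_loss")


@dataclass
class Lesion:
    kind: str
    interval: Interval
    exon_index: int
    cds_offset: int | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")

    def key(self) -> tuple:
        """Identity for truth-set comparison (kind + exact coordinates)."""
        return (self.kind, self.interval.chrom, self.interval.start,
                self.interval.end)


@dataclass
class OrfReport:
    cds: str
    protein: str
    premature_stop: tuple[int, float] | None  # (codon index, fraction of ref)
    intact: bool
    start_ok: bool
    splice_ok: bool
    bad_introns: list[int] = field(default_factory=list)  # 1-based indices


@dataclass
class ReferenceGene:
    """Reference gene model with its CDS and derived protein."""

    model: GeneModel
    cds: str
    protein: str

    @classmethod
    def from_genome(cls, genome: SeqRecordSet | Mapping[str, str],
                    model: GeneModel) -> "ReferenceGene":
        cds = model.spliced_sequence(genome)
        prot = translate(cds)
        if prot.endswith("*"):
            prot = prot[:-1]
        return cls(model=model, cds=cds, protein=prot)


def reconstruct_orf(
    genome: SeqRecordSet | Mapping[str, str],
    model: GeneModel,
    reference_protein_length: int | None = None,
    premature_fraction: float = 0.95,
) -> OrfReport:
    """Splice the exon model, translate from the first codon, audit the ORF.

    A stop is *premature* when it occurs before ``premature_fraction`` of
    the reference protein length (the ORF's own codon count when no
    reference is given).
    """
    cds = model.spliced_sequence(genome)
    if len(cds) < 6:
        raise ValueError(f"gene {model.gene_id}: CDS shorter than 2 codons")
    protein = translate(cds)
    n_codons = len(protein)
    ref_len = reference_protein_length or n_codons
    stop_idx = protein.find("*")
    premature = None
    if stop_idx != -1:
        frac = stop_idx / ref_len
        if frac < premature_fraction:
            premature = (stop_idx, frac)

    seqs = genome.entries if isinstance(genome, SeqRecordSet) else genome
    chrom_seq = seqs[model.chrom]
    bad_introns: list[int] = []
    for idx, intron in enumerate(model.introns(), start=1):
        if model.strand == "+":
            donor = chrom_seq[intron.start : intron.start + 2]
            acceptor = chrom_seq[intron.end - 2 : intron.end]
        else:
            from .formats import reverse_complement

            donor = reverse_complement(chrom_seq[intron.end - 2 : intron.end])
            acceptor = reverse_complement(chrom_seq[intron.start : intron.start + 2])
        if donor != "GT" or acceptor != "AG":
            bad_introns.append(idx)

    start_ok = cds[:3] == "ATG"
    splice_ok = not bad_introns
    frame_ok = len(cds) % 3 == 0
    intact = start_ok and splice_ok and frame_ok and premature is None
    return OrfReport(
        cds=cds,
        protein=protein,
        premature_stop=premature,
        intact=intact,
        start_ok=start_ok,
        splice_ok=splice_ok,
        bad_introns=bad_introns,
    )


# ---------------------------------------------------------------------------
# Indel normalization (shared convention with the simulator's truth sets)


def left_align_deletion(seq: str, pos: int, deleted: str) -> int:
    """5'-most equivalent position of deleting ``deleted`` ending before
    ``pos`` in the *post-deletion* sequence ``seq``.

    Returns the canonical position such that re-inserting ``deleted`` at any
    equivalent point yields the same sequence.
    """
    while pos >= 1 and seq[pos - 1] == deleted[-1]:
        # sliding the deletion window one base left keeps seq identical only
        # if the deleted string is a rotation match
        deleted = seq[pos - 1] + deleted[:-1]
        pos -= 1
    return pos


def left_align_insertion(seq: str, pos: int, length: int) -> int:
    """5'-most equivalent start of an inserted block ``seq[pos:pos+length]``
    in the *post-insertion* sequence."""
    while pos >= 1 and seq[pos - 1] == seq[pos + length - 1]:
        pos -= 1
    return pos


# ---------------------------------------------------------------------------
# Classification


_NT_ALIGNER_CACHE: dict = {}


def _nt_aligner() -> Align.PairwiseAligner:
    if "nt" not in _NT_ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -6.0
        aligner.extend_gap_score = -1.0
        _NT_ALIGNER_CACHE["nt"] = aligner
    return _NT_ALIGNER_CACHE["nt"]


def _cds_indels(ref_cds: str, qry_cds: str) -> list[tuple[str, int, int]]:
    """Indels of a global nucleotide alignment as (kind, qry_offset, length).

    ``kind`` is "del" (bases missing from the query; offset = query position
    after which they are absent) or "ins" (extra query bases starting at
    offset).  Positions are left-normalized.
    """
    alignment = _nt_aligner().align(ref_cds, qry_cds)[0]
    ref_blocks, qry_blocks = alignment.aligned
    out: list[tuple[str, int, int]] = []
    for idx in range(1, len(ref_blocks)):
        ref_gap = ref_blocks[idx][0] - ref_blocks[idx - 1][1]
        qry_gap = qry_blocks[idx][0] - qry_blocks[idx - 1][1]
        qpos = int(qry_blocks[idx - 1][1])
        if ref_gap and not qry_gap:
            # extra bases in the reference = deletion from the query
            deleted = ref_cds[ref_blocks[idx - 1][1] : ref_blocks[idx][0]]
            qpos = left_align_deletion(qry_cds, qpos, deleted)
            out.append(("del", qpos, ref_gap))
        elif qry_gap and not ref_gap:
            qpos = int(qry_blocks[idx - 1][1])
            qstart = left_align_insertion(qry_cds, qpos, qry_gap)
            out.append(("ins", qstart, qry_gap))
        elif ref_gap and qry_gap:
            # double-sided gap: treat as net indel at the query position
            net = qry_gap - ref_gap
            if net:
                kind = "ins" if net > 0 else "del"
                out.append((kind, qpos, abs(net)))
    return out


def _codon_interval(model: GeneModel, codon_index: int) -> Interval:
    positions = [model.cds_to_genome(3 * codon_index + k) for k in range(3)]
    return Interval(model.chrom, min(positions), max(positions) + 1, model.strand)


def classify_lesions(
    reference: ReferenceGene | None,
    genome: SeqRecordSet | Mapping[str, str],
    model: GeneModel,
    orf: OrfReport | None = None,
    alignment: SplicedAlignment | None = None,
    premature_fraction: float = 0.95,
) -> list[Lesion]:
    """Classify inactivating lesions of ``model`` relative to a reference.

    Frameshifts come from the supplied spliced alignment when given,
    otherwise from a global nucleotide alignment of reference vs query CDS.
    Premature stops downstream of a frameshift are folded into that
    frameshift's detail; all lesions are reported in genome order.
    """
    ref_len = len(reference.protein) if reference else None
    if orf is None:
        orf = reconstruct_orf(genome, model, reference_protein_length=ref_len,
                              premature_fraction=premature_fraction)

    lesions: list[Lesion] = []

    # --- frameshifts
    frameshift_offsets: list[int] = []  # CDS offsets (nt) of shift events
    if alignment is not None and alignment.frameshifts:
        for fs in alignment.frameshifts:
            pos = fs.genome_pos
            exon_idx = model.exon_index_at(pos) or 0
            lesions.append(
                Lesion(
                    kind="frameshift",
                    interval=Interval(model.chrom, pos, pos + 1, model.strand),
                    exon_index=max(exon_idx, 1),
                    cds_offset=None,
                    detail=f"alignment frameshift {fs.shift:+d}",
                )
            )
            frameshift_offsets.append(3 * fs.cds_offset)
    elif reference is not None:
        for kind, qpos, length in _cds_indels(reference.cds, orf.cds):
            if length % 3 == 0:
                continue  # in-frame indel, not inactivating by itself
            anchor = min(qpos, len(orf.cds) - 1)
            gpos = model.cds_to_genome(anchor)
            exon_idx = model.exon_index_at(gpos) or len(model.exons)
            span = length if kind == "ins" else 1
            if model.strand == "+":
                iv = Interval(model.chrom, gpos, gpos + span, model.strand)
            else:
                iv = Interval(model.chrom, gpos - span + 1, gpos + 1, model.strand)
            lesions.append(
                Lesion(
                    kind="frameshift",
                    interval=iv,
                    exon_index=exon_idx,
                    cds_offset=qpos,
                    detail=f"{length} nt {kind} (frame {length % 3:+d})",
                )
            )
            frameshift_offsets.append(qpos)

    # --- premature stops.  Scan every in-frame stop before the threshold;
    # a stop with an upstream frameshift is that frameshift's induced stop
    # (annotated on it, scanning stops there: downstream codons are out of
    # frame), otherwise it is a nonsense lesion in its own right.
    n_ref = ref_len or max(len(orf.protein) - 1, 1)
    threshold = premature_fraction * n_ref
    for codon_idx, residue in enumerate(orf.protein):
        if residue != "*" or codon_idx >= threshold:
            continue
        stop_offset = 3 * codon_idx
        codon = orf.cds[stop_offset : stop_offset + 3]
        iv = _codon_interval(model, codon_idx)
        exon_idx = model.exon_index_at(iv.start if model.strand == "+" else iv.end - 1)
        upstream = [o for o in frameshift_offsets if o < stop_offset + 3]
        if upstream:
            target = min(upstream)
            for lesion in lesions:
                if lesion.kind == "frameshift" and (
                    lesion.cds_offset is None or lesion.cds_offset == target
                ):
                    lesion.detail += (
                        f"; induces stop codon {codon} at codon {codon_idx} "
                        f"(exon {exon_idx})"
                    )
                    break
            break
        lesions.append(
            Lesion(
                kind="nonsense",
                interval=iv,
                exon_index=exon_idx or 1,
                cds_offset=stop_offset,
                detail=(
                    f"premature stop {codon} at "
                    f"{100 * codon_idx / n_ref:.0f}% of reference"
                ),
            )
        )

    # --- splice sites
    seqs = genome.entries if isinstance(genome, SeqRecordSet) else genome
    chrom_seq = seqs[model.chrom]
    for idx, intron in enumerate(model.introns(), start=1):
        if model.strand == "+":
            donor_iv = Interval(model.chrom, intron.start, intron.start + 2, "+")
            accept_iv = Interval(model.chrom, intron.end - 2, intron.end, "+")
            donor = chrom_seq[donor_iv.start : donor_iv.end]
            acceptor = chrom_seq[accept_iv.start : accept_iv.end]
        else:
            from .formats import reverse_complement

            donor_iv = Interval(model.chrom, intron.end - 2, intron.end, "-")
            accept_iv = Interval(model.chrom, intron.start, intron.start + 2, "-")
            donor = reverse_complement(chrom_seq[donor_iv.start : donor_iv.end])
            acceptor = reverse_complement(chrom_seq[accept_iv.start : accept_iv.end])
        if donor != "GT":
            lesions.append(
                Lesion(
                    kind="splice_donor",
                    interval=donor_iv,
                    exon_index=idx,
                    detail=f"donor {donor} != GT after exon {idx}",
                )
            )
        if acceptor != "AG":
            lesions.append(
                Lesion(
                    kind="splice_acceptor",
                    interval=accept_iv,
                    exon_index=idx + 1,
                    detail=f"acceptor {acceptor} != AG before exon {idx + 1}",
                )
            )

    # --- start codon
    if not orf.start_ok:
        iv = _codon_interval(model, 0)
        lesions.append(
            Lesion(
                kind="start_loss",
                interval=iv,
                exon_index=1,
                cds_offset=0,
                detail=f"first codon {orf.cds[:3]} != ATG",
            )
        )

    lesions.sort(key=lambda l: (l.interval.start, l.interval.end, l.kind))
    return lesions


# ---------------------------------------------------------------------------
# Percent identity


_AA_ALIGNER_CACHE: dict = {}


def _aa_aligner() -> Align.PairwiseAligner:
    if "aa" not in _AA_ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _AA_ALIGNER_CACHE["aa"] = aligner
    return _AA_ALIGNER_CACHE["aa"]


def _aligned_strings(a: str, b: str) -> tuple[str, str]:
    alignment = _aa_aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def percent_identity(
    seq_a: str,
    seq_b: str,
    aligned: tuple[str, str] | None = None,
) -> float | None:
    """Percent identical columns over aligned columns, gaps included.

    Terminal overhangs (leading/trailing columns gapped in either row) are
    excluded from the denominator.  Returns ``None`` for an empty
    alignment.  Symmetric by construction.
    """
    if aligned is None:
        if not seq_a or not seq_b:
            return None
        sa, sb = (seq_a, seq_b) if seq_a <= seq_b else (seq_b, seq_a)
        aligned = _aligned_strings(sa, sb)
    row_a, row_b = aligned
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    lo = 0
    hi = len(row_a)
    while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    columns = hi - lo
    if columns <= 0:
        return None
    identical = sum(
        1
        for x, y in zip(row_a[lo:hi], row_b[lo:hi])
        if x == y and x != "-"
    )
    return 100.0 * identical / columns


def identity_matrix(sequences: Mapping[str, str]):
    """Symmetric percent-identity matrix (pandas DataFrame, diagonal 100)."""
    import pandas as pd

    names = list(sequences)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    mat = pd.DataFrame(100.0, index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            val = percent_identity(sequences[a], sequences[b])
            mat.loc[a, b] = mat.loc[b, a] = float("nan") if val is None else val
    return mat


# ---------------------------------------------------------------------------
# Serialization


def lesion_to_dict(lesion: Lesion) -> dict:
    return {
        "kind": lesion.kind,
        "chrom": lesion.interval.chrom,
        "start": lesion.interval.start,
        "end": lesion.interval.end,
        "strand": lesion.interval.strand,
        "exon_index": lesion.exon_index,
        "cds_offset": lesion.cds_offset,
        "detail": lesion.detail,
    }


def lesion_from_dict(d: Mapping) -> Lesion:
    return Lesion(
        kind=d["kind"],
        interval=Interval(d["chrom"], d["start"], d["end"], d.get("strand", "+")),
        exon_index=d["exon_index"],
        cds_offset=d.get("cds_offset"),
        detail=d.get("detail", ""),
    )


def write_lesions_json(lesions: Sequence[Lesion], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump([lesion_to_dict(l) for l in lesions], fh, indent=2)
        fh.write("\n")
    return path
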