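"""Read counting, RPKM/TPM and expression calls against an intergenic null.

The null is an empirical distribution of RPKM over randomly placed
non-exonic regions; a feature is called expressed only when it beats both
the null quantile and an absolute TPM floor, mirroring how transient
transcriptional noise is excluded by intergenic negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import GeneModel, Interval, ReadSet

__all__ = [
    "ExpressionRecord",
    "ExpressionThresholds",
    "NullDistribution",
    "SamplingError",
    "count_reads",
    "rpkm",
    "tpm",
    "sample_intergenic",
    "build_null",
    "expression_call",
    "write_expression_tsv",
]

# Table-shaped output header (tissue rows for one feature)
TABLE_COLUMNS = (
    "tissue",
    "mapped read total for gene",
    "mapped read total for tissue",
    "RPKM",
)


class SamplingError(RuntimeError):
    """Not enough intergenic space to place the requested null regions."""


class ConfigurationError(RuntimeError):
    """Thresholds or null distribution unusable as configured."""


@dataclass
class ExpressionThresholds:
    tpm_min: float = 0.5
    null_quantile: float = 0.95
    rounding: int = 3
    min_null_regions: int = 20

    def __post_init__(self) -> None:
        if self.tpm_min <= 0:
            raise ValueError("tpm_min must be > 0")
        if not (0 < self.null_quantile < 1):
            raise ValueError("null_quantile must lie in (0, 1)")


@dataclass
class ExpressionRecord:
    tissue: str
    feature_id: str
    mapped_reads: int
    library_total: int
    feature_length: int
    rpkm: float = field(init=False)
    tpm: float | None = None
    call: str | None = None

    def __post_init__(self) -> None:
        if self.library_total <= 0:
            raise ValueError("library_total must be positive")
        if self.feature_length <= 0:
            raise ValueError("feature_length must be positive")
        if self.mapped_reads < 0:
            raise ValueError("mapped_reads must be nonnegative")
        self.rpkm = rpkm(self.mapped_reads, self.library_total, self.feature_length)


@dataclass
class NullDistribution:
    regions: list[Interval]
    counts: list[int]
    rpkms: list[float]
    matched_length: bool = True

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def quantile(self, q: float) -> float:
        return float(np.quantile(np.asarray(self.rpkms, dtype=float), q))


# ---------------------------------------------------------------------------


def _exon_intervals(feature: GeneModel | Interval) -> list[Interval]:
    if isinstance(feature, Interval):
        return [feature]
    return list(feature.exons)


def _read_arrays(readset: ReadSet):
    """Columnar view of a ReadSet, cached on the object (reads are treated
    as immutable once counting starts)."""
    cached = getattr(readset, "_relicscan_arrays", None)
    if cached is not None and cached[0] == len(readset.reads):
        return cached[1]
    chroms = np.array([r.chrom for r in readset.reads])
    starts = np.array([r.start for r in readset.reads], dtype=np.int64)
    ends = np.array([r.end for r in readset.reads], dtype=np.int64)
    arrays = (chroms, starts, ends)
    object.__setattr__(readset, "_relicscan_arrays", (len(readset.reads), arrays))
    return arrays


def count_reads(readset: ReadSet, feature: GeneModel | Interval) -> int:
    """Reads overlapping the feature's exon union by >= 1 bp, counted once."""
    exons = _exon_intervals(feature)
    if not readset.reads:
        return 0
    chroms, starts, ends = _read_arrays(readset)
    hit = np.zeros(len(readset.reads), dtype=bool)
    for exon in exons:
        hit |= (chroms == exon.chrom) & (starts < exon.end) & (ends > exon.start)
    return int(hit.sum())


def rpkm(mapped_reads: int, library_total: int, feature_length: int) -> float:
    """Reads per kilobase of feature per million mapped reads.

    ``C * 1e9 / (N * L)``; exactly 0.0 when the count is 0.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if feature_length <= 0:
        raise ValueError("feature_length must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be nonnegative")
    if mapped_reads == 0:
        return 0.0
    return mapped_reads * 1e9 / (library_total * feature_length)


def tpm(counts: Mapping[str, int], lengths: Mapping[str, int]) -> dict[str, float]:
    """Transcripts per million over a full feature set.

    Length-normalized rates rescaled to sum to 1e6; an all-zero profile
    maps every feature to 0.0.
    """
    if set(counts) != set(lengths):
        raise ValueError("counts and lengths must cover the same features")
    rates = {}
    for fid, c in counts.items():
        if lengths[fid] <= 0:
            raise ValueError(f"feature {fid!r}: nonpositive length")
        if c < 0:
            raise ValueError(f"feature {fid!r}: negative count")
        rates[fid] = c / lengths[fid]
    total = sum(rates.values())
    if total == 0:
        return {fid: 0.0 for fid in counts}
    return {fid: 1e6 * r / total for fid, r in rates.items()}


# ---------------------------------------------------------------------------
# Intergenic null


def sample_intergenic(
    annotations: Sequence[GeneModel],
    genome_lengths: Mapping[str, int],
    n_regions: int,
    region_length: int,
    seed: int = 0,
) -> list[Interval]:
    """Uniformly sample non-exonic regions of fixed length.

    Sampling is uniform over every placeable start position (positions
    whose region would overlap no annotated exon), with replacement,
    deterministic under ``seed``.
    """
    if n_regions < 1 or region_length < 1:
        raise ValueError("n_regions and region_length must be positive")
    # merged exon union per chromosome
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome_lengths}
    for model in annotations:
        for e in model.exons:
            if e.chrom in by_chrom:
                by_chrom[e.chrom].append((e.start, e.end))
    gaps: list[tuple[str, int, int]] = []  # (chrom, gap_start, n_placeable)
    total_placeable = 0
    for chrom, length in genome_lengths.items():
        merged: list[list[int]] = []
        for s, e in sorted(by_chrom[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        bounds = [0] + [x for se in merged for x in se] + [length]
        for gs, ge in zip(bounds[::2], bounds[1::2]):
            placeable = (ge - gs) - region_length + 1
            if placeable > 0:
                gaps.append((chrom, gs, placeable))
                total_placeable += placeable
    if total_placeable == 0:
        raise SamplingError(
            f"no placeable start positions for regions of {region_length} bp "
            f"(need {n_regions})"
        )
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, total_placeable, size=n_regions)
    cumulative = np.cumsum([g[2] for g in gaps])
    regions: list[Interval] = []
    for d in draws:
        gi = int(np.searchsorted(cumulative, d, side="right"))
        chrom, gs, _ = gaps[gi]
        offset = int(d) - (int(cumulative[gi - 1]) if gi else 0)
        start = gs + offset
        regions.append(Interval(chrom, start, start + region_length, "+"))
    return regions


def build_null(
    readset: ReadSet,
    regions: Sequence[Interval],
    matched_length: bool = True,
) -> NullDistribution:
    counts = [count_reads(readset, r) for r in regions]
    rpkms = [rpkm(c, readset.library_total, r.length) for c, r in zip(counts, regions)]
    return NullDistribution(
        regions=list(regions),
        counts=counts,
        rpkms=rpkms,
        matched_length=matched_length,
    )


def expression_call(
    record: ExpressionRecord,
    null: NullDistribution,
    thresholds: ExpressionThresholds | None = None,
) -> str:
    """Call one tissue: ``expressed`` needs TPM above the floor AND RPKM
    above the null quantile; RPKM at or below the quantile is ``noise``;
    anything else is ``ambiguous``."""
    thresholds = thresholds or ExpressionThresholds()
    if null.n_regions < thresholds.min_null_regions:
        raise ConfigurationError(
            f"null has {null.n_regions} regions; need >= "
            f"{thresholds.min_null_regions}"
        )
    cutoff = null.quantile(thresholds.null_quantile)
    if record.rpkm <= cutoff:
        call = "noise"
    elif record.tpm is not None and record.tpm > thresholds.tpm_min:
        call = "expressed"
    else:
        call = "ambiguous"
    record.call = call
    return call


def write_expression_tsv(
    records: Sequence[ExpressionRecord],
    path: str | Path,
    rounding: int = 3,
) -> Path:
    """Emit the table-shaped TSV: one row per tissue for one feature."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for rec in records:
            value = round(rec.rpkm, rounding)
            text = "0" if value == 0 else f"{value:.{rounding}f}".rstrip("0").rstrip(".")
            fh.write(
                f"{rec.tissue}\t{rec.mapped_reads}\t{rec.library_total}\t{text}\n"
            )
    return path
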