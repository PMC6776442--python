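"""Selection of conserved, cell-type-specific candidate enhancers (GREs)
from ATAC-seq peak intervals, per-cell-type signal, and conservation scores.

The panel is built in four steps, mirroring comparative open-chromatin
screening practice:

1. merge overlapping peak intervals into a non-redundant reference list;
2. set a conservation cutoff from the score distribution of length-matched
   control intervals placed a fixed distance (default 100 kb) from each
   peak, taking the 95th percentile (nearest-rank definition);
3. scale each cell-type signal column to a common total (default 1e7) and
   score each peak as (target signal + 0.5) / (mean non-target signal + 0.5);
4. rank by that fold-enrichment and keep the top ``panel_size`` peaks
   (default 287).

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end <= start in {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakTable:
    """Peak intervals with per-cell-type mean ATAC signal and conservation."""

    intervals: list[GenomicInterval]
    signal: pd.DataFrame  # peaks x cell types, indexed by interval id
    conservation: pd.Series | None = None

    def __post_init__(self):
        ids = [iv.id for iv in self.intervals]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate interval ids")
        if len(self.signal) != len(self.intervals):
            raise ValidationError("signal row count != interval count")
        if not list(self.signal.index) == ids:
            self.signal = self.signal.loc[ids]
        if (self.signal.to_numpy() < 0).any():
            raise ValidationError("negative ATAC signal")
        if self.conservation is not None:
            self.conservation = self.conservation.loc[ids]

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]

    def subset(self, keep_ids) -> "PeakTable":
        keep = set(keep_ids)
        ivs = [iv for iv in self.intervals if iv.id in keep]
        cons = self.conservation.loc[[iv.id for iv in ivs]] if self.conservation is not None else None
        return PeakTable(
            intervals=ivs,
            signal=self.signal.loc[[iv.id for iv in ivs]],
            conservation=cons,
        )


@dataclass
class SelectionConfig:
    conservation_percentile: float = 95.0
    control_offset_bp: int = 100_000
    signal_scale: float = 1e7
    atac_pseudocount: float = 0.5
    panel_size: int = 287
    target_celltype: str = "Sst"

    def __post_init__(self):
        if not (0.0 < self.conservation_percentile < 100.0):
            raise ValidationError("conservation_percentile must be in (0, 100)")
        if self.control_offset_bp <= 0 or self.signal_scale <= 0:
            raise ValidationError("control_offset_bp and signal_scale must be positive")
        if self.atac_pseudocount <= 0 or self.panel_size < 1:
            raise ValidationError("atac_pseudocount and panel_size must be positive")


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of overlapping intervals, sorted by (chrom, start).

    Book-ended intervals (one ends exactly where the next starts) are NOT
    merged: half-open intervals that merely touch share no base.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ordered:
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(
                    prev.chrom, prev.start, iv.end,
                    id=f"{prev.chrom}:{prev.start}-{iv.end}",
                )
        else:
            out.append(
                GenomicInterval(iv.chrom, iv.start, iv.end,
                                id=f"{iv.chrom}:{iv.start}-{iv.end}")
            )
    return out


def distal_controls(
    peaks: list[GenomicInterval],
    offset_bp: int,
    chrom_sizes: dict[str, int],
) -> tuple[list[GenomicInterval], list[str]]:
    """Length-matched control intervals a fixed distance from each peak.

    Each control keeps its peak's length and starts at ``peak.start +
    offset_bp``; if that would run past the chromosome end, the control is
    mirrored to ``peak.start - offset_bp``. Peaks admitting neither
    placement are dropped and their ids returned.
    """
    controls: list[GenomicInterval] = []
    dropped: list[str] = []
    for pk in peaks:
        size = chrom_sizes.get(pk.chrom)
        if size is None:
            raise ValidationError(f"no chromosome size for {pk.chrom}")
        length = pk.length
        fwd = pk.start + offset_bp
        rev = pk.start - offset_bp
        if fwd + length <= size:
            controls.append(
                GenomicInterval(pk.chrom, fwd, fwd + length, id=f"{pk.id}_ctrl")
            )
        elif rev >= 0 and rev + length <= size:
            controls.append(
                GenomicInterval(pk.chrom, rev, rev + length, id=f"{pk.id}_ctrl")
            )
        else:
            dropped.append(pk.id)
    return controls, dropped


def conservation_threshold(control_scores, percentile: float = 95.0) -> float:
    """Nearest-rank percentile of the control score distribution:
    the ceil(p/100 * n)-th order statistic."""
    scores = np.asarray(control_scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("empty control score distribution")
    if not (0.0 < percentile <= 100.0):
        raise ValidationError("percentile must be in (0, 100]")
    k = math.ceil(percentile / 100.0 * scores.size)
    return float(np.sort(scores)[k - 1])


def filter_conserved(peaks: PeakTable, threshold: float) -> PeakTable:
    """Retain peaks with conservation >= threshold (ties retained)."""
    if peaks.conservation is None or peaks.conservation.isna().any():
        raise ValidationError("conservation scores missing")
    keep = peaks.conservation[peaks.conservation >= threshold].index
    return peaks.subset(keep)


def normalize_signal(signal: pd.DataFrame, scale: float = 1e7) -> pd.DataFrame:
    """Scale each cell-type column so its total equals ``scale``."""
    totals = signal.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"zero-total signal column(s): {bad}")
    return signal * (scale / totals)


def atac_enrichment(
    norm_signal: pd.DataFrame,
    target: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-peak specificity score:
    (target signal + c) / (mean of non-target signals + c)."""
    if target not in norm_signal.columns:
        raise ValidationError(f"unknown target cell type {target!r}")
    if norm_signal.shape[1] < 2:
        raise ValidationError("need at least two cell types")
    rest = norm_signal.drop(columns=[target]).mean(axis=1)
    return (norm_signal[target] + pseudocount) / (rest + pseudocount)


def select_panel(
    scores: pd.Series,
    k: int,
    target_signal: pd.Series | None = None,
) -> pd.Series:
    """Top-``k`` peaks in descending score order.

    Ties are broken by higher target-type signal (when supplied), then by
    original input order, so the ranking is deterministic.
    """
    if k > len(scores):
        raise ValidationError(f"k={k} exceeds number of peaks {len(scores)}")
    pos = np.arange(len(scores))
    tsig = (
        target_signal.loc[scores.index].to_numpy()
        if target_signal is not None
        else np.zeros(len(scores))
    )
    order = np.lexsort((pos, -tsig, -scores.to_numpy()))
    return scores.iloc[order[:k]]


def select_gre_panel(
    peaks: PeakTable,
    control_scores,
    config: SelectionConfig,
) -> pd.DataFrame:
    """Run the full selection: conservation filter, normalization,
    fold-enrichment scoring, top-k ranking.

    Returns a DataFrame (one row per selected GRE, ranked) with columns
    ``rank``, ``score``, ``conservation``, and the normalized per-type
    signal.
    """
    threshold = conservation_threshold(control_scores, config.conservation_percentile)
    conserved = filter_conserved(peaks, threshold)
    if len(conserved.intervals) == 0:
        raise ValidationError("no peaks pass the conservation threshold")
    norm = normalize_signal(conserved.signal, config.signal_scale)
    scores = atac_enrichment(norm, config.target_celltype, config.atac_pseudocount)
    k = min(config.panel_size, len(scores))
    if config.panel_size > len(scores):
        raise ValidationError(
            f"panel_size {config.panel_size} exceeds {len(scores)} conserved peaks"
        )
    ranked = select_panel(scores, k, target_signal=norm[config.target_celltype])
    out = pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "score": ranked.to_numpy(),
            "conservation": conserved.conservation.loc[ranked.index].to_numpy(),
        },
        index=ranked.index,
    )
    out = out.join(norm.loc[ranked.index])
    out.index.name = "gre_id"
    return out


# ---------------------------------------------------------------------------
# plain-text I/O (BED and TSV)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ / BED6 intervals (name column used as id when present)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{i+1}: fewer than 3 BED fields")
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else f"peak{i}"
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), id=name)
            )
    return out


def write_bed(intervals: list[GenomicInterval], path, scores=None) -> None:
    """Write BED6 (score column filled from ``scores`` when given)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0.0 if scores is None else float(scores[iv.id])
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{score:.6g}\t.\n")


def read_signal_tsv(path) -> pd.DataFrame:
    """TSV with a peak_id column followed by one column per cell type."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def read_conservation_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0]).iloc[:, 0]
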