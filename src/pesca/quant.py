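"""Mismatch-tolerant deconvolution of viral reporter barcodes from
single-nucleus reads into UMI-deduplicated count matrices.

Reads are (cell barcode, UMI, observed 10-mer) records. Each observed
sequence is compared to the designed barcode set by Hamming distance
(substitutions only, against a fixed-length window — indel-tolerant
matching is out of scope) and classified:

``assigned``
    exactly one barcode within ``max_mismatch`` (default 1) AND no second
    barcode within ``uniqueness_radius`` (default 2);
``ambiguous``
    two or more barcodes within the uniqueness radius;
``unassigned``
    otherwise.

Because a validated design guarantees pairwise distance >= 3, two barcodes
within one mismatch of the same read are impossible; this is asserted at
match time rather than assumed. Duplicate (cell, UMI, barcode) triples are
condensed to a single molecule count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .barcodes import BarcodeSet, GreBarcodeMap, encode_sequences
from .errors import ValidationError

READ_COLUMNS = ("cell_barcode", "umi", "sequence")


@dataclass
class AssignmentPolicy:
    max_mismatch: int = 1
    uniqueness_radius: int = 2

    def __post_init__(self):
        if self.max_mismatch < 0 or self.uniqueness_radius < 0:
            raise ValidationError("mismatch parameters must be non-negative")
        if self.max_mismatch > self.uniqueness_radius:
            raise ValidationError("max_mismatch must be <= uniqueness_radius")


@dataclass
class MatchResult:
    status: str  # "assigned" | "ambiguous" | "unassigned"
    barcode: str | None = None
    distance: int | None = None


@dataclass
class QCReport:
    n_reads: int = 0
    n_bad_length: int = 0
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0
    n_whitelist_rejected: int = 0
    n_cells: int = 0
    n_umis: int = 0

    @property
    def frac_not_unique(self) -> float:
        """Fraction of length-valid viral reads that could not be uniquely
        assigned to a known barcode (the screen's library-integrity QC
        statistic)."""
        considered = self.n_assigned + self.n_ambiguous + self.n_unassigned
        if considered == 0:
            return 0.0
        return (self.n_ambiguous + self.n_unassigned) / considered

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frac_not_unique"] = self.frac_not_unique
        return d

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class CellByFeatureMatrix:
    """UMI counts, cells x features (barcodes or GREs)."""

    cells: list[str]
    features: list[str]
    counts: sp.csr_matrix

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.features)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.cells, columns=self.features)

    def save(self, outdir, prefix: str = "counts") -> None:
        """MatrixMarket + cells/features TSV sidecars."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / f"{prefix}.mtx"), sp.coo_matrix(self.counts))
        (outdir / f"{prefix}.cells.tsv").write_text(
            "\n".join(self.cells) + ("\n" if self.cells else "")
        )
        (outdir / f"{prefix}.features.tsv").write_text(
            "\n".join(self.features) + ("\n" if self.features else "")
        )

    @classmethod
    def load(cls, outdir, prefix: str = "counts") -> "CellByFeatureMatrix":
        outdir = Path(outdir)
        counts = sp.csr_matrix(mmread(str(outdir / f"{prefix}.mtx")))
        cells = (outdir / f"{prefix}.cells.tsv").read_text().splitlines()
        features = (outdir / f"{prefix}.features.tsv").read_text().splitlines()
        return cls(cells=cells, features=features, counts=counts)


def _classify_unique(
    uniq_mat: np.ndarray,
    bc_mat: np.ndarray,
    policy: AssignmentPolicy,
    min_distance: int,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """For each unique sequence return (assigned barcode index or -1,
    status code 0=assigned 1=ambiguous 2=unassigned)."""
    n = len(uniq_mat)
    assigned = np.full(n, -1, dtype=np.int64)
    status = np.full(n, 2, dtype=np.int8)
    for lo in range(0, n, chunk):
        block = uniq_mat[lo : lo + chunk]
        # (b, m) Hamming distances
        dists = (block[:, None, :] != bc_mat[None, :, :]).sum(axis=2)
        n_within_m = (dists <= policy.max_mismatch).sum(axis=1)
        n_within_r = (dists <= policy.uniqueness_radius).sum(axis=1)
        if min_distance >= 2 * policy.max_mismatch + 1 and (n_within_m > 1).any():
            raise AssertionError(
                "two barcodes within max_mismatch of one read despite a "
                f"pairwise distance >= {min_distance} design"
            )
        nearest = dists.argmin(axis=1)
        ok = (n_within_m == 1) & (n_within_r == 1)
        amb = n_within_r >= 2
        idx = np.arange(lo, lo + len(block))
        assigned[idx[ok]] = nearest[ok]
        status[idx[ok]] = 0
        status[idx[amb]] = 1
    return assigned, status


def match_barcode(
    sequence: str,
    bset: BarcodeSet,
    policy: AssignmentPolicy | None = None,
) -> MatchResult:
    """Classify a single trimmed sequence against the designed set."""
    policy = policy or AssignmentPolicy()
    if len(sequence) != bset.length:
        raise ValidationError(
            f"sequence length {len(sequence)} != barcode length {bset.length}"
        )
    seq_mat = encode_sequences([sequence.upper()])
    assigned, status = _classify_unique(
        seq_mat, bset.encoded(), policy, bset.min_distance
    )
    if status[0] == 0:
        bc = bset.barcodes[assigned[0]]
        dist = sum(a != b for a, b in zip(sequence.upper(), bc))
        return MatchResult("assigned", barcode=bc, distance=dist)
    return MatchResult("ambiguous" if status[0] == 1 else "unassigned")


def trim_flanks(seq: str, prefix: str = "", suffix: str = "") -> str | None:
    """Strip fixed vector flanks; returns None when a flank does not match."""
    if prefix:
        if not seq.startswith(prefix):
            return None
        seq = seq[len(prefix):]
    if suffix:
        if not seq.endswith(suffix):
            return None
        seq = seq[: len(seq) - len(suffix)]
    return seq


def count_umis(
    reads: pd.DataFrame,
    bset: BarcodeSet,
    policy: AssignmentPolicy | None = None,
    cell_whitelist=None,
) -> tuple[CellByFeatureMatrix, QCReport]:
    """UMI-deduplicated cell x barcode matrix from a read table.

    Features are the full designed barcode set (zero columns kept so that
    library-complexity detection fractions have the designed denominator).
    """
    policy = policy or AssignmentPolicy()
    qc = QCReport(n_reads=len(reads))
    for col in READ_COLUMNS:
        if col not in reads.columns:
            raise ValidationError(f"read table missing column {col!r}")
    if len(reads) == 0:
        warnings.warn("empty read table; returning empty matrix")
        return (
            CellByFeatureMatrix(
                cells=[], features=list(bset.barcodes),
                counts=sp.csr_matrix((0, len(bset)), dtype=np.int64),
            ),
            qc,
        )

    seqs = reads["sequence"].to_numpy()
    lengths = np.char.str_len(seqs.astype(str))
    good_len = lengths == bset.length
    qc.n_bad_length = int((~good_len).sum())
    reads_ok = reads.loc[good_len]

    uniq, inverse = np.unique(reads_ok["sequence"].to_numpy(), return_inverse=True)
    uniq_mat = encode_sequences(list(uniq))
    assigned_u, status_u = _classify_unique(
        uniq_mat, bset.encoded(), policy, bset.min_distance
    )
    status = status_u[inverse]
    assigned = assigned_u[inverse]
    qc.n_assigned = int((status == 0).sum())
    qc.n_ambiguous = int((status == 1).sum())
    qc.n_unassigned = int((status == 2).sum())

    keep = status == 0
    df = pd.DataFrame(
        {
            "cell": reads_ok["cell_barcode"].to_numpy()[keep],
            "umi": reads_ok["umi"].to_numpy()[keep],
            "feature": assigned[keep],
        }
    )
    if cell_whitelist is not None:
        allow = set(cell_whitelist)
        in_wl = df["cell"].isin(allow)
        qc.n_whitelist_rejected = int((~in_wl).sum())
        df = df.loc[in_wl]
        cells = list(cell_whitelist)
    else:
        cells = sorted(df["cell"].unique())

    df = df.drop_duplicates(subset=["cell", "umi", "feature"])
    qc.n_umis = len(df)
    qc.n_cells = len(cells)

    cell_index = {c: i for i, c in enumerate(cells)}
    rows = df["cell"].map(cell_index).to_numpy(dtype=np.int64)
    cols = df["feature"].to_numpy(dtype=np.int64)
    counts = sp.coo_matrix(
        (np.ones(len(df), dtype=np.int64), (rows, cols)),
        shape=(len(cells), len(bset)),
    ).tocsr()
    mat = CellByFeatureMatrix(cells=cells, features=list(bset.barcodes), counts=counts)
    return mat, qc


def aggregate_gre(
    matrix: CellByFeatureMatrix,
    gmap: GreBarcodeMap,
) -> CellByFeatureMatrix:
    """Sum each GRE's constituent barcode columns into one GRE column.

    Barcodes absent from the map are dropped with a warning; total counts
    are conserved up to those dropped columns (asserted)."""
    bc_to_gre = gmap.barcode_to_gre()
    unmapped = [f for f in matrix.features if f not in bc_to_gre]
    if unmapped:
        warnings.warn(f"{len(unmapped)} barcode column(s) not in GRE map; dropped")
    gres = gmap.gre_ids
    gre_index = {g: j for j, g in enumerate(gres)}
    feat_idx = [i for i, f in enumerate(matrix.features) if f in bc_to_gre]
    col_map = np.array(
        [gre_index[bc_to_gre[matrix.features[i]]] for i in feat_idx], dtype=np.int64
    )
    # indicator matrix (n_mapped_barcodes x n_gres)
    ind = sp.coo_matrix(
        (np.ones(len(feat_idx)), (np.arange(len(feat_idx)), col_map)),
        shape=(len(feat_idx), len(gres)),
    ).tocsr()
    sub = matrix.counts[:, feat_idx]
    agg = sp.csr_matrix(sub @ ind).astype(np.int64)
    out = CellByFeatureMatrix(cells=matrix.cells, features=gres, counts=agg)
    assert out.total == int(sub.sum()), "count conservation violated in aggregation"
    return out


@dataclass
class ComplexityReport:
    """Detection fractions and depth histogram of the designed library."""

    n_barcodes_designed: int
    n_barcodes_detected: int
    n_gres_designed: int
    n_gres_detected: int
    barcode_hist_edges: list[float] = field(default_factory=list)
    barcode_hist_counts: list[int] = field(default_factory=list)
    gre_hist_edges: list[float] = field(default_factory=list)
    gre_hist_counts: list[int] = field(default_factory=list)

    @property
    def frac_barcodes_detected(self) -> float:
        return self.n_barcodes_detected / self.n_barcodes_designed

    @property
    def frac_gres_detected(self) -> float:
        return self.n_gres_detected / self.n_gres_designed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frac_barcodes_detected"] = self.frac_barcodes_detected
        d["frac_gres_detected"] = self.frac_gres_detected
        return d


def library_complexity(
    matrix: CellByFeatureMatrix,
    bset: BarcodeSet,
    gmap: GreBarcodeMap,
    n_bins: int = 20,
) -> ComplexityReport:
    """Fraction of designed barcodes / GREs observed at least once, and
    log10 depth histograms of per-barcode and per-GRE totals."""
    totals = pd.Series(
        np.asarray(matrix.counts.sum(axis=0)).ravel(), index=matrix.features
    )
    bc_totals = totals.reindex(bset.barcodes, fill_value=0)
    gre_totals = pd.Series(0.0, index=gmap.gre_ids)
    bc_to_gre = gmap.barcode_to_gre()
    for bc, t in bc_totals.items():
        gre = bc_to_gre.get(bc)
        if gre is not None:
            gre_totals[gre] += t
    bc_hist, bc_edges = np.histogram(np.log10(bc_totals + 1), bins=n_bins)
    gre_hist, gre_edges = np.histogram(np.log10(gre_totals + 1), bins=n_bins)
    return ComplexityReport(
        n_barcodes_designed=len(bset),
        n_barcodes_detected=int((bc_totals > 0).sum()),
        n_gres_designed=len(gmap.gre_ids),
        n_gres_detected=int((gre_totals > 0).sum()),
        barcode_hist_edges=bc_edges.tolist(),
        barcode_hist_counts=bc_hist.tolist(),
        gre_hist_edges=gre_edges.tolist(),
        gre_hist_counts=gre_hist.tolist(),
    )


# ---------------------------------------------------------------------------
# read-table I/O


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in READ_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_barcode", "cell_type"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns cell_barcode, cell_type")
    return df


def write_labels_tsv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)
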