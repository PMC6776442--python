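"""Synthetic inputs for every pipeline stage.

Two generators are provided:

``simulate_peak_fixture``
    A toy ATAC peak table — intervals on a toy genome, a peaks x cell-type
    signal matrix in which designated peaks have elevated signal in one cell
    type, and per-peak conservation scores in which designated "conserved"
    peaks exceed the 95th percentile of a matched control distribution.
    Ground-truth flags are returned alongside.

``simulate_screen``
    A full synthetic enhancer screen with known ground truth. Each cell is
    assigned a type from the screen's composition (ten cortical types, one
    rare target population by default); with probability
    ``infection_fraction`` it carries viral transcripts whose total UMI
    count is negative-binomial; each UMI is allocated to one GRE-barcode
    with probability proportional to the GRE weight, multiplied by that
    GRE's ``true_fold`` when the cell is target-type; reads carry i.i.d.
    per-base substitution errors on the barcode. The generator returns the
    raw read table, per-cell labels, the GRE-barcode map, and the noiseless
    cell x barcode UMI counts as ground truth.

The defaults are the screen's study conditions: 287 GREs x 3 barcodes, ten
cell types with a ~5% target population, 15.6 viral UMIs per cell on
average with 86% of cells carrying at least one viral transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .barcodes import BarcodeSet, GreBarcodeMap, assign_barcodes, design_barcodes
from .errors import ValidationError
from .quant import CellByFeatureMatrix
from .selection import GenomicInterval, PeakTable

# Cell-type composition modeled on adult mouse visual cortex: excitatory
# neurons dominate; SST interneurons are the rare target population (~5%).
DEFAULT_PROPORTIONS = {
    "Exc": 0.50,
    "Olig": 0.12,
    "Astro": 0.10,
    "Pv": 0.06,
    "Vip": 0.05,
    "Sst": 0.05,
    "Micro": 0.04,
    "OPC": 0.04,
    "Vasc": 0.03,
    "Npy": 0.01,
}


@dataclass
class ScreenTruth:
    """Ground-truth parameters of a simulated screen.

    ``true_fold`` maps GRE ids to the ratio of expected viral expression in
    target vs non-target cells (unlisted GREs default to 1.0).
    ``mean_viral_umis_per_cell`` is the mean over *all* cells; infected
    cells draw totals with mean ``mean_viral_umis_per_cell /
    infection_fraction`` so the overall mean and the infected fraction are
    both honoured.
    """

    n_gres: int = 287
    barcodes_per_gre: int = 3
    cell_type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    target_celltype: str = "Sst"
    true_fold: dict[str, float] = field(default_factory=dict)
    mean_viral_umis_per_cell: float = 15.6
    infection_fraction: float = 0.86
    nb_dispersion: float = 0.25
    barcode_error_rate: float = 0.005
    barcode_length: int = 10
    umi_length: int = 8
    duplication_factor: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_gres < 1 or self.barcodes_per_gre < 1:
            raise ValidationError("n_gres and barcodes_per_gre must be positive")
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"cell type proportions sum to {total}, not 1")
        if self.target_celltype not in self.cell_type_proportions:
            raise ValidationError(
                f"target type {self.target_celltype!r} not among cell types"
            )
        if not (0.0 < self.infection_fraction <= 1.0):
            raise ValidationError("infection_fraction must be in (0, 1]")
        if any(f <= 0 for f in self.true_fold.values()):
            raise ValidationError("true_fold values must be positive")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not (0.0 <= self.barcode_error_rate < 0.25):
            raise ValidationError("barcode_error_rate must be in [0, 0.25)")
        if self.duplication_factor < 1:
            raise ValidationError("duplication_factor must be >= 1")

    def gre_ids(self) -> list[str]:
        return [f"GRE{i+1:03d}" for i in range(self.n_gres)]

    def fold_vector(self) -> np.ndarray:
        ids = self.gre_ids()
        unknown = set(self.true_fold) - set(ids)
        if unknown:
            raise ValidationError(f"true_fold refers to unknown GREs: {sorted(unknown)}")
        return np.array([self.true_fold.get(g, 1.0) for g in ids])


@dataclass
class SimulatedScreen:
    """Bundle returned by :func:`simulate_screen`."""

    reads: pd.DataFrame  # columns cell_barcode, umi, sequence
    labels: pd.DataFrame  # columns cell_barcode, cell_type
    barcode_set: BarcodeSet
    gre_map: GreBarcodeMap
    truth: ScreenTruth
    truth_counts: CellByFeatureMatrix  # noiseless cell x barcode UMI counts


def _int_to_seq(values: np.ndarray, length: int) -> np.ndarray:
    """Vectorized base-4 integer -> ACGT word conversion."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    digits = np.empty((len(values), length), dtype=np.uint8)
    v = values.astype(np.int64).copy()
    for pos in range(length - 1, -1, -1):
        digits[:, pos] = v % 4
        v //= 4
    return lut[digits]


def _bytes_to_strings(mat: np.ndarray) -> list[str]:
    width = mat.shape[1]
    return np.frombuffer(mat.tobytes(), dtype=f"S{width}").astype(str).tolist()


def simulate_screen(
    truth: ScreenTruth,
    n_cells: int,
    seed: int | None = None,
    barcode_set: BarcodeSet | None = None,
    gre_map: GreBarcodeMap | None = None,
) -> SimulatedScreen:
    """Generate a full synthetic screen; identical seeds give identical output.

    ``barcode_set`` / ``gre_map`` may be supplied to reuse one designed
    library across simulations (the physical library is fixed in a real
    screen); otherwise they are designed deterministically from the seed.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be positive")
    master = truth.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    seed_design, seed_cells = [s.generate_state(1)[0] for s in ss.spawn(2)]
    rng = np.random.default_rng(seed_cells)

    gre_ids = truth.gre_ids()
    n_slots = truth.n_gres * truth.barcodes_per_gre
    if barcode_set is None:
        barcode_set = design_barcodes(
            truth.barcode_length, 3, n_slots, seed=int(seed_design % 2**31)
        )
    if gre_map is None:
        gre_map = assign_barcodes(
            gre_ids, barcode_set, truth.barcodes_per_gre,
            seed=int(seed_design % 2**31),
        )

    # cell identities
    types = np.array(list(truth.cell_type_proportions))
    props = np.array(list(truth.cell_type_proportions.values()))
    type_idx = rng.choice(len(types), size=n_cells, p=props)
    cell_types = types[type_idx]
    is_target = cell_types == truth.target_celltype
    cell_ids = np.array([f"cell{i:06d}" for i in range(n_cells)])

    # viral UMI totals: Bernoulli(infection) x NB(mean/infection, dispersion)
    infected = rng.random(n_cells) < truth.infection_fraction
    mean_inf = truth.mean_viral_umis_per_cell / truth.infection_fraction
    r = 1.0 / truth.nb_dispersion
    p_nb = r / (r + mean_inf)
    totals = np.where(infected, rng.negative_binomial(r, p_nb, size=n_cells), 0)

    # per-slot allocation probabilities (slot = GRE x barcode, map order)
    fold = truth.fold_vector()
    slot_base = np.repeat(np.ones(truth.n_gres), truth.barcodes_per_gre)
    slot_fold = np.repeat(fold, truth.barcodes_per_gre)
    p_rest = slot_base / slot_base.sum()
    w_target = slot_base * slot_fold
    p_target = w_target / w_target.sum()

    # allocate UMIs to slots per cell
    cells_rows, slot_rows, count_rows = [], [], []
    for i in np.flatnonzero(totals):
        probs = p_target if is_target[i] else p_rest
        counts = rng.multinomial(totals[i], probs)
        nz = np.flatnonzero(counts)
        cells_rows.append(np.full(len(nz), i))
        slot_rows.append(nz)
        count_rows.append(counts[nz])
    if cells_rows:
        cell_of_entry = np.concatenate(cells_rows)
        slot_of_entry = np.concatenate(slot_rows)
        umis_of_entry = np.concatenate(count_rows)
    else:
        cell_of_entry = np.empty(0, dtype=int)
        slot_of_entry = np.empty(0, dtype=int)
        umis_of_entry = np.empty(0, dtype=int)

    # ground-truth cell x barcode matrix (all cells, designed barcode order)
    slot_barcodes = [
        seq for seqs in gre_map.slot_matrix() for seq in seqs
    ]
    feat_index = {seq: j for j, seq in enumerate(barcode_set.barcodes)}
    truth_mat = sp.coo_matrix(
        (
            umis_of_entry,
            (cell_of_entry, [feat_index[slot_barcodes[s]] for s in slot_of_entry]),
        ),
        shape=(n_cells, len(barcode_set)),
        dtype=np.int64,
    ).tocsr()
    truth_counts = CellByFeatureMatrix(
        cells=cell_ids.tolist(),
        features=list(barcode_set.barcodes),
        counts=truth_mat,
    )

    # expand to one row per UMI
    umi_cell = np.repeat(cell_of_entry, umis_of_entry)
    umi_slot = np.repeat(slot_of_entry, umis_of_entry)

    # distinct UMI words within each cell (redraw collisions)
    umi_space = 4**truth.umi_length
    if totals.max(initial=0) > umi_space:
        raise ValidationError("umi_length too short for per-cell molecule count")
    umi_val = rng.integers(0, umi_space, size=len(umi_cell))
    while True:
        order = np.lexsort((umi_val, umi_cell))
        dup = np.zeros(len(umi_cell), dtype=bool)
        same = (np.diff(umi_cell[order]) == 0) & (np.diff(umi_val[order]) == 0)
        dup[order[1:][same]] = True
        if not dup.any():
            break
        umi_val[dup] = rng.integers(0, umi_space, size=int(dup.sum()))

    # one or more reads per UMI, with substitution errors on the barcode
    dup_factor = truth.duplication_factor
    read_cell = np.repeat(umi_cell, dup_factor)
    read_slot = np.repeat(umi_slot, dup_factor)
    read_umi = np.repeat(umi_val, dup_factor)

    slot_codes = np.array(
        [feat_index[slot_barcodes[s]] for s in range(n_slots)], dtype=np.int64
    )
    bc_mat = barcode_set.encoded()  # (n_barcodes, L) values 0..3
    seq_mat = bc_mat[slot_codes[read_slot]].copy()
    if truth.barcode_error_rate > 0 and len(seq_mat):
        err = rng.random(seq_mat.shape) < truth.barcode_error_rate
        shift = rng.integers(1, 4, size=seq_mat.shape, dtype=np.uint8)
        seq_mat[err] = (seq_mat[err] + shift[err]) % 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_strings = _bytes_to_strings(lut[seq_mat]) if len(seq_mat) else []
    umi_strings = (
        _bytes_to_strings(_int_to_seq(read_umi, truth.umi_length))
        if len(read_umi)
        else []
    )

    reads = pd.DataFrame(
        {
            "cell_barcode": cell_ids[read_cell],
            "umi": umi_strings,
            "sequence": seq_strings,
        }
    )
    labels = pd.DataFrame({"cell_barcode": cell_ids, "cell_type": cell_types})
    return SimulatedScreen(
        reads=reads,
        labels=labels,
        barcode_set=barcode_set,
        gre_map=gre_map,
        truth=truth,
        truth_counts=truth_counts,
    )


# ---------------------------------------------------------------------------
# peak fixture


@dataclass
class PeakFixture:
    """Toy peak table with ground-truth flags and distal-control scores."""

    peaks: PeakTable
    flags: pd.DataFrame  # columns is_specific, is_conserved indexed by peak id
    control_scores: np.ndarray
    target_celltype: str


def simulate_peak_fixture(
    n_peaks: int,
    n_celltypes: int = 3,
    n_specific: int = 10,
    seed: int = 0,
    specificity_factor: float = 6.0,
    conserved_fraction: float = 0.4,
) -> PeakFixture:
    """Toy genome peak fixture for the GRE-selection stage.

    ``n_specific`` peaks get ``specificity_factor``-fold elevated signal in
    the first cell type (the target). Designated conserved peaks (all
    specific peaks, plus a ``conserved_fraction`` of the rest) are given
    conservation scores strictly above the 95th percentile of the returned
    control distribution; all other peaks are strictly below it, so the
    ground-truth flags are unambiguous by construction.
    """
    if n_peaks < 1 or n_celltypes < 2:
        raise ValidationError("need n_peaks >= 1 and n_celltypes >= 2")
    if n_specific > n_peaks:
        raise ValidationError("n_specific cannot exceed n_peaks")
    rng = np.random.default_rng(seed)

    celltypes = [f"ct{j}" for j in range(n_celltypes)]
    target = celltypes[0]

    starts = np.arange(n_peaks) * 1500 + rng.integers(0, 400, size=n_peaks)
    widths = rng.integers(200, 500, size=n_peaks)
    intervals = [
        GenomicInterval("chr1", int(s), int(s + w), id=f"peak{i:05d}")
        for i, (s, w) in enumerate(zip(starts, widths))
    ]
    ids = [iv.id for iv in intervals]

    # non-negative ATAC signal: gamma baseline, elevated target column for
    # the specific peaks
    signal = rng.gamma(shape=20.0, scale=5.0, size=(n_peaks, n_celltypes))
    specific_idx = rng.choice(n_peaks, size=n_specific, replace=False)
    signal[specific_idx, 0] *= specificity_factor

    # conservation: controls set the threshold; flagged peaks exceed it
    control_scores = rng.normal(0.0, 0.3, size=max(n_peaks, 100))
    cutoff = np.quantile(control_scores, 0.95)
    is_specific = np.zeros(n_peaks, dtype=bool)
    is_specific[specific_idx] = True
    is_conserved = is_specific.copy()
    others = np.flatnonzero(~is_specific)
    n_extra = int(round(conserved_fraction * len(others)))
    if n_extra:
        is_conserved[rng.choice(others, size=n_extra, replace=False)] = True
    conservation = np.where(
        is_conserved,
        cutoff + 0.05 + rng.gamma(2.0, 0.2, size=n_peaks),
        np.minimum(rng.normal(0.0, 0.3, size=n_peaks), cutoff - 0.01),
    )

    peaks = PeakTable(
        intervals=intervals,
        signal=pd.DataFrame(signal, index=ids, columns=celltypes),
        conservation=pd.Series(conservation, index=ids),
    )
    flags = pd.DataFrame(
        {"is_specific": is_specific, "is_conserved": is_conserved}, index=ids
    )
    return PeakFixture(
        peaks=peaks,
        flags=flags,
        control_scores=control_scores,
        target_celltype=target,
    )
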