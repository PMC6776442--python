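"""Design and validation of DNA barcode sets with a minimum edit-distance
guarantee, and assignment of barcodes to GREs.

Viral reporter barcodes are short fixed-length DNA words (default 10-mers)
separated by a minimum number of insertions, deletions, or substitutions
(default 3), so that a single sequencing error can never convert one barcode
into a read that is closer to a different barcode. Two metrics are offered:

``levenshtein``
    Standard unit-cost edit distance (computed with edlib).
``sequence_levenshtein``
    The barcode-design variant that also charges read-frame shifts at the
    sequence ends: the distance is the minimum over the final row and final
    column of the edit-distance DP table, i.e. the cheapest way to turn one
    word into a prefix-compatible read of the other.

Sets are built by a seeded greedy closure over the (shuffled) candidate
space: a candidate is kept iff it is at least ``min_dist`` away from every
barcode already kept. A SymSpell-style deletion-neighbourhood index prunes
the quadratic scan for the Levenshtein metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np

from .errors import CapacityError, ValidationError

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# byte -> 0..3 lookup used to vectorize sequence encoding
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i

METRICS = ("levenshtein", "sequence_levenshtein")
_METRIC_ALIASES = {"seqlev": "sequence_levenshtein", "lev": "levenshtein"}


def _canon_metric(metric: str) -> str:
    metric = _METRIC_ALIASES.get(metric, metric)
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    return metric


def check_sequence(seq: str) -> str:
    """Validate an ACGT string; returns it unchanged."""
    if not seq:
        raise ValidationError("empty barcode sequence")
    if any(c not in _BASE_INDEX for c in seq):
        raise ValidationError(f"non-ACGT character in sequence {seq!r}")
    return seq


def encode_sequences(seqs) -> np.ndarray:
    """Encode equal-length ACGT strings into a (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = _ENC[raw].reshape(len(seqs), L)
    if (mat == 255).any():
        raise ValidationError("non-ACGT character in sequence batch")
    return mat


def decode_matrix(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    lut = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return [bytes(row).decode("ascii") for row in lut[mat]]


def levenshtein(a: str, b: str) -> int:
    """Standard unit-cost edit distance."""
    return edlib.align(a, b, task="distance")["editDistance"]


def sequence_levenshtein(a: str, b: str) -> int:
    """Sequence-Levenshtein distance: min over the last row and last column
    of the edit-distance DP table (boundary frame shifts are free)."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    best = prev[lb]  # dp[0][lb]
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        best = min(best, cur[lb])
        prev = cur
    return min(best, min(prev))


def edit_distance(a: str, b: str, metric: str = "levenshtein") -> int:
    """Edit distance between two ACGT words under the chosen metric."""
    check_sequence(a)
    check_sequence(b)
    metric = _canon_metric(metric)
    if metric == "levenshtein":
        return levenshtein(a, b)
    return sequence_levenshtein(a, b)


def _bounded_lev(a: str, b: str, k: int) -> int:
    """Levenshtein distance if <= k, else -1 (edlib early-exit)."""
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


@dataclass
class BarcodeSet:
    """An ordered set of equal-length ACGT barcodes with a pairwise
    minimum-distance guarantee under ``metric``."""

    barcodes: list[str]
    min_distance: int = 3
    metric: str = "levenshtein"

    def __post_init__(self):
        self.metric = _canon_metric(self.metric)
        if not self.barcodes:
            raise ValidationError("empty barcode set")
        L = len(self.barcodes[0])
        for seq in self.barcodes:
            check_sequence(seq)
            if seq != seq.upper():
                raise ValidationError(f"barcode {seq!r} is not uppercase")
            if len(seq) != L:
                raise ValidationError("barcodes have unequal lengths")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes in set")

    @property
    def length(self) -> int:
        return len(self.barcodes[0])

    def __len__(self) -> int:
        return len(self.barcodes)

    def encoded(self) -> np.ndarray:
        return encode_sequences(self.barcodes)


@dataclass
class ValidationReport:
    """Result of the exhaustive pairwise distance check."""

    n_pairs_checked: int
    violations: list[tuple[int, int, str, str, int]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def validate_barcode_set(bset: BarcodeSet) -> ValidationReport:
    """Exhaustive O(n^2) verification that all pairwise distances are
    >= ``bset.min_distance``; lists every violating pair."""
    seqs = bset.barcodes
    k = bset.min_distance - 1
    violations = []
    n_pairs = 0
    use_lev = bset.metric == "levenshtein"
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            n_pairs += 1
            if use_lev:
                d = _bounded_lev(seqs[i], seqs[j], k)
                if d != -1:
                    violations.append((i, j, seqs[i], seqs[j], d))
            else:
                d = sequence_levenshtein(seqs[i], seqs[j])
                if d < bset.min_distance:
                    violations.append((i, j, seqs[i], seqs[j], d))
    return ValidationReport(n_pairs_checked=n_pairs, violations=violations)


def _deletion_keys(seq: str, depth: int):
    """All subsequences of ``seq`` obtained by deleting up to ``depth``
    characters. Two words at Levenshtein distance <= depth share a key."""
    n = len(seq)
    keys = {seq}
    for d in range(1, min(depth, n) + 1):
        for pos in itertools.combinations(range(n), d):
            keys.add("".join(c for i, c in enumerate(seq) if i not in pos))
    return keys


def _has_homopolymer(seq: str, run: int) -> bool:
    count, prev = 1, ""
    for c in seq:
        count = count + 1 if c == prev else 1
        if count >= run:
            return True
        prev = c
    return False


def design_barcodes(
    length: int = 10,
    min_dist: int = 3,
    n_required: int = 861,
    metric: str = "levenshtein",
    seed: int | None = 0,
    max_homopolymer: int | None = None,
    shuffle: bool = True,
) -> BarcodeSet:
    """Greedily build a barcode set with all pairwise distances >= min_dist.

    Candidates are enumerated in a seeded shuffle of lexicographic order
    (``shuffle=False`` keeps plain lexicographic order, which makes the
    greedy closure exactly reproducible against a brute-force oracle).

    Raises
    ------
    CapacityError
        If the candidate space is exhausted before ``n_required`` barcodes
        are found; ``.achieved`` carries the count obtained.
    """
    if length < 1 or min_dist < 1 or n_required < 1:
        raise ValidationError("length, min_dist and n_required must be positive")
    metric = _canon_metric(metric)
    if min_dist > length and n_required > 1:
        # two equal-length words are at most `length` substitutions apart
        raise CapacityError(
            f"min_dist {min_dist} exceeds the maximum achievable distance "
            f"{length} between {length}-mers",
            achieved=1,
        )
    if length > 12:
        raise ValidationError("exhaustive candidate enumeration limited to length <= 12")

    n_pool = 4**length
    order = np.arange(n_pool, dtype=np.int64)
    if shuffle:
        rng = np.random.default_rng(seed)
        rng.shuffle(order)

    powers = 4 ** np.arange(length - 1, -1, -1, dtype=np.int64)
    lut = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)

    accepted: list[str] = []
    accepted_mat = np.empty((0, length), dtype=np.uint8)
    depth = min_dist - 1
    delete_index: dict[str, list[int]] = {}
    use_index = metric == "levenshtein"

    for idx in order:
        digits = ((idx // powers) % 4).astype(np.uint8)
        seq = bytes(lut[digits]).decode("ascii")
        if max_homopolymer is not None and _has_homopolymer(seq, max_homopolymer + 1):
            continue
        if accepted:
            # Hamming prefilter: lev <= hamming, so hamming < min_dist is a
            # guaranteed violation
            ham = (accepted_mat != digits).sum(axis=1)
            if (ham < min_dist).any():
                continue
        if use_index:
            suspects = set()
            for key in _deletion_keys(seq, depth):
                suspects.update(delete_index.get(key, ()))
            ok = all(
                _bounded_lev(seq, accepted[s], depth) == -1 for s in suspects
            )
        else:
            ok = all(
                sequence_levenshtein(seq, other) >= min_dist for other in accepted
            )
        if not ok:
            continue
        if use_index:
            i = len(accepted)
            for key in _deletion_keys(seq, depth):
                delete_index.setdefault(key, []).append(i)
        accepted.append(seq)
        accepted_mat = np.vstack([accepted_mat, digits[None, :]])
        if len(accepted) >= n_required:
            break

    if len(accepted) < n_required:
        raise CapacityError(
            f"candidate space exhausted: found {len(accepted)} of "
            f"{n_required} barcodes (length={length}, min_dist={min_dist})",
            achieved=len(accepted),
        )
    return BarcodeSet(barcodes=accepted, min_distance=min_dist, metric=metric)


@dataclass
class GreBarcodeMap:
    """Mapping of each GRE to its (default 3) reporter barcodes."""

    entries: dict[str, list[str]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for gre, seqs in self.entries.items():
            for seq in seqs:
                check_sequence(seq)
                if seq in seen:
                    raise ValidationError(
                        f"barcode {seq} assigned to both {seen[seq]} and {gre}"
                    )
                seen[seq] = gre

    @property
    def barcodes_per_gre(self) -> int:
        return len(next(iter(self.entries.values())))

    @property
    def gre_ids(self) -> list[str]:
        return list(self.entries)

    def barcode_to_gre(self) -> dict[str, str]:
        return {seq: gre for gre, seqs in self.entries.items() for seq in seqs}

    def slot_matrix(self) -> list[list[str]]:
        """Barcodes arranged as [gre][slot]."""
        return [list(seqs) for seqs in self.entries.values()]

    def n_pairs(self) -> int:
        return sum(len(v) for v in self.entries.values())


def assign_barcodes(
    gre_ids,
    bset: BarcodeSet,
    per_gre: int = 3,
    seed: int | None = 0,
) -> GreBarcodeMap:
    """Seeded random assignment (without replacement) of ``per_gre`` barcodes
    from ``bset`` to each GRE in ``gre_ids``."""
    gre_ids = list(gre_ids)
    if len(set(gre_ids)) != len(gre_ids):
        raise ValidationError("duplicate GRE ids")
    needed = len(gre_ids) * per_gre
    if needed > len(bset):
        raise CapacityError(
            f"need {needed} barcodes for {len(gre_ids)} GREs x {per_gre}, "
            f"set has {len(bset)}",
            achieved=len(bset),
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(bset))[:needed]
    chosen = [bset.barcodes[i] for i in perm]
    entries = {
        gre: chosen[i * per_gre : (i + 1) * per_gre]
        for i, gre in enumerate(gre_ids)
    }
    return GreBarcodeMap(entries=entries)


# ---------------------------------------------------------------------------
# plain-text I/O

def write_barcodes_tsv(bset: BarcodeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode_id\tsequence\n")
        for i, seq in enumerate(bset.barcodes):
            fh.write(f"bc{i:04d}\t{seq}\n")


def read_barcodes_tsv(path, min_distance: int = 3, metric: str = "levenshtein") -> BarcodeSet:
    seqs = []
    with open(path) as fh:
        header = fh.readline()
        if "sequence" not in header:
            raise ValidationError(f"{path}: expected a 'sequence' column")
        col = header.rstrip("\n").split("\t").index("sequence")
        for line in fh:
            if line.strip():
                seqs.append(line.rstrip("\n").split("\t")[col])
    return BarcodeSet(barcodes=seqs, min_distance=min_distance, metric=metric)


def write_barcodes_fasta(bset: BarcodeSet, path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(bset.barcodes):
            fh.write(f">bc{i:04d}\n{seq}\n")


def write_gre_map_tsv(gmap: GreBarcodeMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gre_id\tbarcode_seq\n")
        for gre, seqs in gmap.entries.items():
            for seq in seqs:
                fh.write(f"{gre}\t{seq}\n")


def read_gre_map_tsv(path) -> GreBarcodeMap:
    entries: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gre_id", "barcode_seq"]:
            raise ValidationError(f"{path}: expected columns gre_id, barcode_seq")
        for line in fh:
            if not line.strip():
                continue
            gre, seq = line.rstrip("\n").split("\t")[:2]
            entries.setdefault(gre, []).append(seq)
    return GreBarcodeMap(entries=entries)
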