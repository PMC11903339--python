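"""Barcode library design and decoding for in situ sequencing.

Guide barcodes are read base-by-base over 12 sequencing cycles, so a
usable library must (a) be fully deconvolvable from a short prefix — all
barcodes pairwise distinct within their first 11 bases — and (b) keep a
pairwise Levenshtein distance of at least 2 between 12-base prefixes so
that any single read error is detected (the corrupted read matches no
library prefix) rather than silently miscalled. A balanced per-position
base composition keeps the four sequencing channels informative in every
cycle.

The designer greedily selects from a candidate pool in seeded-shuffled
order; the verifier recomputes all guarantees exhaustively; the decoder
is detect-only (distance 2 cannot guarantee correction).

Note: for equal-length strings a Levenshtein distance <= 1 is possible
only via identity or a single substitution, so it coincides with a
Hamming distance <= 1; the designer exploits this for a vectorized
distance-2 screen while the verifier reports true edit distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DNA_ALPHABET = "ACGT"

_BASE_CODE = {b: i for i, b in enumerate(DNA_ALPHABET)}


def levenshtein(a: str, b: str) -> int:
    """Standard edit distance (substitution/insertion/deletion, unit
    cost) between two strings."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _encode(barcodes: list[str], length: int) -> np.ndarray:
    arr = np.empty((len(barcodes), length), dtype=np.uint8)
    for i, bc in enumerate(barcodes):
        for j in range(length):
            arr[i, j] = _BASE_CODE[bc[j]]
    return arr


def pairwise_levenshtein_min(prefixes: np.ndarray) -> int:
    """Exact minimum pairwise Levenshtein distance over an (n, L) array
    of encoded equal-length strings, via a numpy-vectorized DP over all
    pairs simultaneously."""
    n, L = prefixes.shape
    if n < 2:
        raise ValueError("need at least 2 barcodes")
    ii, jj = np.triu_indices(n, k=1)
    A = prefixes[ii]  # (P, L)
    B = prefixes[jj]
    P = A.shape[0]
    prev = np.broadcast_to(np.arange(L + 1), (P, L + 1)).astype(np.int32).copy()
    for i in range(1, L + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        sub = (A[:, i - 1][:, None] != B).astype(np.int32)  # (P, L): cost at (i, j)
        for j in range(1, L + 1):
            cur[:, j] = np.minimum(
                np.minimum(prev[:, j] + 1, cur[:, j - 1] + 1),
                prev[:, j - 1] + sub[:, j - 1],
            )
        prev = cur
    return int(prev[:, L].min())


@dataclass
class BarcodeEntry:
    barcode: str
    gene: str
    targeting: bool = True


@dataclass
class BarcodeLibrary:
    """A selected barcode set with its prefix guarantees.

    Invariants: all barcodes share one length >= ``prefix_len_detect``;
    pairwise Levenshtein distance over the first ``prefix_len_detect``
    bases >= 2; first ``prefix_len_unique`` bases pairwise distinct.
    """

    entries: list[BarcodeEntry]
    prefix_len_detect: int = 12
    prefix_len_unique: int = 11

    @property
    def barcodes(self) -> list[str]:
        return [e.barcode for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LibraryReport:
    """Exhaustively verified library guarantees."""

    min_pairwise_levenshtein_12: int | None
    min_unique_prefix_len: int | None
    per_position_base_fractions: np.ndarray  # 4 x L, columns sum to 1


@dataclass
class CallResult:
    """Outcome of decoding one read against a library."""

    read: str
    assigned_barcode: str | None
    status: str  # "exact" or "rejected"


class LibraryDesignError(RuntimeError):
    """Candidate pool exhausted before the requested size was reached."""

    def __init__(self, requested: int, library: "BarcodeLibrary"):
        self.requested = requested
        self.library = library
        super().__init__(
            f"pool exhausted: selected {len(library)} of {requested} requested barcodes"
        )


def _validate_pool(pool: list[str], min_len: int) -> int:
    if not pool:
        raise ValueError("empty candidate pool")
    length = len(pool[0])
    if any(len(b) != length for b in pool):
        raise ValueError("candidate barcodes must have uniform length")
    if length < min_len:
        raise ValueError(f"barcodes must be at least {min_len} bases long")
    bad = next((b for b in pool if any(c not in _BASE_CODE for c in b)), None)
    if bad is not None:
        raise ValueError(f"barcode {bad!r} contains non-ACGT characters")
    return length


def design_library(
    pool: list[str],
    n_select: int,
    prefix_len_detect: int = 12,
    prefix_len_unique: int = 11,
    composition_band: tuple[float, float] = (0.15, 0.40),
    min_count_for_band: int = 20,
    seed: int | None = None,
    genes: list[str] | None = None,
) -> BarcodeLibrary:
    """Greedy first-fit selection of ``n_select`` barcodes satisfying the
    deconvolution and error-detection constraints.

    Candidates are visited in seeded-shuffled pool order; one is accepted
    if its ``prefix_len_detect``-base prefix keeps Levenshtein distance
    >= 2 to every accepted barcode, its ``prefix_len_unique``-base prefix
    is unseen, and (once at least ``min_count_for_band`` barcodes are
    accepted) no base's per-position frequency would leave
    ``composition_band`` — a soft balance constraint; candidates that
    would violate it are skipped.

    Raises :class:`LibraryDesignError` (carrying the partial library) if
    the pool is exhausted first.
    """
    length = _validate_pool(pool, prefix_len_detect)
    if n_select > len(pool):
        raise ValueError("n_select exceeds pool size")
    if genes is not None and len(genes) != len(pool):
        raise ValueError("genes must align with pool")
    order = np.arange(len(pool))
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    band_lo, band_hi = composition_band

    accepted: list[int] = []
    acc_prefix = np.empty((n_select, prefix_len_detect), dtype=np.uint8)
    seen_unique: set[str] = set()
    base_counts = np.zeros((4, length), dtype=np.int64)
    pos_idx = np.arange(length)
    for cand in order:
        bc = pool[cand]
        enc = np.frombuffer(bc.encode(), dtype=np.uint8)
        enc = np.select(
            [enc == ord("A"), enc == ord("C"), enc == ord("G"), enc == ord("T")],
            [0, 1, 2, 3],
        ).astype(np.uint8)
        n_acc = len(accepted)
        if n_acc:
            # equal-length prefixes: Levenshtein >= 2 <=> Hamming >= 2
            mism = (acc_prefix[:n_acc] != enc[:prefix_len_detect]).sum(axis=1)
            if mism.min() < 2:
                continue
        if bc[:prefix_len_unique] in seen_unique:
            continue
        if n_acc >= min_count_for_band:
            # self-balancing: refuse to add to a base already at the band
            # ceiling anywhere along the barcode
            cand_frac = base_counts[enc, pos_idx] / n_acc
            if cand_frac.max() >= band_hi:
                continue
        acc_prefix[n_acc] = enc[:prefix_len_detect]
        seen_unique.add(bc[:prefix_len_unique])
        base_counts[enc, pos_idx] += 1
        accepted.append(int(cand))
        if len(accepted) == n_select:
            break
    entries = [
        BarcodeEntry(
            pool[i],
            genes[i] if genes is not None else f"G{k + 1:05d}",
            True,
        )
        for k, i in enumerate(accepted)
    ]
    lib = BarcodeLibrary(entries, prefix_len_detect, prefix_len_unique)
    if len(accepted) < n_select:
        raise LibraryDesignError(n_select, lib)
    return lib


def verify_library(lib: BarcodeLibrary) -> LibraryReport:
    """Exhaustively recompute the library's guarantees.

    Reports the minimum pairwise Levenshtein distance over
    ``prefix_len_detect``-base prefixes, the smallest prefix length at
    which all barcodes are pairwise distinct (vacuously 1 for a single
    barcode; None if full barcodes collide), and the per-position base
    composition over the full length.
    """
    if not lib.entries:
        raise ValueError("empty library")
    barcodes = lib.barcodes
    length = len(barcodes[0])
    if any(len(b) != length for b in barcodes):
        raise ValueError("mixed barcode lengths")
    enc = _encode(barcodes, length)
    if len(barcodes) >= 2:
        min_lev = pairwise_levenshtein_min(enc[:, : lib.prefix_len_detect])
    else:
        min_lev = None
    min_unique: int | None = None
    for k in range(1, length + 1):
        if len({b[:k] for b in barcodes}) == len(barcodes):
            min_unique = k
            break
    fractions = np.stack(
        [(enc == c).mean(axis=0) for c in range(4)], axis=0
    )  # 4 x L
    return LibraryReport(min_lev, min_unique, fractions)


def decode_read(read: str, lib: BarcodeLibrary) -> CallResult:
    """Decode a single read by exact prefix match (error detection only:
    any read whose prefix matches no library prefix is rejected; no
    nearest-neighbour rescue)."""
    return decode_reads([read], lib)[0]


def decode_reads(reads: list[str], lib: BarcodeLibrary) -> list[CallResult]:
    """Decode many reads against one library (prefix lookup built once)."""
    k = lib.prefix_len_detect
    lookup = {e.barcode[:k]: e.barcode for e in lib.entries}
    results = []
    for read in reads:
        if len(read) < k:
            raise ValueError(f"read shorter than {k} bases: {read!r}")
        hit = lookup.get(read[:k])
        if hit is None:
            results.append(CallResult(read, None, "rejected"))
        else:
            results.append(CallResult(read, hit, "exact"))
    return results


def random_pool(n: int, length: int = 20, seed: int = 0) -> list[str]:
    """Uniform random candidate barcodes."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, length))
    bases = np.array(list(DNA_ALPHABET))
    return ["".join(bases[row]) for row in codes]
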