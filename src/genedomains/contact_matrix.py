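"""Fragment-resolution Hi-C contact maps.

The coordinate system of every matrix in this package is a
:class:`FragmentMap`: the ordered restriction fragments of one chromosome,
0-based half-open, adjacent and non-overlapping.  Contacts are stored
sparsely as upper-triangle ``(i, j) -> value`` entries (``i <= j``);
symmetry is implied, never stored twice.

Provides KR (symmetric iterative proportional scaling) and VC_SQRT
balancing, the per-separation distance-decay expectation, the
observed/expected transform, and a plain-text triplet reader/writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentMap",
    "ContactMatrix",
    "DecayProfile",
    "OEMatrix",
    "BalancingError",
    "build_fragment_map",
    "kr_balance",
    "vc_sqrt_balance",
    "bin_fragments",
    "decay_profile",
    "observed_over_expected",
    "read_triplets",
    "write_triplets",
    "read_fragment_map_bed",
    "write_fragment_map_bed",
    "read_balancing_tsv",
    "write_balancing_tsv",
]


class BalancingError(RuntimeError):
    """Raised when matrix balancing fails to converge."""


@dataclass(frozen=True)
class FragmentMap:
    """Ordered restriction fragments tiling one chromosome.

    Parameters
    ----------
    chromosome:
        Chromosome identifier.
    starts, ends:
        Fragment boundaries, 0-based half-open.  ``ends[k] == starts[k+1]``
        and together the fragments cover ``[0, length)``.
    """

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.shape != ends.shape or starts.ndim != 1 or starts.size == 0:
            raise ValueError("starts/ends must be equal-length non-empty 1-D arrays")
        if np.any(ends <= starts):
            raise ValueError("every fragment must have positive length")
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
            raise ValueError("fragments must tile the chromosome without gaps")

    @property
    def n_fragments(self) -> int:
        return int(self.starts.size)

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def locate(self, position) -> np.ndarray | int:
        """Fragment index containing each genomic position (bp)."""
        pos = np.asarray(position)
        if np.any(pos < 0) or np.any(pos >= self.length):
            raise ValueError(f"position out of chromosome bounds [0, {self.length})")
        idx = np.searchsorted(self.ends, pos, side="right")
        return idx if pos.ndim else int(idx)

    def start_to_index(self, position) -> np.ndarray | int:
        """Fragment index whose start coordinate is exactly `position`."""
        pos = np.asarray(position, dtype=np.int64)
        idx = np.searchsorted(self.starts, pos)
        bad = (idx >= self.n_fragments) | (self.starts[np.minimum(idx, self.n_fragments - 1)] != pos)
        if np.any(bad):
            first = np.atleast_1d(pos)[np.atleast_1d(bad)][0]
            raise ValueError(f"{first} is not a fragment start on {self.chromosome}")
        return idx if pos.ndim else int(idx)


def build_fragment_map(chromosome_length: int, cut_sites, chromosome: str = "chr1") -> FragmentMap:
    """Digest a chromosome of `chromosome_length` bp at `cut_sites`.

    Cut sites must be strictly increasing and strictly inside
    ``(0, chromosome_length)``; the result has ``len(cut_sites) + 1``
    fragments tiling ``[0, chromosome_length)``.
    """
    cuts = np.asarray(cut_sites, dtype=np.int64).reshape(-1)
    if chromosome_length <= 0:
        raise ValueError("chromosome_length must be positive")
    if cuts.size:
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("cut sites must be strictly increasing")
        if cuts[0] <= 0 or cuts[-1] >= chromosome_length:
            raise ValueError("cut sites must lie strictly inside the chromosome")
    bounds = np.concatenate([[0], cuts, [chromosome_length]])
    return FragmentMap(chromosome, bounds[:-1], bounds[1:])


@dataclass
class ContactMatrix:
    """Sparse symmetric fragment-by-fragment contact counts.

    Only the upper triangle is stored (``row <= col``).  ``balancing`` is
    the optional per-fragment weight vector (NaN for masked fragments)
    produced by :func:`kr_balance` / :func:`vc_sqrt_balance`.
    """

    fragment_map: FragmentMap
    row: np.ndarray
    col: np.ndarray
    value: np.ndarray
    balancing: np.ndarray | None = None
    resolution_factor: int = 1

    def __post_init__(self) -> None:
        self.row = np.asarray(self.row, dtype=np.int64)
        self.col = np.asarray(self.col, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=np.float64)
        if not (self.row.shape == self.col.shape == self.value.shape):
            raise ValueError("row/col/value must have identical shapes")
        if np.any(self.row > self.col):
            raise ValueError("entries must satisfy row <= col")
        n = self.fragment_map.n_fragments
        if self.row.size and (self.row.min() < 0 or self.col.max() >= n):
            raise ValueError("fragment index out of range")
        if not np.all(np.isfinite(self.value)) or np.any(self.value < 0):
            raise ValueError("counts must be finite and >= 0")

    @classmethod
    def from_entries(cls, fragment_map: FragmentMap, entries: dict, **kw) -> "ContactMatrix":
        if not entries:
            z = np.empty(0, dtype=np.int64)
            return cls(fragment_map, z, z.copy(), np.empty(0), **kw)
        ij = np.array(sorted(entries), dtype=np.int64)
        vals = np.array([entries[tuple(p)] for p in ij], dtype=np.float64)
        return cls(fragment_map, ij[:, 0], ij[:, 1], vals, **kw)

    @classmethod
    def from_dense(cls, fragment_map: FragmentMap, dense: np.ndarray, **kw) -> "ContactMatrix":
        dense = np.asarray(dense, dtype=np.float64)
        if dense.shape != (fragment_map.n_fragments,) * 2:
            raise ValueError("dense shape does not match fragment map")
        if not np.allclose(dense, dense.T):
            raise ValueError("dense matrix must be symmetric")
        r, c = np.nonzero(np.triu(dense))
        return cls(fragment_map, r, c, dense[r, c], **kw)

    @property
    def n_fragments(self) -> int:
        return self.fragment_map.n_fragments

    def to_dense(self) -> np.ndarray:
        n = self.n_fragments
        out = np.zeros((n, n))
        out[self.row, self.col] = self.value
        out[self.col, self.row] = self.value
        return out

    def get(self, i: int, j: int) -> float:
        i, j = (i, j) if i <= j else (j, i)
        hit = (self.row == i) & (self.col == j)
        return float(self.value[hit][0]) if hit.any() else 0.0

    def entries(self) -> dict:
        return {(int(i), int(j)): float(v) for i, j, v in zip(self.row, self.col, self.value)}

    def row_sums(self) -> np.ndarray:
        """Symmetric row sums (diagonal counted once)."""
        n = self.n_fragments
        s = np.bincount(self.row, weights=self.value, minlength=n)
        off = self.row != self.col
        s += np.bincount(self.col[off], weights=self.value[off], minlength=n)
        return s


@dataclass(frozen=True)
class DecayProfile:
    """Mean contact per fragment separation d = 0, 1, ... over ALL pairs.

    ``n_pairs[d]`` is the number of fragment pairs at separation d on the
    chromosome (zeros included in the mean).
    """

    mean: np.ndarray
    n_pairs: np.ndarray

    def expected(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=np.int64)
        out = np.zeros(d.shape)
        ok = d < self.mean.size
        out[ok] = self.mean[d[ok]]
        return out


@dataclass
class OEMatrix:
    """Distance-normalized (observed / expected) sparse contact map."""

    fragment_map: FragmentMap
    row: np.ndarray
    col: np.ndarray
    value: np.ndarray

    @property
    def n_fragments(self) -> int:
        return self.fragment_map.n_fragments

    def to_dense(self) -> np.ndarray:
        n = self.n_fragments
        out = np.zeros((n, n))
        out[self.row, self.col] = self.value
        out[self.col, self.row] = self.value
        return out


def _balanced_values(matrix: ContactMatrix, weights: np.ndarray) -> ContactMatrix:
    keep = np.isfinite(weights[matrix.row]) & np.isfinite(weights[matrix.col])
    r, c = matrix.row[keep], matrix.col[keep]
    v = matrix.value[keep] * weights[r] * weights[c]
    return ContactMatrix(matrix.fragment_map, r, c, v, balancing=weights,
                         resolution_factor=matrix.resolution_factor)


def kr_balance(matrix: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000) -> ContactMatrix:
    """KR-style balancing by symmetric iterative proportional scaling.

    Finds a positive vector x with ``B(i,j) = x_i * A(i,j) * x_j`` whose
    row sums agree to within `tol` (relative spread) over unmasked rows.
    Fragments with no off-mask contacts are masked (weight NaN).
    """
    n = matrix.n_fragments
    if matrix.value.size == 0:
        raise BalancingError("cannot balance an empty matrix")
    mask = matrix.row_sums() > 0
    if mask.sum() < 1:
        raise BalancingError("no rows with contacts to balance")
    # work on the masked dense submatrix; fragment-resolution chromosomes
    # are small enough for this (n ~ 1e4)
    idx = np.flatnonzero(mask)
    sub = matrix.to_dense()[np.ix_(idx, idx)]
    # rows that only touch masked rows can become all-zero; drop iteratively
    while True:
        rs = sub.sum(axis=1)
        dead = rs == 0
        if not dead.any():
            break
        idx = idx[~dead]
        sub = sub[np.ix_(~dead, ~dead)]
        if idx.size == 0:
            raise BalancingError("no balanceable rows remain")
    x = np.ones(idx.size)
    spread = np.inf
    for _ in range(max_iter):
        rs = (sub * x).sum(axis=1) * x
        mean = rs.mean()
        spread = np.abs(rs - mean).max() / mean
        if spread < tol:
            break
        x /= np.sqrt(rs)
    else:
        raise BalancingError(
            f"KR balancing did not converge in {max_iter} iterations "
            f"(relative row-sum spread {spread:.3e} > tol {tol:.1e})")
    weights = np.full(n, np.nan)
    weights[idx] = x
    return _balanced_values(matrix, weights)


def vc_sqrt_balance(matrix: ContactMatrix) -> ContactMatrix:
    """Square-root vanilla-coverage balancing.

    ``B(i,j) = A(i,j) / sqrt(rowsum_i * rowsum_j)``; rows with zero sum
    are masked and logged.
    """
    rs = matrix.row_sums()
    zero = rs == 0
    if zero.any():
        logger.info("vc_sqrt_balance: masking %d empty rows", int(zero.sum()))
    weights = np.full(matrix.n_fragments, np.nan)
    weights[~zero] = 1.0 / np.sqrt(rs[~zero])
    return _balanced_values(matrix, weights)


def bin_fragments(matrix: ContactMatrix, n_per_bin: int) -> ContactMatrix:
    """Aggregate counts over `n_per_bin` consecutive fragments.

    Used for two-fragment-resolution maps and for compartment binning.
    The binned map lives on a coarser FragmentMap whose bins concatenate
    consecutive fragments (last bin may be short).
    """
    if n_per_bin < 1:
        raise ValueError("n_per_bin must be >= 1")
    if n_per_bin == 1:
        return matrix
    fm = matrix.fragment_map
    bounds = np.concatenate([fm.starts[::n_per_bin], [fm.length]])
    binned_map = FragmentMap(fm.chromosome, bounds[:-1], bounds[1:])
    br, bc = matrix.row // n_per_bin, matrix.col // n_per_bin
    agg: dict = {}
    for i, j, v in zip(br, bc, matrix.value):
        key = (int(i), int(j))
        agg[key] = agg.get(key, 0.0) + float(v)
    out = ContactMatrix.from_entries(binned_map, agg)
    out.resolution_factor = matrix.resolution_factor * n_per_bin
    return out


def decay_profile(matrix: ContactMatrix) -> DecayProfile:
    """Per-separation mean contact over ALL fragment pairs (zeros included)."""
    if matrix.value.size == 0:
        raise ValueError("cannot build a decay profile from an empty matrix")
    n = matrix.n_fragments
    sep = matrix.col - matrix.row
    sums = np.bincount(sep, weights=matrix.value, minlength=n)
    n_pairs = n - np.arange(n)
    return DecayProfile(mean=sums / n_pairs, n_pairs=n_pairs)


def observed_over_expected(matrix: ContactMatrix, profile: DecayProfile | None = None) -> OEMatrix:
    """Divide each entry by the mean contact at its separation.

    Separations with zero expected mean yield no OE entry (dropped and
    logged).  `profile` defaults to the matrix's own decay profile.
    """
    if profile is None:
        profile = decay_profile(matrix)
    if profile.mean.size != matrix.n_fragments:
        raise ValueError("decay profile does not match the fragment map")
    sep = matrix.col - matrix.row
    exp = profile.mean[sep]
    ok = exp > 0
    if (~ok).any():
        logger.info("observed_over_expected: dropped %d entries at zero-mean separations",
                    int((~ok).sum()))
    return OEMatrix(matrix.fragment_map, matrix.row[ok], matrix.col[ok],
                    matrix.value[ok] / exp[ok])


# ---------------------------------------------------------------------------
# plain-text I/O

def write_triplets(matrix: ContactMatrix, path) -> None:
    """Write `pos1 pos2 value` lines (fragment start coordinates, tab-separated)."""
    fm = matrix.fragment_map
    df = pd.DataFrame({
        "pos1": fm.starts[matrix.row],
        "pos2": fm.starts[matrix.col],
        "value": matrix.value,
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_triplets(path, fragment_map: FragmentMap) -> ContactMatrix:
    """Read a triplet file onto `fragment_map`.

    Positions must be fragment start coordinates; a mismatch raises with
    the offending line number.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["pos1", "pos2", "value"])
    except pd.errors.EmptyDataError:
        z = np.empty(0, dtype=np.int64)
        return ContactMatrix(fragment_map, z, z.copy(), np.empty(0))
    rows = np.empty(len(df), dtype=np.int64)
    cols = np.empty(len(df), dtype=np.int64)
    for k, (p1, p2) in enumerate(zip(df["pos1"], df["pos2"])):
        try:
            i = fragment_map.start_to_index(int(p1))
            j = fragment_map.start_to_index(int(p2))
        except ValueError as exc:
            raise ValueError(f"{path}: line {k + 1}: {exc}") from None
        rows[k], cols[k] = min(i, j), max(i, j)
    order = np.lexsort((cols, rows))
    return ContactMatrix(fragment_map, rows[order], cols[order],
                         df["value"].to_numpy(dtype=np.float64)[order])


def write_fragment_map_bed(fragment_map: FragmentMap, path) -> None:
    pd.DataFrame({
        "chrom": fragment_map.chromosome,
        "start": fragment_map.starts,
        "end": fragment_map.ends,
    }).to_csv(path, sep="\t", header=False, index=False)


def read_fragment_map_bed(path) -> FragmentMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("fragment map BED must contain exactly one chromosome")
    return FragmentMap(str(chroms[0]), df["start"].to_numpy(), df["end"].to_numpy())


def write_balancing_tsv(matrix: ContactMatrix, path) -> None:
    if matrix.balancing is None:
        raise ValueError("matrix has no balancing vector")
    pd.DataFrame({
        "fragment_index": np.arange(matrix.n_fragments),
        "weight": matrix.balancing,
    }).to_csv(path, sep="\t", index=False)


def read_balancing_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["weight"].to_numpy(dtype=np.float64)
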