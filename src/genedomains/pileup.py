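"""Gene-centric aggregate Hi-C images ("pile-ups").

For each gene, a square OE window covering [start - pad, end + pad) is
sampled on a bp-proportional pixel grid, resized to a fixed 80x80 raster
by bicubic interpolation, flipped 180 degrees for (-) strand genes, and
averaged over the cohort.

The 80x80 raster (padding factor 0.5) is partitioned into six
upper-triangle blocks from the gene borders: S-A (up x up), S-B
(up x gene), S-C (up x down), G (gene x gene), S-D (gene x down),
S-E (down x down).  The domain score is mean-OE-per-pixel of G over
mean-OE-per-pixel of S-C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contact_matrix import OEMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PileupImage",
    "SubregionSums",
    "DomainScore",
    "SUBREGIONS",
    "extract_window",
    "resize_bicubic",
    "gene_raster",
    "pileup",
    "subregion_masks",
    "subregion_sums",
    "domain_score",
    "group_by_value",
    "correlate_subregions",
    "diff_pileup",
    "write_pileup_tsv",
    "read_pileup_tsv",
]

SUBREGIONS = ("S-A", "S-B", "S-C", "G", "S-D", "S-E")


@dataclass
class PileupImage:
    """Averaged OE raster for a gene cohort."""

    raster: np.ndarray
    n_genes: int
    padding_factor: float

    @property
    def size(self) -> int:
        return self.raster.shape[0]


@dataclass(frozen=True)
class SubregionSums:
    """Per-block OE totals and mean-per-pixel values over the upper triangle."""

    sums: dict
    means: dict
    n_pixels: dict


@dataclass(frozen=True)
class DomainScore:
    """G-block mean over S-C-block mean; `value` is None when S-C mean is 0."""

    value: float | None

    @property
    def defined(self) -> bool:
        return self.value is not None


def _keys_weights(n_in: int, n_out: int, a: float = -0.5) -> np.ndarray:
    """Cubic-convolution (Keys) interpolation weight matrix, edge-clamped.

    Rows sum to 1 exactly, so constants are preserved; at n_in == n_out
    the matrix is the identity.
    """

    def kernel(s: np.ndarray) -> np.ndarray:
        s = np.abs(s)
        w = np.zeros_like(s)
        near = s <= 1
        w[near] = (a + 2) * s[near] ** 3 - (a + 3) * s[near] ** 2 + 1
        far = (s > 1) & (s < 2)
        w[far] = a * (s[far] ** 3 - 5 * s[far] ** 2 + 8 * s[far] - 4)
        return w

    x = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    base = np.floor(x).astype(int)
    W = np.zeros((n_out, n_in))
    for m in range(-1, 3):
        idx = np.clip(base + m, 0, n_in - 1)
        W[np.arange(n_out), idx] += kernel(x - (base + m))
    return W


def resize_bicubic(matrix: np.ndarray, out_size: int = 80) -> np.ndarray:
    """Resize a square matrix by separable bicubic (Keys, a = -0.5) interpolation."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input must be a square matrix")
    if matrix.shape[0] < 2:
        raise ValueError("input must be at least 2x2")
    W = _keys_weights(matrix.shape[0], out_size)
    return W @ matrix @ W.T


def extract_window(oe: OEMatrix, start: int, end: int,
                   n_samples: int = 160,
                   dense: np.ndarray | None = None,
                   coverage: np.ndarray | None = None):
    """Sample the OE map over window [start, end) on a bp-proportional grid.

    Returns (matrix, covered_fraction): `matrix` is n_samples x n_samples
    with missing OE entries as 0; `covered_fraction` is the fraction of
    pixels backed by a populated OE entry.  Windows outside the
    chromosome raise ValueError (callers skip those genes).
    """
    fm = oe.fragment_map
    if start < 0 or end > fm.length or end - start < 2:
        raise ValueError(f"window [{start}, {end}) outside chromosome [0, {fm.length})")
    if dense is None:
        dense = oe.to_dense()
    if coverage is None:
        coverage = np.zeros(dense.shape, dtype=bool)
        coverage[oe.row, oe.col] = True
        coverage[oe.col, oe.row] = True
    pos = start + (np.arange(n_samples) + 0.5) * (end - start) / n_samples
    frag = fm.locate(np.floor(pos).astype(np.int64))
    sub = dense[np.ix_(frag, frag)]
    cov = coverage[np.ix_(frag, frag)]
    return sub, float(cov.mean())


def gene_raster(oe: OEMatrix, gene, padding_factor: float = 0.5,
                out_size: int = 80, n_samples: int = 160,
                max_missing: float = 0.5, dense=None, coverage=None) -> np.ndarray | None:
    """One gene's flipped, resized OE raster; None if the gene is excluded.

    Exclusion: window out of chromosome bounds, or more than `max_missing`
    of the window pixels lacking an OE entry.
    """
    pad = int(round(padding_factor * gene.length))
    lo, hi = gene.start - pad, gene.end + pad
    try:
        win, covered = extract_window(oe, lo, hi, n_samples, dense, coverage)
    except ValueError:
        logger.debug("gene %s: window out of bounds, skipped", gene.gene_id)
        return None
    if 1.0 - covered > max_missing:
        logger.debug("gene %s: %.0f%% of window missing, skipped",
                     gene.gene_id, 100 * (1 - covered))
        return None
    raster = resize_bicubic(win, out_size)
    if gene.strand == "-":
        raster = raster[::-1, ::-1]
    return raster


def pileup(genes, oe: OEMatrix, padding_factor: float = 0.5,
           out_size: int = 80, n_samples: int = 160,
           max_missing: float = 0.5) -> PileupImage:
    """Mean raster over a gene cohort ((-) strand genes rotated 180 degrees)."""
    dense = oe.to_dense()
    coverage = np.zeros(dense.shape, dtype=bool)
    coverage[oe.row, oe.col] = True
    coverage[oe.col, oe.row] = True
    acc = np.zeros((out_size, out_size))
    n = 0
    for gene in genes:
        raster = gene_raster(oe, gene, padding_factor, out_size, n_samples,
                             max_missing, dense, coverage)
        if raster is not None:
            acc += raster
            n += 1
    if n == 0:
        raise ValueError("no eligible genes in cohort")
    logger.info("pileup: averaged %d genes (padding %.1f)", n, padding_factor)
    return PileupImage(acc / n, n, padding_factor)


def _gene_bounds(size: int, padding_factor: float) -> tuple[int, int]:
    share = 1.0 / (1.0 + 2.0 * padding_factor)
    g0 = int(round(size * (1.0 - share) / 2.0))
    return g0, size - g0


def subregion_masks(size: int = 80, padding_factor: float = 0.5) -> dict:
    """Boolean masks tiling the upper triangle (diagonal included) into six blocks."""
    g0, g1 = _gene_bounds(size, padding_factor)
    r, c = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    upper = r <= c
    up_r, gene_r, down_r = r < g0, (r >= g0) & (r < g1), r >= g1
    up_c, gene_c, down_c = c < g0, (c >= g0) & (c < g1), c >= g1
    return {
        "S-A": upper & up_r & up_c,
        "S-B": upper & up_r & gene_c,
        "S-C": upper & up_r & down_c,
        "G": upper & gene_r & gene_c,
        "S-D": upper & gene_r & down_c,
        "S-E": upper & down_r & down_c,
    }


def subregion_sums(image: PileupImage) -> SubregionSums:
    masks = subregion_masks(image.size, image.padding_factor)
    sums, means, n_pix = {}, {}, {}
    for name, mask in masks.items():
        vals = image.raster[mask]
        sums[name] = float(vals.sum())
        means[name] = float(vals.mean())
        n_pix[name] = int(mask.sum())
    return SubregionSums(sums, means, n_pix)


def domain_score(image: PileupImage) -> DomainScore:
    sr = subregion_sums(image)
    if sr.means["S-C"] == 0:
        return DomainScore(None)
    return DomainScore(sr.means["G"] / sr.means["S-C"])


def group_by_value(items, values, n_groups: int = 10) -> list[str]:
    """Label items Q1..Qn by descending value (Q1 highest).

    Groups are as equal as possible; the remainder goes to the earliest
    groups.  Ties keep stable input order.
    """
    items = list(items)
    values = np.asarray(values, dtype=np.float64)
    if len(items) != values.size:
        raise ValueError("items and values must have equal length")
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if len(items) < n_groups:
        raise ValueError(f"cannot split {len(items)} items into {n_groups} groups")
    # stable descending sort: ascending stable sort, then reverse via ranks
    order = np.argsort(-values, kind="stable")
    n = len(items)
    base, rem = divmod(n, n_groups)
    sizes = [base + 1] * rem + [base] * (n_groups - rem)
    labels = [""] * n
    pos = 0
    for g, size in enumerate(sizes, start=1):
        for idx in order[pos:pos + size]:
            labels[idx] = f"Q{g}"
        pos += size
    return labels


def correlate_subregions(subregion_table: pd.DataFrame,
                         feature_table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between per-gene subregion sums and feature enrichments.

    Both tables are indexed by gene; rows are aligned on the shared index.
    Returns a long table (subregion, feature, rho, p); rho is NaN when
    either vector is constant (flagged via the `defined` column).
    """
    shared = subregion_table.index.intersection(feature_table.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genes with both measurements")
    sub = subregion_table.loc[shared]
    feat = feature_table.loc[shared]
    rows = []
    for region in sub.columns:
        for feature in feat.columns:
            x, y = sub[region].to_numpy(), feat[feature].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append((region, feature, np.nan, np.nan, False))
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append((region, feature, float(rho), float(p), True))
    return pd.DataFrame(rows, columns=["subregion", "feature", "rho", "p", "defined"])


def diff_pileup(image_a: PileupImage, image_b: PileupImage) -> PileupImage:
    """Elementwise difference a - b of two equally shaped pile-ups."""
    if image_a.raster.shape != image_b.raster.shape:
        raise ValueError("pile-up shapes differ")
    if image_a.padding_factor != image_b.padding_factor:
        raise ValueError("pile-up padding factors differ")
    logger.info("diff_pileup: cohorts n=%d vs n=%d", image_a.n_genes, image_b.n_genes)
    return PileupImage(image_a.raster - image_b.raster,
                       min(image_a.n_genes, image_b.n_genes),
                       image_a.padding_factor)


def write_pileup_tsv(image: PileupImage, path) -> None:
    """Raster as TSV; n_genes/padding in a JSON sidecar `<path>.json`."""
    import json

    np.savetxt(path, image.raster, delimiter="\t")
    with open(str(path) + ".json", "w") as fh:
        json.dump({"n_genes": image.n_genes,
                   "padding_factor": image.padding_factor,
                   "size": image.size}, fh)


def read_pileup_tsv(path) -> PileupImage:
    import json

    raster = np.loadtxt(path, delimiter="\t")
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return PileupImage(raster, meta["n_genes"], meta["padding_factor"])
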