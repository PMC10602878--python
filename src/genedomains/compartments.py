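"""A/B compartment analysis on binned OE maps.

Counts are aggregated over n consecutive fragments (n = 5 or 50), the
binned map is OE-normalized, and the Pearson correlation matrix of its
rows is eigendecomposed.  Bin labels come from the first eigenvector:
either its sign (coarse mode) or the thresholded rule A if ev > 0.002,
B if ev < -0.003, else none (local mode).  Gene classes (A, B, AB, BA,
ABA, BAB) collapse the run sequence of labeled bins over the gene body,
read 5' to 3'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_matrix import ContactMatrix, bin_fragments, observed_over_expected

__all__ = [
    "CompartmentTrack",
    "A_THRESHOLD",
    "B_THRESHOLD",
    "binned_oe_dense",
    "correlation_matrix",
    "first_eigenvector",
    "assign_labels",
    "compartment_track",
    "gene_class",
]

A_THRESHOLD = 0.002
B_THRESHOLD = -0.003


@dataclass
class CompartmentTrack:
    """Per-bin first-eigenvector values and A/B/none labels.

    `bin_starts`/`bin_ends` are bp intervals of the n-fragment bins;
    masked (zero-variance) bins carry NaN eigenvector values and label
    "none".
    """

    chromosome: str
    bin_starts: np.ndarray
    bin_ends: np.ndarray
    eigenvector: np.ndarray
    labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chromosome, "start": self.bin_starts,
                             "end": self.bin_ends, "ev": self.eigenvector,
                             "label": self.labels})


def binned_oe_dense(matrix: ContactMatrix, n_per_bin: int):
    """Sum counts into n-fragment bins and OE-normalize; returns (dense, binned_map)."""
    binned = bin_fragments(matrix, n_per_bin)
    oe = observed_over_expected(binned)
    return oe.to_dense(), binned.fragment_map


def correlation_matrix(dense_oe: np.ndarray):
    """Pearson correlation of bin rows, zero-variance bins masked.

    Returns (corr, kept_indices): `corr` is over kept bins with unit
    diagonal.
    """
    dense_oe = np.asarray(dense_oe, dtype=np.float64)
    kept = np.flatnonzero(dense_oe.std(axis=1) > 0)
    if kept.size < 3:
        raise ValueError("need at least 3 bins with variance > 0")
    sub = dense_oe[np.ix_(kept, kept)]
    # re-check variance after masking columns
    keep2 = sub.std(axis=1) > 0
    kept = kept[keep2]
    if kept.size < 3:
        raise ValueError("need at least 3 bins with variance > 0")
    sub = dense_oe[np.ix_(kept, kept)]
    corr = np.corrcoef(sub)
    np.fill_diagonal(corr, 1.0)
    return corr, kept


def first_eigenvector(corr: np.ndarray, accessibility: np.ndarray | None = None) -> np.ndarray:
    """Unit eigenvector of the largest-magnitude eigenvalue.

    Sign convention: positive Pearson correlation with per-bin
    `accessibility` when provided, otherwise first nonzero entry made
    positive.
    """
    corr = np.asarray(corr, dtype=np.float64)
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(np.abs(evals))[::-1]
    if evals.size > 1 and np.isclose(np.abs(evals[order[0]]), np.abs(evals[order[1]])):
        warnings.warn("leading eigenvalue is (near-)degenerate; "
                      "orientation rule breaks the tie deterministically")
    v = evecs[:, order[0]]
    v = v / np.linalg.norm(v)
    flip = False
    if accessibility is not None and np.std(accessibility) > 0 and np.std(v) > 0:
        flip = np.corrcoef(v, accessibility)[0, 1] < 0
    else:
        nz = np.flatnonzero(v)
        flip = v[nz[0]] < 0 if nz.size else False
    return -v if flip else v


def assign_labels(ev: np.ndarray, mode: str = "thresholded") -> np.ndarray:
    """Per-bin A/B/none labels from eigenvector values.

    mode "sign": A if ev > 0 else B.  mode "thresholded": A if
    ev > 0.002, B if ev < -0.003, else none.  NaN is always "none".
    """
    ev = np.asarray(ev, dtype=np.float64)
    labels = np.full(ev.shape, "none", dtype=object)
    ok = np.isfinite(ev)
    if mode == "sign":
        labels[ok & (ev > 0)] = "A"
        labels[ok & (ev <= 0)] = "B"
    elif mode == "thresholded":
        labels[ok & (ev > A_THRESHOLD)] = "A"
        labels[ok & (ev < B_THRESHOLD)] = "B"
    else:
        raise ValueError("mode must be 'sign' or 'thresholded'")
    return np.asarray(labels, dtype=object)


def compartment_track(matrix: ContactMatrix, n_per_bin: int = 5,
                      mode: str = "thresholded",
                      accessibility: np.ndarray | None = None) -> CompartmentTrack:
    """Full pipeline: bin, OE, correlate, eigendecompose, label."""
    dense, binned_map = binned_oe_dense(matrix, n_per_bin)
    corr, kept = correlation_matrix(dense)
    acc = accessibility[kept] if accessibility is not None else None
    v = first_eigenvector(corr, acc)
    ev = np.full(binned_map.n_fragments, np.nan)
    ev[kept] = v
    return CompartmentTrack(binned_map.chromosome, binned_map.starts,
                            binned_map.ends, ev, assign_labels(ev, mode))


def gene_class(gene, track: CompartmentTrack) -> str:
    """Compartment class of a gene from its overlapping labeled bins.

    The A/B run sequence over the gene body (5' to 3'; "none" bins are
    skipped) maps to A, B, AB, BA, ABA or BAB; anything longer, or a gene
    with no labeled bin, is "excluded".
    """
    overlap = (track.bin_ends > gene.start) & (track.bin_starts < gene.end)
    labels = [l for l in track.labels[overlap] if l in ("A", "B")]
    if gene.strand == "-":
        labels = labels[::-1]
    runs: list[str] = []
    for l in labels:
        if not runs or runs[-1] != l:
            runs.append(l)
    seq = "".join(runs)
    if seq in ("A", "B", "AB", "BA", "ABA", "BAB"):
        return seq
    return "excluded"
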