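"""Directionality index (DI) on OE contact maps, and metagene profiling.

The DI of a fragment contrasts its summed OE contacts with fragments up
to ``window_bp`` upstream (A) against those downstream (B):

    E  = (A + B) / 2
    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)

with DI defined as 0 when A == B (the sign factor is otherwise
undefined; this includes the no-contact case A == B == 0).

Window membership for irregular fragment lengths: a fragment g belongs to
the upstream window of focal fragment f when its midpoint lies in
``[start_f - window, start_f)``, and to the downstream window when it
lies in ``(end_f, end_f + window]``.  The half-open/half-closed pairing
makes DI exactly antisymmetric under coordinate reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_matrix import OEMatrix

__all__ = ["DIProfile", "MetageneProfile", "di_score", "di_track", "metagene",
           "write_di_bedgraph"]


@dataclass
class DIProfile:
    """Per-fragment DI values with their A/B/E components kept for audit."""

    fragment_map: object
    di: np.ndarray
    upstream: np.ndarray
    downstream: np.ndarray

    @property
    def expected(self) -> np.ndarray:
        return (self.upstream + self.downstream) / 2.0

    def to_per_bp(self) -> np.ndarray:
        """Expand to a per-bp signal array (each fragment's DI over its span)."""
        fm = self.fragment_map
        out = np.empty(fm.length)
        for k in range(fm.n_fragments):
            out[fm.starts[k]:fm.ends[k]] = self.di[k]
        return out


@dataclass
class MetageneProfile:
    """Mean signal in fixed bins over upstream flank, scaled body, downstream flank."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])

    def to_frame(self) -> pd.DataFrame:
        segs = (["upstream"] * self.upstream.size + ["body"] * self.body.size
                + ["downstream"] * self.downstream.size)
        return pd.DataFrame({"bin": np.arange(self.values.size), "segment": segs,
                             "mean": self.values, "n": self.n_genes})


def _di_from_sums(a: float, b: float) -> float:
    if a == b:
        return 0.0
    e = (a + b) / 2.0
    chi = (a - e) ** 2 / e + (b - e) ** 2 / e
    return float(np.sign(b - a) * chi)


def di_score(oe: OEMatrix, fragment_index: int, window_bp: float = 10_000) -> float:
    """DI of one fragment; window truncated silently at chromosome edges."""
    fm = oe.fragment_map
    mids = fm.midpoints
    dense = oe.to_dense()
    s, e = fm.starts[fragment_index], fm.ends[fragment_index]
    up = (mids >= s - window_bp) & (mids < s)
    down = (mids > e) & (mids <= e + window_bp)
    return _di_from_sums(float(dense[fragment_index, up].sum()),
                         float(dense[fragment_index, down].sum()))


def di_track(oe: OEMatrix, window_bp: float = 10_000) -> DIProfile:
    """DI for every fragment of the map."""
    fm = oe.fragment_map
    mids = fm.midpoints
    dense = oe.to_dense()
    n = fm.n_fragments
    di = np.zeros(n)
    ups = np.zeros(n)
    downs = np.zeros(n)
    for f in range(n):
        s, e = fm.starts[f], fm.ends[f]
        up = (mids >= s - window_bp) & (mids < s)
        down = (mids > e) & (mids <= e + window_bp)
        a = float(dense[f, up].sum())
        b = float(dense[f, down].sum())
        ups[f], downs[f] = a, b
        di[f] = _di_from_sums(a, b)
    return DIProfile(fm, di, ups, downs)


def write_di_bedgraph(profile: DIProfile, path) -> None:
    fm = profile.fragment_map
    pd.DataFrame({"chrom": fm.chromosome, "start": fm.starts,
                  "end": fm.ends, "value": profile.di}).to_csv(
        path, sep="\t", header=False, index=False)


def _rebin(signal: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a 1-D signal into n_bins equal-width (bp-proportional) bins."""
    if signal.size == 0:
        return np.full(n_bins, np.nan)
    if signal.size < n_bins:
        # shorter than one bin per spec: spread the per-bp values evenly
        edges = np.linspace(0, signal.size, n_bins + 1)
        out = np.empty(n_bins)
        for k in range(n_bins):
            lo, hi = int(np.floor(edges[k])), int(np.ceil(edges[k + 1]))
            out[k] = signal[lo:max(hi, lo + 1)].mean()
        return out
    edges = np.linspace(0, signal.size, n_bins + 1).round().astype(int)
    return np.array([signal[edges[k]:edges[k + 1]].mean() for k in range(n_bins)])


def metagene(signal: np.ndarray, genes, n_bins: int = 100,
             flank_bp: int | None = None) -> MetageneProfile:
    """Average a per-bp signal over gene bodies and flanks.

    Each gene body is rescaled to `n_bins` bins; flanks of `flank_bp`
    (default: median gene length) get `n_bins` bins each.  (-) strand
    genes contribute their profile reversed.  Genes whose flanks exceed
    the signal bounds have the out-of-bounds part dropped (NaN-ignored in
    the mean).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no genes supplied")
    if flank_bp is None:
        flank_bp = int(np.median([g.end - g.start for g in genes]))
    total = 3 * n_bins
    acc = np.zeros(total)
    cnt = np.zeros(total)
    for g in genes:
        lo, hi = g.start - flank_bp, g.end + flank_bp
        body = _rebin(signal[g.start:g.end], n_bins)
        up = _rebin(signal[max(lo, 0):g.start], n_bins) if g.start > 0 else np.full(n_bins, np.nan)
        down = (_rebin(signal[g.end:min(hi, signal.size)], n_bins)
                if g.end < signal.size else np.full(n_bins, np.nan))
        prof = np.concatenate([up, body, down])
        if g.strand == "-":
            prof = prof[::-1]
        ok = np.isfinite(prof)
        acc[ok] += prof[ok]
        cnt[ok] += 1
    mean = np.divide(acc, cnt, out=np.full(total, np.nan), where=cnt > 0)
    return MetageneProfile(mean[:n_bins], mean[n_bins:2 * n_bins],
                           mean[2 * n_bins:], len(genes))
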