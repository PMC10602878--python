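"""Gene annotations, accessibility tracks and domain-border scoring.

Accessibility at a gene border (TSS or TES) is the maximum track value
within a 100 bp flank on either side of the site.  Single genes are
ranked by the product of their TSS and TES accessibility; runs of k
adjacent genes (all intergenic gaps < 40 kb) form candidate multigene
domains ranked by the product of their outer-border accessibilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "AccessibilityTrack",
    "BorderScore",
    "MultigeneDomain",
    "site_accessibility",
    "border_score",
    "enumerate_multigene",
    "classify_orientation",
    "multigene_pileup_windows",
    "read_gff3_genes",
    "read_bed6_genes",
    "write_genes_gff3",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: 0-based half-open interval plus strand.

    TSS/TES are derived, strand-aware: the TSS of a (-) gene is its `end`
    coordinate.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class AccessibilityTrack:
    """Non-negative per-bp signal with bedGraph semantics.

    Stored as sorted, non-overlapping (start, end, value) runs per
    chromosome; positions not covered by a run read as 0.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if np.any(ends <= starts) or np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: intervals must be sorted and non-overlapping")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: signal must be >= 0")
            self._runs[chrom] = (starts, ends, values)

    @classmethod
    def from_array(cls, chrom: str, signal: np.ndarray) -> "AccessibilityTrack":
        """Run-length-encode a dense per-bp array."""
        signal = np.asarray(signal, dtype=np.float64)
        change = np.flatnonzero(np.diff(signal)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [signal.size]])
        return cls({chrom: (starts, ends, signal[starts])})

    @property
    def chromosomes(self) -> list[str]:
        return list(self._runs)

    def chrom_end(self, chrom: str) -> int:
        return int(self._runs[chrom][1][-1])

    def max_over(self, chrom: str, lo: int, hi: int) -> float:
        """Max signal on [lo, hi), clipped to the track; 0 if no data."""
        if chrom not in self._runs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        starts, ends, values = self._runs[chrom]
        lo = max(lo, 0)
        i = np.searchsorted(ends, lo, side="right")
        j = np.searchsorted(starts, hi, side="left")
        if j <= i:
            return 0.0
        return float(values[i:j].max())

    def to_array(self, chrom: str, length: int | None = None) -> np.ndarray:
        starts, ends, values = self._runs[chrom]
        length = length if length is not None else int(ends[-1])
        out = np.zeros(length)
        for s, e, v in zip(starts, ends, values):
            out[s:min(e, length)] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        parts = [pd.DataFrame({"chrom": c, "start": s, "end": e, "value": v})
                 for c, (s, e, v) in self._runs.items()]
        return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class BorderScore:
    """TSS/TES accessibility of one gene and the derived product and ratio."""

    tss_acc: float
    tes_acc: float

    @property
    def product(self) -> float:
        return self.tss_acc * self.tes_acc

    @property
    def ratio(self) -> float | None:
        """tss / tes accessibility; None (undefined) when tes is 0."""
        if self.tes_acc == 0:
            return None
        return self.tss_acc / self.tes_acc


@dataclass(frozen=True)
class MultigeneDomain:
    """A run of k adjacent genes treated as one domain.

    The left border is the outer-facing site of the first gene (its site
    at the run's leftmost coordinate); mirrored for the right border.
    """

    genes: tuple[GeneAnnotation, ...]
    lb_site: str  # "TSS" or "TES"
    rb_site: str
    lb_acc: float
    rb_acc: float
    internal_acc: tuple[float, ...]

    @property
    def start(self) -> int:
        return self.genes[0].start

    @property
    def end(self) -> int:
        return self.genes[-1].end

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def chromosome(self) -> str:
        return self.genes[0].chromosome

    @property
    def border_product(self) -> float:
        return self.lb_acc * self.rb_acc

    def internal_ratio_score(self) -> float | None:
        """border_product / product of internal border accessibilities.

        None when any internal accessibility is 0 (undefined).
        """
        denom = float(np.prod(self.internal_acc)) if self.internal_acc else 1.0
        if denom == 0:
            return None
        return self.border_product / denom

    @property
    def orientation(self) -> str | None:
        if len(self.genes) != 2:
            return None
        return classify_orientation(self.genes[0], self.genes[1])


def site_accessibility(track: AccessibilityTrack, chrom: str, position: int,
                       flank: int = 100) -> float:
    """Max accessibility within `flank` bp on either side of `position`."""
    return track.max_over(chrom, position - flank, position + flank + 1)


def border_score(gene: GeneAnnotation, track: AccessibilityTrack,
                 flank: int = 100) -> BorderScore:
    return BorderScore(
        tss_acc=site_accessibility(track, gene.chromosome, gene.tss, flank),
        tes_acc=site_accessibility(track, gene.chromosome, gene.tes, flank),
    )


def classify_orientation(left: GeneAnnotation, right: GeneAnnotation) -> str:
    """Orientation of an adjacent gene pair: (+,-) convergent, (-,+) divergent."""
    pair = (left.strand, right.strand)
    if pair == ("+", "-"):
        return "convergent"
    if pair == ("-", "+"):
        return "divergent"
    return "parallel"


def _outer_sites(first: GeneAnnotation, last: GeneAnnotation) -> tuple[str, str]:
    lb = "TSS" if first.strand == "+" else "TES"
    rb = "TES" if last.strand == "+" else "TSS"
    return lb, rb


def enumerate_multigene(genes: Sequence[GeneAnnotation], k: int,
                        track: AccessibilityTrack | None = None,
                        max_gap: int = 40_000, flank: int = 100,
                        min_gap: int | None = None) -> list[MultigeneDomain]:
    """All runs of k consecutive genes whose intergenic gaps are < max_gap.

    Genes must be sorted by start within one chromosome.  Overlapping
    genes count as gap 0.  `min_gap` optionally requires every gap to
    exceed it (linear-distance control).  Border accessibilities are 0
    when no track is given.
    """
    if k < 2:
        raise ValueError("multigene domains need k >= 2")
    genes = sorted(genes, key=lambda g: (g.chromosome, g.start))
    out: list[MultigeneDomain] = []
    for i in range(len(genes) - k + 1):
        run = genes[i:i + k]
        if len({g.chromosome for g in run}) != 1:
            continue
        gaps = [max(0, b.start - a.end) for a, b in zip(run, run[1:])]
        if any(g >= max_gap for g in gaps):
            continue
        if min_gap is not None and any(g <= min_gap for g in gaps):
            continue
        lb_site, rb_site = _outer_sites(run[0], run[-1])
        if track is not None:
            chrom = run[0].chromosome
            lb = site_accessibility(track, chrom, run[0].start, flank)
            rb = site_accessibility(track, chrom, run[-1].end, flank)
            internal = []
            for gi, g in enumerate(run):
                for pos in (g.start, g.end):
                    if (gi, pos) in ((0, run[0].start), (k - 1, run[-1].end)):
                        continue
                    internal.append(site_accessibility(track, chrom, pos, flank))
        else:
            lb = rb = 0.0
            internal = [0.0] * (2 * k - 2)
        out.append(MultigeneDomain(tuple(run), lb_site, rb_site, lb, rb,
                                   tuple(internal)))
    return out


def multigene_pileup_windows(domains: Iterable[MultigeneDomain],
                             chrom_length: int,
                             padding_factor: float = 0.5):
    """Pile-up windows [start - pad*len, end + pad*len) for each domain.

    Domains whose window exceeds chromosome bounds are excluded.  Returns
    (kept_domains, windows) where each window is a (start, end, strand)
    tuple on the '+' strand (multigene pile-ups are not strand-flipped).
    """
    kept, windows = [], []
    for d in domains:
        pad = int(round(padding_factor * d.length))
        lo, hi = d.start - pad, d.end + pad
        if lo < 0 or hi > chrom_length:
            continue
        kept.append(d)
        windows.append((lo, hi, "+"))
    return kept, windows


# ---------------------------------------------------------------------------
# annotation / track I/O

def _parse_gff_attributes(attr: str) -> dict:
    out = {}
    for field in attr.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3_genes(path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Genes from a GFF3 file (1-based closed coords converted to 0-based)."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    df = df[df["type"] == feature_type]
    genes = []
    for n, row in enumerate(df.itertuples(index=False)):
        attrs = _parse_gff_attributes(row.attributes)
        gid = attrs.get("ID", attrs.get("gene_id", f"gene{n}"))
        genes.append(GeneAnnotation(gid, str(row.seqid), int(row.start) - 1,
                                    int(row.end), row.strand))
    return genes


def write_genes_gff3(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chromosome}\tgenedomains\tgene\t{g.start + 1}\t{g.end}"
                     f"\t.\t{g.strand}\t.\tID={g.gene_id}\n")


def read_bed6_genes(path) -> list[GeneAnnotation]:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return [GeneAnnotation(str(r.name_), str(r.chrom), int(r.start), int(r.end), r.strand)
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)]


def read_bedgraph(path) -> AccessibilityTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="t")
    runs = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        runs[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                            sub["value"].to_numpy())
    return AccessibilityTrack(runs)


def write_bedgraph(track: AccessibilityTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)
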