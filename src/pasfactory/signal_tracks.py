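"""Coverage normalisation, enrichment-region calling, and metagene assembly.

A ``SignalTrack`` holds per-chromosome signal vectors at a fixed bin size
(1 bp for nascent-RNA 3'-end tracks, 50 bp for ChIP coverage).  Tracks can be
normalised to sequencing depth (counts per million mapped reads) or calibrated
against an exogenous spike-in (reads per million spike-in reads), which makes
global occupancy changes between samples measurable — depth normalisation
alone cancels any genome-wide proportional change.

Enriched regions are called per 50-bp bin with a Poisson upper-tail test
against a local background rate (the maximum of the scaled input in the bin,
its 5-kb and 10-kb neighbourhood means, and the genome-wide mean), BH-adjusted
genome-wide; significant bins with gaps up to 1 kb are merged into broad
regions.  Dual-antibody enrichment is the base-pair intersection of two
antibodies' region sets.  An adapter reads externally produced
narrowPeak/broadPeak files so an external caller's output can substitute.

The composite metagene concatenates, per gene, 50-bp binned signal over
TSS -5 kb..+1.5 kb (130 bins), gene-body bins 4..22 of 25 equal bins
(19 bins) and PAS -1.5 kb..+10 kb (230 bins) — 379 columns, with minus-strand
genes reversed so column order always runs 5' to 3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignalTrack",
    "EnrichedRegionSet",
    "MetageneMatrix",
    "calibrate_spikein",
    "depth_normalize",
    "call_enriched_regions",
    "intersect_antibodies",
    "read_peak_file",
    "classify_gene_enrichment",
    "build_metagene",
]

BIN = 50


@dataclass
class SignalTrack:
    """Binned signal vectors per chromosome.

    ``bin_size`` is the genomic width of one vector element.  ``total_reads``
    and ``spike_reads`` are the raw tallies used for depth / spike-in scaling;
    ``scale_applied`` records the factor already multiplied in.
    """

    values: dict[str, np.ndarray]
    bin_size: int = 1
    sample: str = "sample"
    stranded: bool = False
    strand: str | None = None
    total_reads: int | None = None
    spike_reads: int | None = None
    scale_applied: float = 1.0

    def copy(self) -> "SignalTrack":
        return replace(self, values={c: v.copy() for c, v in self.values.items()})

    def scaled(self, factor: float) -> "SignalTrack":
        out = self.copy()
        for v in out.values.values():
            v *= factor
        out.scale_applied = self.scale_applied * factor
        return out

    def genome_mean(self) -> float:
        tot = sum(float(v.sum()) for v in self.values.values())
        n = sum(v.size for v in self.values.values())
        return tot / n if n else 0.0

    def binned(self, bin_size: int) -> "SignalTrack":
        """Re-bin to a coarser resolution by summation."""
        if bin_size % self.bin_size:
            raise ValueError("target bin size must be a multiple of the current one")
        k = bin_size // self.bin_size
        if k == 1:
            return self.copy()
        out = {}
        for c, v in self.values.items():
            nb = int(np.ceil(v.size / k))
            pad = np.zeros(nb * k, dtype=float)
            pad[: v.size] = v
            out[c] = pad.reshape(nb, k).sum(axis=1)
        return replace(self, values=out, bin_size=bin_size)

    def sum(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


@dataclass
class EnrichedRegionSet:
    """Merged, non-overlapping significant regions for one antibody."""

    antibody: str
    regions: pd.DataFrame  # chrom, start, end, qvalue
    fdr: float

    def __post_init__(self) -> None:
        want = ["chrom", "start", "end", "qvalue"]
        if list(self.regions.columns)[:4] != want:
            self.regions = self.regions.reindex(columns=want)

    def total_bp(self) -> int:
        if self.regions.empty:
            return 0
        return int((self.regions.end - self.regions.start).sum())

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, r in self.regions.iterrows():
                fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t"
                         f"{self.antibody}_{i}\t{r.qvalue:.3g}\t.\n")


@dataclass
class MetageneMatrix:
    """Per-gene composite profiles (rows sorted by descending mean signal)."""

    matrix: pd.DataFrame  # rows: gene_id, columns: composite bin index
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def mean_profile(self) -> np.ndarray:
        return np.nanmean(self.matrix.to_numpy(dtype=float), axis=0)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    """Write a track as bedGraph (runs of equal value collapsed)."""
    with open(path, "w") as fh:
        for chrom, v in track.values.items():
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [v.size]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s * track.bin_size}\t{e * track.bin_size}"
                             f"\t{v[s]:g}\n")


def read_bedgraph(path: str, chrom_sizes: dict[str, int], bin_size: int = 1,
                  sample: str = "sample") -> SignalTrack:
    """Read a bedGraph into a binned SignalTrack (values summed per bin)."""
    values = {c: np.zeros(int(np.ceil(n / bin_size))) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            chrom, s, e, v = line.split()[:4]
            if chrom not in values:
                continue
            s, e, v = int(s), int(e), float(v)
            if bin_size == 1:
                values[chrom][s:e] += v
            else:
                for pos in range(s, e, bin_size):
                    b = pos // bin_size
                    span = min(e, (b + 1) * bin_size) - pos
                    values[chrom][b] += v * span / bin_size
    return SignalTrack(values, bin_size=bin_size, sample=sample)


def depth_normalize(track: SignalTrack, per: float = 1e6) -> SignalTrack:
    """Scale to signal per ``per`` mapped reads (CPM-style)."""
    total = track.total_reads if track.total_reads else track.sum()
    if total <= 0:
        raise ValueError("cannot depth-normalize an empty track")
    return track.scaled(per / total)


def calibrate_spikein(track: SignalTrack, spike_reads: int | None = None,
                      total_reads: int | None = None, per: float = 1e6) -> SignalTrack:
    """Scale signal by reads per million *spike-in* reads.

    With a constant exogenous chromatin admixture per cell, the spike-in read
    count is proportional to sequencing depth per unit of input chromatin, so
    this scaling preserves genuine global occupancy differences between
    samples.  Rejects ``spike_reads == 0`` (fall back to depth-only mode).
    """
    spike = spike_reads if spike_reads is not None else track.spike_reads
    if not spike or spike <= 0:
        raise ValueError("spike_reads must be > 0; use depth_normalize() for "
                         "depth-only scaling")
    out = track.scaled(per / spike)
    out.spike_reads = spike
    if total_reads is not None:
        out.total_reads = total_reads
    return out


# ---------------------------------------------------------------------------
# enrichment-region calling

def call_enriched_regions(
    ip: SignalTrack,
    control: SignalTrack,
    fdr: float = 0.01,
    antibody: str = "ab",
    local_bp: tuple[int, int] = (5000, 10000),
    merge_gap: int = 1000,
) -> EnrichedRegionSet:
    """Poisson local-background broad-region calling on 50-bp bins.

    The IP track must hold raw (integer) bin counts.  The input track is
    scaled to the IP depth; each bin's background rate is the maximum of the
    scaled input in that bin, its 5-kb and 10-kb window means, and the
    genome-wide input mean (guarding against rate underestimation in
    low-coverage stretches).  Upper-tail Poisson p-values are BH-adjusted over
    all bins; bins with q < ``fdr`` merged across gaps <= ``merge_gap`` give
    broad regions, each reporting its best bin q-value.  With a zero-coverage
    input the genome-wide IP mean serves as the only background rate.
    """
    ipb = ip.binned(BIN)
    inb = control.binned(BIN)
    ip_total, in_total = ipb.sum(), inb.sum()
    zero_input = in_total <= 0
    ratio = 1.0 if zero_input else ip_total / in_total

    pvals, keys = [], []
    for chrom, ipv in ipb.values.items():
        if zero_input:
            lam = np.full(ipv.size, max(ipb.genome_mean(), 1e-8))
        else:
            inv = inb.values[chrom] * ratio
            lam = np.maximum.reduce([
                inv,
                _window_mean(inv, local_bp[0] // BIN),
                _window_mean(inv, local_bp[1] // BIN),
                np.full(inv.size, inb.genome_mean() * ratio),
            ])
            lam = np.maximum(lam, 1e-8)
        p = stats.poisson.sf(np.round(ipv) - 1, lam)  # P(X >= observed)
        pvals.append(p)
        keys.append((chrom, ipv.size))

    flat = np.concatenate(pvals)
    q = multipletests(flat, method="fdr_bh")[1]

    rows = []
    off = 0
    for chrom, nb in keys:
        qc = q[off: off + nb]
        off += nb
        sig = np.flatnonzero(qc < fdr)
        if sig.size == 0:
            continue
        gap_bins = merge_gap // BIN
        run_start = prev = sig[0]
        for b in sig[1:]:
            if b - prev <= gap_bins + 1:
                prev = b
                continue
            rows.append((chrom, run_start * BIN, (prev + 1) * BIN,
                         float(qc[run_start: prev + 1].min())))
            run_start = prev = b
        rows.append((chrom, run_start * BIN, (prev + 1) * BIN,
                     float(qc[run_start: prev + 1].min())))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "qvalue"])
    return EnrichedRegionSet(antibody, df, fdr)


def _window_mean(x: np.ndarray, wbins: int) -> np.ndarray:
    if wbins <= 1:
        return x
    kernel = np.ones(wbins) / wbins
    return np.convolve(x, kernel, mode="same")


def intersect_antibodies(a: EnrichedRegionSet, b: EnrichedRegionSet) -> EnrichedRegionSet:
    """Base-pair intersection of two antibodies' enriched-region sets."""
    rows = []
    bb = b.regions.groupby("chrom") if not b.regions.empty else None
    for chrom, grp in (a.regions.groupby("chrom") if not a.regions.empty else []):
        if bb is None or chrom not in bb.groups:
            continue
        other = bb.get_group(chrom)
        for _, ra in grp.iterrows():
            for _, rb in other.iterrows():
                s, e = max(ra.start, rb.start), min(ra.end, rb.end)
                if s < e:
                    rows.append((chrom, int(s), int(e), float(max(ra.qvalue, rb.qvalue))))
    df = _merge_regions(pd.DataFrame(rows, columns=["chrom", "start", "end", "qvalue"]))
    return EnrichedRegionSet(f"{a.antibody}&{b.antibody}", df, max(a.fdr, b.fdr))


def _merge_regions(df: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping/adjacent intervals, keeping the best (min) q-value."""
    if df.empty:
        return df
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    cur = None
    for r in df.itertuples(index=False):
        if cur is not None and r.chrom == cur[0] and r.start <= cur[2]:
            cur[2] = max(cur[2], r.end)
            cur[3] = min(cur[3], r.qvalue)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [r.chrom, r.start, r.end, r.qvalue]
    rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "qvalue"])


def read_peak_file(path: str, antibody: str = "external", fdr: float = 0.01) -> EnrichedRegionSet:
    """Adapter for externally produced narrowPeak/broadPeak/BED region files.

    Column 9 (-log10 q) is converted back to a q-value when present.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            qv = 10 ** (-float(f[8])) if len(f) >= 9 else fdr
            rows.append((f[0], int(f[1]), int(f[2]), qv))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "qvalue"])
    return EnrichedRegionSet(antibody, df, fdr)


# ---------------------------------------------------------------------------
# gene-level enrichment classes

def classify_gene_enrichment(
    genes: list,
    enriched: EnrichedRegionSet,
    pas_upstream: int = 2000,
    pas_downstream: int = 5000,
) -> pd.DataFrame:
    """Classify each gene as not_enriched / three_prime / tss_gene_body.

    A gene is enriched if a region overlaps its body (TSS to PAS) or the PAS
    to +5 kb downstream window.  It is ``three_prime`` when a region overlaps
    PAS -2 kb..+5 kb (strand-aware), regardless of additional enrichment at
    the TSS or elsewhere; all other enriched genes are ``tss_gene_body``.
    The gene's 3' coordinate is its maximum-signal PAS summit when known,
    else the annotated end.
    """
    by_chrom: dict[str, np.ndarray] = {}
    if not enriched.regions.empty:
        for chrom, grp in enriched.regions.groupby("chrom"):
            by_chrom[chrom] = grp[["start", "end"]].to_numpy()

    def overlaps(chrom: str, lo: int, hi: int) -> bool:
        arr = by_chrom.get(chrom)
        if arr is None or lo >= hi:
            return False
        return bool(np.any((arr[:, 0] < hi) & (lo < arr[:, 1])))

    rows = []
    for ag in genes:
        g = ag.gene if hasattr(ag, "gene") else ag
        pas = ag.end_coordinate() if hasattr(ag, "end_coordinate") else g.annotated_end
        tss = g.tss
        body = (min(tss, pas), max(tss, pas) + 1)
        if g.strand == "+":
            pas_win = (pas - pas_upstream, pas + pas_downstream + 1)
            down_win = (pas, pas + pas_downstream + 1)
        else:
            pas_win = (pas - pas_downstream, pas + pas_upstream + 1)
            down_win = (pas - pas_downstream, pas + 1)
        pas_win = (max(0, pas_win[0]), pas_win[1])
        down_win = (max(0, down_win[0]), down_win[1])

        in_body = overlaps(g.chrom, *body)
        in_down = overlaps(g.chrom, *down_win)
        in_pas = overlaps(g.chrom, *pas_win)
        if not (in_body or in_down):
            cls = "not_enriched"
        elif in_pas:
            cls = "three_prime"
        else:
            cls = "tss_gene_body"
        rows.append({"gene_id": g.gene_id, "class": cls})
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# metagene

TSS_UP, TSS_DOWN = 5000, 1500
PAS_UP, PAS_DOWN = 1500, 10000
GB_BINS, GB_KEEP = 25, (4, 22)  # inclusive 1-based indices of kept body bins


def build_metagene(
    tracks: list[SignalTrack] | SignalTrack,
    genes: list,
    bin_size: int = BIN,
) -> MetageneMatrix:
    """Assemble the 379-column composite metagene matrix.

    Signal is the average of the supplied (replicate) tracks.  Stranded tracks
    are matched to the gene strand; unstranded tracks are used as-is.  Genes
    truncated by a chromosome edge are padded with NaN, which is excluded from
    column means.  Rows are sorted by descending mean signal.
    """
    if isinstance(tracks, SignalTrack):
        tracks = [tracks]
    n_tss = (TSS_UP + TSS_DOWN) // bin_size
    n_pas = (PAS_UP + PAS_DOWN) // bin_size
    n_gb = GB_KEEP[1] - GB_KEEP[0] + 1
    rows, ids = [], []
    for ag in genes:
        g = ag.gene if hasattr(ag, "gene") else ag
        pas = ag.end_coordinate() if hasattr(ag, "end_coordinate") else g.annotated_end
        per_track = []
        for t in tracks:
            if t.stranded and t.strand is not None and t.strand != g.strand:
                continue
            v = t.values.get(g.chrom)
            if v is None:
                continue
            sig = _expand(v, t.bin_size)
            tssb = _window_bins(sig, g.tss, TSS_UP, TSS_DOWN, g.strand, bin_size)
            gb = _body_bins(sig, g.tss, pas, g.strand)
            pasb = _window_bins(sig, pas, PAS_UP, PAS_DOWN, g.strand, bin_size)
            per_track.append(np.concatenate([tssb, gb[GB_KEEP[0] - 1: GB_KEEP[1]], pasb]))
        if not per_track:
            continue
        rows.append(np.nanmean(np.vstack(per_track), axis=0))
        ids.append(g.gene_id)
    mat = pd.DataFrame(np.vstack(rows) if rows else
                       np.empty((0, n_tss + n_gb + n_pas)), index=ids)
    if len(mat):
        order = np.argsort(-np.nanmean(mat.to_numpy(), axis=1), kind="stable")
        mat = mat.iloc[order]
    segments = {"tss": (0, n_tss), "body": (n_tss, n_tss + n_gb),
                "pas": (n_tss + n_gb, n_tss + n_gb + n_pas)}
    return MetageneMatrix(mat, segments)


def _expand(v: np.ndarray, bin_size: int) -> np.ndarray:
    """Per-base view of a binned vector (bin value spread as mean per base)."""
    if bin_size == 1:
        return v
    return np.repeat(v / bin_size, bin_size)


def _window_bins(sig: np.ndarray, anchor: int, up: int, down: int,
                 strand: str, bin_size: int) -> np.ndarray:
    """Mean signal in ``bin_size`` bins across anchor-up..anchor+down, 5'->3'."""
    if strand == "+":
        lo, hi = anchor - up, anchor + down
    else:
        lo, hi = anchor - down + 1, anchor + up + 1
    n = hi - lo
    window = np.full(n, np.nan)
    s, e = max(0, lo), min(sig.size, hi)
    if s < e:
        window[s - lo: e - lo] = sig[s:e]
    if strand == "-":
        window = window[::-1]
    nb = n // bin_size
    return np.nanmean(window[: nb * bin_size].reshape(nb, bin_size), axis=1)


def _body_bins(sig: np.ndarray, tss: int, pas: int, strand: str,
               n_bins: int = GB_BINS) -> np.ndarray:
    lo, hi = (tss, pas + 1) if strand == "+" else (pas, tss + 1)
    lo, hi = max(0, lo), min(sig.size, hi)
    if hi - lo < n_bins:
        return np.full(n_bins, np.nan)
    edges = np.linspace(lo, hi, n_bins + 1).astype(int)
    means = np.array([sig[edges[i]: edges[i + 1]].mean() for i in range(n_bins)])
    return means[::-1] if strand == "-" else means
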