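"""Polyadenylation-site (PAS) calling from 3' mRNA-seq read ends.

The QuantSeq-style oligo(dT) assay mis-primes on genome-encoded A stretches,
producing false 3'-end evidence ("internal priming").  The pipeline therefore:

1. builds a strand-specific genomic *priming mask* — every run of >= 6
   consecutive A and every 10-nt window containing more than 6 A on the plus
   strand, the T analogue on the minus strand — refined by 20-nt *unmask*
   windows centred on whitelisted genuine 3' ends (annotated gene ends,
   validated PAS) so real PAS in A/T-rich context survive;
2. reduces reads to their RNA 3'-terminal nucleotide and removes ends that
   fall in the mask;
3. calls PAS: depth-normalised end densities summed over all samples are
   tiled into non-overlapping 30-nt windows, windows with summed signal
   strictly above a threshold (default 30) are merged, local maxima within
   each merged interval seed new 30-nt intervals centred at the maxima, and
   one recentre-and-deduplicate pass resolves overlaps (residual overlaps
   keep the higher-signal interval);
4. counts per-sample raw reads in each PAS and assigns each PAS to the gene
   whose span, extended 6 kb downstream, contains its summit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PrimingMask",
    "End3Track",
    "PASInterval",
    "PASCountMatrix",
    "build_priming_mask",
    "reduce_to_end3",
    "filter_masked_ends",
    "call_pas",
    "quantify_pas",
]

PAS_WIDTH = 30


@dataclass
class PrimingMask:
    """Boolean per-base internal-priming masks, one per strand per chromosome."""

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    def masked_fraction(self) -> float:
        tot = sum(a.size for a in self.plus.values()) + sum(a.size for a in self.minus.values())
        hit = sum(int(a.sum()) for a in self.plus.values()) + sum(int(a.sum()) for a in self.minus.values())
        return hit / tot if tot else 0.0

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for strand, masks in (("+", self.plus), ("-", self.minus)):
                for chrom, arr in masks.items():
                    for s, e in _bool_runs(arr):
                        fh.write(f"{chrom}\t{s}\t{e}\tmask\t0\t{strand}\n")


@dataclass
class End3Track:
    """Per-base counts of read 3'-terminal nucleotides, both strands.

    ``plus``/``minus`` map chromosome -> integer count vector.  The library
    size is the total retained read count and is used for depth normalisation.
    """

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    sample: str = "sample"
    condition: str = ""
    skipped: int = 0  # unmapped/unstranded records dropped on reduction

    @property
    def library_size(self) -> int:
        return int(sum(a.sum() for a in self.plus.values())
                   + sum(a.sum() for a in self.minus.values()))

    def strand(self, s: str) -> dict[str, np.ndarray]:
        return self.plus if s == "+" else self.minus

    def copy(self) -> "End3Track":
        return End3Track(
            {c: a.copy() for c, a in self.plus.items()},
            {c: a.copy() for c, a in self.minus.items()},
            self.sample, self.condition, self.skipped,
        )

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], sample: str = "sample",
              condition: str = "") -> "End3Track":
        return cls(
            {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()},
            {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()},
            sample, condition,
        )


@dataclass
class PASInterval:
    """A called PAS: a 30-nt interval with its summit and per-sample counts."""

    chrom: str
    start: int
    end: int
    strand: str
    summit: int
    summed_signal: float = 0.0
    pas_id: str = ""
    gene_id: str | None = None
    order_index: int | None = None  # 5'->3' within the gene
    counts: dict[str, int] = field(default_factory=dict)

    def total_signal(self) -> float:
        return self.summed_signal

    def __post_init__(self) -> None:
        if self.end - self.start != PAS_WIDTH:
            raise ValueError(f"PAS interval must be {PAS_WIDTH} nt wide")
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the interval")


@dataclass
class PASCountMatrix:
    """Raw per-sample counts per PAS, with gene assignment and read accounting.

    ``counts`` rows are PAS ids; ``meta`` carries chrom/strand/summit/gene and
    the per-gene 5'->3' order index.  ``orphan_ids`` are PAS assigned to no
    extended gene span (kept, excluded from gene-level statistics).
    ``background_reads`` counts retained read ends outside every called PAS so
    that read conservation can be checked exactly:
    matrix + orphan + background + mask-filtered == total reduced reads.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    orphan_ids: list[str]
    background_reads: dict[str, int]

    def gene_counts(self, include_orphans: bool = False) -> pd.DataFrame:
        """Per-gene counts: sum of PAS counts over each gene's assigned PAS."""
        meta = self.meta if include_orphans else self.meta[self.meta.gene_id.notna()]
        joined = self.counts.loc[meta.index].join(meta[["gene_id"]])
        return joined.groupby("gene_id").sum(numeric_only=True)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# mask construction

_VALID = set(b"ACGTN")


def build_priming_mask(
    genome: dict[str, str],
    whitelist_ends: list[tuple[str, int, str]] | None = None,
    run_min: int = 6,
    window: int = 10,
    window_min_excl: int = 6,
    unmask_width: int = 20,
) -> PrimingMask:
    """Build the strand-specific internal-priming mask for a genome.

    Plus strand: mask every locus in a run of >= ``run_min`` consecutive A and
    every ``window``-nt window containing more than ``window_min_excl`` A.
    Minus strand: the same rules applied to T.  Whitelisted 3' ends
    (``(chrom, position, strand)``) carve strand-specific ``unmask_width``-nt
    holes centred on the position.

    Rejects sequences containing characters outside ACGTN (case-insensitive),
    reporting the first offending position.
    """
    plus, minus = {}, {}
    for chrom, seq in genome.items():
        b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        bad = ~np.isin(b, np.frombuffer(b"ACGTN", dtype=np.uint8))
        if bad.any():
            pos = int(np.argmax(bad))
            raise ValueError(
                f"invalid base {chr(b[pos])!r} at {chrom}:{pos} (only ACGTN allowed)")
        plus[chrom] = _rich_mask(b == ord("A"), run_min, window, window_min_excl)
        minus[chrom] = _rich_mask(b == ord("T"), run_min, window, window_min_excl)

    for chrom, pos, strand in (whitelist_ends or []):
        if chrom not in plus:
            continue
        target = plus[chrom] if strand == "+" else minus[chrom]
        half = unmask_width // 2
        target[max(0, pos - half): pos + unmask_width - half] = False
    return PrimingMask(plus, minus)


def _rich_mask(is_base: np.ndarray, run_min: int, window: int,
               window_min_excl: int) -> np.ndarray:
    n = is_base.size
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    # runs of >= run_min consecutive hits
    padded = np.concatenate(([False], is_base, [False]))
    d = np.diff(padded.astype(np.int8))
    starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s >= run_min:
            mask[s:e] = True
    # windows with strictly more than window_min_excl hits
    if n >= window:
        csum = np.concatenate(([0], np.cumsum(is_base)))
        wsum = csum[window:] - csum[:-window]
        hit_starts = np.flatnonzero(wsum > window_min_excl)
        if hit_starts.size:
            delta = np.zeros(n + 1, dtype=np.int32)
            np.add.at(delta, hit_starts, 1)
            np.add.at(delta, np.minimum(hit_starts + window, n), -1)
            mask |= np.cumsum(delta[:-1]) > 0
    return mask


def _bool_runs(arr: np.ndarray):
    padded = np.concatenate(([False], arr, [False]))
    d = np.diff(padded.astype(np.int8))
    return zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1))


# ---------------------------------------------------------------------------
# read-end reduction and filtering

def reduce_to_end3(
    reads,
    chrom_sizes: dict[str, int],
    protocol: str = "forward",
    sample: str = "sample",
    condition: str = "",
) -> End3Track:
    """Reduce aligned reads to one count at the RNA 3'-most aligned base.

    ``reads`` is an iterable of ``(chrom, start, end, strand)`` (half-open) or
    a BED6 path.  ``protocol`` declares whether the read strand equals the RNA
    strand (``forward``) or is its reverse complement (``reverse``, e.g.
    QuantSeq REV).  For a plus-strand RNA the 3' end is ``end - 1``; for a
    minus-strand RNA it is ``start``.  Records with unknown strand or
    chromosome are skipped and tallied in ``track.skipped``.
    """
    if protocol not in ("forward", "reverse"):
        raise ValueError("protocol must be 'forward' or 'reverse'")
    if isinstance(reads, str):
        reads = _iter_sam(reads) if reads.endswith((".bam", ".sam")) \
            else _iter_bed6(reads)
    track = End3Track.zeros(chrom_sizes, sample=sample, condition=condition)
    flip = {"+": "-", "-": "+"}
    for chrom, start, end, strand in reads:
        if strand not in flip or chrom not in track.plus:
            track.skipped += 1
            continue
        rna_strand = strand if protocol == "forward" else flip[strand]
        pos = end - 1 if rna_strand == "+" else start
        if not (0 <= pos < track.plus[chrom].size):
            track.skipped += 1
            continue
        track.strand(rna_strand)[chrom][pos] += 1
    return track


def _iter_sam(path: str):
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                yield "*", 0, 0, "."  # tallied as skipped
                continue
            strand = "-" if rec.is_reverse else "+"
            yield rec.reference_name, rec.reference_start, rec.reference_end, strand


def _iter_bed6(path: str):
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 6 or line.startswith(("#", "track", "browser")):
                continue
            yield f[0], int(f[1]), int(f[2]), f[5]


def filter_masked_ends(track: End3Track, mask: PrimingMask) -> tuple[End3Track, int]:
    """Zero 3'-end counts at masked positions; returns (filtered track, removed)."""
    out = track.copy()
    removed = 0
    for chrom, arr in out.plus.items():
        m = mask.plus.get(chrom)
        if m is not None:
            removed += int(arr[m].sum())
            arr[m] = 0
    for chrom, arr in out.minus.items():
        m = mask.minus.get(chrom)
        if m is not None:
            removed += int(arr[m].sum())
            arr[m] = 0
    return out, removed


# ---------------------------------------------------------------------------
# PAS calling

def call_pas(
    tracks: list[End3Track],
    window: int = PAS_WIDTH,
    min_signal: float = 30.0,
    depth_scale: float = 1e6,
) -> list[PASInterval]:
    """Call PAS from the depth-normalised sum of all samples' 3'-end densities.

    Each sample track is scaled to counts per ``depth_scale`` reads, summed per
    strand; then per strand: the genome is tiled into non-overlapping
    ``window``-nt windows from coordinate 0, windows with summed signal
    strictly above ``min_signal`` are merged when adjacent, local signal maxima
    within each merged interval seed ``window``-nt intervals centred on the
    maxima, and one further recentre pass plus higher-signal-wins overlap
    resolution yields the final non-overlapping interval set.

    Summit ties on a plateau break to the 5'-most position in the direction of
    transcription.
    """
    if not tracks:
        return []
    chroms = {c: a.size for t in tracks for c, a in t.plus.items()}
    out: list[PASInterval] = []
    for strand in ("+", "-"):
        for chrom, n in chroms.items():
            total = np.zeros(n, dtype=np.float64)
            for t in tracks:
                lib = t.library_size
                if lib == 0:
                    continue
                total += t.strand(strand)[chrom] * (depth_scale / lib)
            out.extend(_call_strand(total, chrom, strand, window, min_signal))
    out.sort(key=lambda p: (p.chrom, p.start, p.strand))
    for i, p in enumerate(out):
        p.pas_id = f"PAS{i:05d}"
    return out


def _call_strand(signal: np.ndarray, chrom: str, strand: str,
                 window: int, min_signal: float) -> list[PASInterval]:
    n = signal.size
    ntiles = n // window
    if ntiles == 0:
        return []
    tiled = signal[: ntiles * window].reshape(ntiles, window).sum(axis=1)
    keep = np.flatnonzero(tiled > min_signal)
    if keep.size == 0:
        return []
    # merge runs of adjacent kept tiles into intervals
    merged: list[tuple[int, int]] = []
    run_start = keep[0]
    prev = keep[0]
    for k in keep[1:]:
        if k == prev + 1:
            prev = k
        else:
            merged.append((run_start * window, (prev + 1) * window))
            run_start = prev = k
    merged.append((run_start * window, (prev + 1) * window))

    # local maxima within each merged interval seed candidate 30-nt intervals
    candidates: list[int] = []
    for s, e in merged:
        candidates.extend(_local_maxima(signal, s, e, strand))
    intervals = {_centered(c, n, window) for c in candidates}

    # documented single re-iteration: recentre each interval at its own
    # maximum, then deduplicate
    recentred = set()
    for s, e in intervals:
        summit = _argmax_strandwise(signal, s, e, strand)
        recentred.add(_centered(summit, n, window))

    # residual overlaps: keep the higher-signal interval (greedy)
    scored = sorted(
        ((float(signal[s:e].sum()), s, e) for s, e in recentred),
        key=lambda x: (-x[0], x[1]),
    )
    taken: list[tuple[int, int]] = []
    final = []
    for score, s, e in scored:
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        summit = _argmax_strandwise(signal, s, e, strand)
        final.append(PASInterval(chrom, s, e, strand, summit, summed_signal=score))
    final.sort(key=lambda p: p.start)
    return final


def _local_maxima(signal: np.ndarray, s: int, e: int, strand: str) -> list[int]:
    """Positions of strict-plateau local maxima of ``signal[s:e]`` (one per plateau)."""
    seg = signal[s:e]
    out = []
    i = 0
    while i < seg.size:
        if seg[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < seg.size and seg[j + 1] == seg[i]:
            j += 1
        left_ok = i == 0 or seg[i - 1] < seg[i]
        right_ok = j == seg.size - 1 or seg[j + 1] < seg[i]
        if left_ok and right_ok:
            out.append(s + (i if strand == "+" else j))  # 5'-most of plateau
        i = j + 1
    return out


def _argmax_strandwise(signal: np.ndarray, s: int, e: int, strand: str) -> int:
    seg = signal[s:e]
    if strand == "+":
        return s + int(np.argmax(seg))
    return s + seg.size - 1 - int(np.argmax(seg[::-1]))


def _centered(summit: int, n: int, window: int) -> tuple[int, int]:
    half = window // 2
    s = min(max(0, summit - half), max(0, n - window))
    return s, s + window


# ---------------------------------------------------------------------------
# quantification

def quantify_pas(
    pas: list[PASInterval],
    tracks: list[End3Track],
    genes: list,
    extension_bp: int = 6000,
    filtered_reads: dict[str, int] | None = None,
) -> PASCountMatrix:
    """Count raw per-sample reads in each PAS and assign PAS to genes.

    A PAS belongs to the gene whose span extended ``extension_bp`` downstream
    contains its summit (same strand); ties go to the gene with the nearer
    annotated 3' end.  PAS in no extended span are retained as orphans and
    excluded from gene-level statistics.  ``filtered_reads`` (per-sample
    mask-removed totals) is stored alongside the background tally so read
    conservation can be asserted exactly.
    """
    gene_lookup = []
    for ag in genes:
        g = ag.gene if hasattr(ag, "gene") else ag
        lo, hi = g.extended_span(extension_bp)
        gene_lookup.append((g, lo, hi))

    counts = {}
    background = {}
    for t in tracks:
        col = []
        inside = 0
        for p in pas:
            c = int(t.strand(p.strand)[p.chrom][p.start:p.end].sum())
            col.append(c)
            inside += c
        counts[t.sample] = col
        background[t.sample] = t.library_size - inside

    meta_rows = []
    orphans = []
    for p in pas:
        hits = [
            (abs(p.summit - g.annotated_end), g.gene_id)
            for g, lo, hi in gene_lookup
            if g.chrom == p.chrom and g.strand == p.strand and lo <= p.summit < hi
        ]
        p.gene_id = min(hits)[1] if hits else None
        if p.gene_id is None:
            orphans.append(p.pas_id)
        meta_rows.append({
            "pas_id": p.pas_id, "chrom": p.chrom, "start": p.start, "end": p.end,
            "strand": p.strand, "summit": p.summit, "gene_id": p.gene_id,
            "summed_signal": p.summed_signal,
        })

    meta_cols = ["pas_id", "chrom", "start", "end", "strand", "summit",
                 "gene_id", "summed_signal"]
    meta = pd.DataFrame(meta_rows, columns=meta_cols).set_index("pas_id")
    # per-gene 5'->3' order index in transcription direction
    meta["order_index"] = pd.NA
    for gid, grp in meta[meta.gene_id.notna()].groupby("gene_id"):
        ascending = grp.strand.iloc[0] == "+"
        order = grp.summit.sort_values(ascending=ascending)
        meta.loc[order.index, "order_index"] = range(1, len(order) + 1)
    for p in pas:
        if p.gene_id is not None:
            p.order_index = int(meta.loc[p.pas_id, "order_index"])

    cmat = pd.DataFrame(counts, index=meta.index)
    for p in pas:
        p.counts = cmat.loc[p.pas_id].to_dict()
    return PASCountMatrix(cmat, meta, orphans, background)


def write_pas_bed(pas: list[PASInterval], path: str) -> None:
    """BED6 of called PAS; name is gene_id:order_index (or 'orphan')."""
    with open(path, "w") as fh:
        for p in sorted(pas, key=lambda q: (q.chrom, q.start)):
            name = f"{p.gene_id}:{p.order_index}" if p.gene_id else "orphan"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t"
                     f"{p.summed_signal:.1f}\t{p.strand}\n")
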