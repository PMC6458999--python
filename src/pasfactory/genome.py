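"""Gene annotation handling, analysis-set selection and gene-spacing analysis.

All coordinates are 0-based, half-open genomic intervals; GTF input (1-based,
closed) is converted on read.  Genes are gene-level union spans: multi-isoform
annotations are collapsed to one span per ``gene_id`` before any analysis.

The *analysis set* is the gene universe every downstream stage filters: genes
that (1) have at least one active polyadenylation site (PAS) within their span
extended 6 kb downstream, (2) overlap no other annotated gene on the same
strand, and (3) have a 3' end isolated by at least 6 kb from the next
same-strand annotated gene downstream.  The isolation requirement lets
strand-specific signal downstream of a gene be assigned to that gene
unambiguously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneModel",
    "AnalysisGene",
    "GeneDistance",
    "read_gtf_genes",
    "select_analysis_set",
    "downstream_distance",
    "compare_distance_groups",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene-level annotation record (union span over isoforms)."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start < 1:
            raise ValueError(f"{self.gene_id}: gene length must be >= 1")

    @property
    def tss(self) -> int:
        """Transcription start site (base coordinate)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def annotated_end(self) -> int:
        """Annotated 3' end (base coordinate)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def extended_span(self, downstream_bp: int = 6000) -> tuple[int, int]:
        """Half-open span extended ``downstream_bp`` in the direction of transcription."""
        if self.strand == "+":
            return self.start, self.end + downstream_bp
        return max(0, self.start - downstream_bp), self.end


@dataclass
class AnalysisGene:
    """A gene with its downstream-analysis eligibility flags and active PAS."""

    gene: GeneModel
    active_pas: list = field(default_factory=list)  # PASInterval objects
    effective_end: int | None = None  # maximum-signal PAS summit
    isolated_3prime: bool = False
    same_strand_overlap: bool = False
    in_analysis_set: bool = False

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def length_ge_5kb(self) -> bool:
        return self.gene.length > 5000

    def end_coordinate(self) -> int:
        """Effective 3' end: max-signal PAS summit if known, else annotated end."""
        return self.effective_end if self.effective_end is not None else self.gene.annotated_end


@dataclass(frozen=True)
class GeneDistance:
    gene_id: str
    distance_bp: float  # non-negative; math.inf if nothing downstream


def read_gtf_genes(path: str) -> list[GeneModel]:
    """Read gene feature rows from a GENCODE-dialect GTF, collapsing to union spans.

    Only ``gene`` feature rows are used; 1-based closed GTF coordinates are
    converted to 0-based half-open.  Biotype is reduced to
    protein_coding / non_coding.
    """
    spans: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = _parse_gtf_attrs(f[8])
            gid = attrs.get("gene_id", f"{f[0]}:{f[3]}")
            bt = attrs.get("gene_type", attrs.get("gene_biotype", "protein_coding"))
            bt = "protein_coding" if bt == "protein_coding" else "non_coding"
            start, end = int(f[3]) - 1, int(f[4])
            rec = spans.setdefault(gid, [f[0], start, end, f[6], bt])
            rec[1] = min(rec[1], start)
            rec[2] = max(rec[2], end)
    return [
        GeneModel(gid, chrom, start, end, strand, bt)
        for gid, (chrom, start, end, strand, bt) in spans.items()
    ]


def _parse_gtf_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        kv = part.split(None, 1)
        if len(kv) == 2:
            out[kv[0]] = kv[1].strip().strip('"')
    return out


def select_analysis_set(
    genes: list[GeneModel],
    pas_catalog: list,
    isolation_bp: int = 6000,
    pas_extension_bp: int = 6000,
) -> list[AnalysisGene]:
    """Flag every gene for analysis-set membership.

    A gene is in the analysis set iff it has >= 1 active PAS (a called PAS whose
    summit lies within the gene span extended ``pas_extension_bp`` downstream,
    same strand), overlaps no annotated gene on the same strand, and its
    annotated 3' end is >= ``isolation_bp`` from the next same-strand annotated
    gene downstream.

    Raises ``ValueError`` for a PAS on a chromosome absent from the annotation.
    """
    known_chroms = {g.chrom for g in genes}
    for p in pas_catalog:
        if p.chrom not in known_chroms:
            raise ValueError(
                f"PAS interval {p.chrom}:{p.start}-{p.end}({p.strand}) "
                f"on unknown chromosome {p.chrom!r}"
            )

    out = []
    for g in genes:
        lo, hi = g.extended_span(pas_extension_bp)
        active = [
            p for p in pas_catalog
            if p.chrom == g.chrom and p.strand == g.strand and lo <= p.summit < hi
        ]
        active.sort(key=lambda p: p.summit, reverse=(g.strand == "-"))  # 5'->3'

        overlap = any(
            o is not g and o.chrom == g.chrom and o.strand == g.strand
            and o.start < g.end and g.start < o.end
            for o in genes
        )

        # distance from the 3' end to the next same-strand gene downstream
        iso_dist = math.inf
        for o in genes:
            if o is g or o.chrom != g.chrom or o.strand != g.strand:
                continue
            if g.strand == "+":
                d = o.start - g.end
            else:
                d = g.start - o.end
            if d >= 0:
                iso_dist = min(iso_dist, d)

        isolated = iso_dist >= isolation_bp
        max_pas = max(active, key=lambda p: p.total_signal(), default=None) if active else None
        out.append(
            AnalysisGene(
                gene=g,
                active_pas=active,
                effective_end=(max_pas.summit if max_pas is not None else None),
                isolated_3prime=isolated,
                same_strand_overlap=overlap,
                in_analysis_set=bool(active) and not overlap and isolated,
            )
        )
    return out


def downstream_distance(gene: GeneModel, all_genes: list[GeneModel]) -> GeneDistance:
    """Distance from a gene's 3' end to the nearest downstream annotated gene end.

    "Gene end" means both the TSS and the 3' end of every *other* gene, on
    either strand; downstream is in the query's direction of transcription.
    A gene end overlapping the query's 3' end gives distance 0; if no end lies
    downstream the distance is infinite (chromosome end).
    """
    q = gene.annotated_end
    best = math.inf
    for o in all_genes:
        if o.gene_id == gene.gene_id or o.chrom != gene.chrom:
            continue
        for endpoint in (o.tss, o.annotated_end):
            d = (endpoint - q) if gene.strand == "+" else (q - endpoint)
            if d >= 0:
                best = min(best, d)
    return GeneDistance(gene.gene_id, best)


def compare_distance_groups(groups: dict[str, list]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between gene-spacing groups.

    Returns one row per ordered pair of group labels with the U statistic,
    two-sided p-value, and per-group median/quartiles (boxplot statistics).
    Groups of size < 2 are rejected.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    vals = {}
    for label, ds in groups.items():
        x = np.asarray([d.distance_bp if not isinstance(d, (int, float)) else d for d in ds], float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 finite values")
        vals[label] = x
    labels = list(vals)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            u, p = stats.mannwhitneyu(vals[a], vals[b], alternative="two-sided")
            rows.append({
                "group_a": a, "group_b": b, "U": u, "p": p,
                "median_a": float(np.median(vals[a])),
                "median_b": float(np.median(vals[b])),
                "q1_a": float(np.percentile(vals[a], 25)),
                "q3_a": float(np.percentile(vals[a], 75)),
                "q1_b": float(np.percentile(vals[b], 25)),
                "q3_b": float(np.percentile(vals[b], 75)),
            })
    return pd.DataFrame(rows)
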