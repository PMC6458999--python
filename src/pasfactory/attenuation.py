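"""Premature-termination / premature-CPA attenuation calling and termination
window quantification.

Attenuation is the down-regulation of a gene's full-length output by premature
cleavage/polyadenylation (CPA) or premature termination inside the gene body.
Depleting a termination factor relieves it, so an attenuated gene is one that
is significantly *upregulated* on depletion and additionally shows either

* premature termination: a more than 2-fold drop in mean intragenic
  nascent-transcription signal (the first 20 of 25 equal gene-body bins,
  control over depleted, both tracks depth-normalised), or
* premature CPA: at least one PAS other than the gene's major PAS whose usage
  decreases significantly on depletion (padj < 0.1 in the differential-usage
  test); a fold-change variant replaces the significance gate with a
  >= 2-fold drop in mean depth-normalised PAS signal, for datasets too
  variable for per-PAS significance.

The attenuated set is the union of the two criteria gated on upregulation.

The module also groups multi-PAS genes by the position of their major PAS
(the two strongest PAS within 2-fold of each other and >= 2 kb apart;
proximal-major when the 5' PAS is strictly stronger) and quantifies the
termination window: 50-bp binned signal from the gene's effective 3' end to
+10 kb downstream, with the argmax offset locating the termination peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apa_stats import DEResult, UsageTestResult
from .pas_calling import PASCountMatrix
from .signal_tracks import SignalTrack, depth_normalize

__all__ = [
    "AttenuationCall",
    "MajorPASGroup",
    "TerminationProfile",
    "intragenic_signal_ratio",
    "call_attenuated",
    "call_attenuated_foldchange_variant",
    "group_major_pas",
    "termination_window",
    "attenuation_summary",
]


@dataclass
class AttenuationCall:
    gene_id: str
    upregulated: bool
    premature_termination: bool
    premature_cpa: bool
    intragenic_ratio: float = np.nan
    decreased_pas_ids: list[str] = field(default_factory=list)

    @property
    def attenuated(self) -> bool:
        return self.upregulated and (self.premature_termination or self.premature_cpa)


@dataclass
class MajorPASGroup:
    gene_id: str
    group: str  # major_proximal | major_distal | excluded
    pas1_signal: float = np.nan  # proximal of the two strongest
    pas2_signal: float = np.nan  # distal of the two strongest
    separation_bp: int = 0
    exclusion_reason: str | None = None


@dataclass
class TerminationProfile:
    gene_id: str
    profile: np.ndarray  # 50-bp bins, effective end -> +span
    argmax_offset: int | None  # bp downstream of the 3' end; None if no signal
    truncated: bool = False


def intragenic_signal_ratio(
    track_control: SignalTrack,
    track_treated: SignalTrack,
    gene,
    n_bins: int = 25,
    used_bins: int = 20,
) -> float:
    """Control/treated ratio of mean intragenic signal over the 5' gene body.

    The gene body (TSS to effective 3' end) is divided into ``n_bins`` equal
    bins ordered in the direction of transcription; the mean over the first
    ``used_bins`` excludes the terminal region around the PAS itself.  Both
    tracks are depth-normalised before the ratio.  A zero treated mean yields
    ``inf``.
    """
    c = _body_mean(depth_normalize(track_control), gene, n_bins, used_bins)
    t = _body_mean(depth_normalize(track_treated), gene, n_bins, used_bins)
    if t == 0:
        return np.inf
    return c / t


def _body_mean(track: SignalTrack, ag, n_bins: int, used_bins: int) -> float:
    g = ag.gene if hasattr(ag, "gene") else ag
    end = ag.end_coordinate() if hasattr(ag, "end_coordinate") else g.annotated_end
    sig = track.values[g.chrom]
    if track.bin_size != 1:
        sig = np.repeat(sig / track.bin_size, track.bin_size)
    lo, hi = (g.tss, end + 1) if g.strand == "+" else (end, g.tss + 1)
    lo, hi = max(0, lo), min(sig.size, hi)
    edges = np.linspace(lo, hi, n_bins + 1).astype(int)
    means = np.array([float(sig[edges[i]: edges[i + 1]].mean()) for i in range(n_bins)])
    if g.strand == "-":
        means = means[::-1]
    return float(means[:used_bins].mean())


def _major_pas(matrix: PASCountMatrix, control_samples: list[str]) -> dict[str, str]:
    """Strongest pooled-control PAS per gene."""
    pooled = matrix.counts[control_samples].sum(axis=1)
    out = {}
    for gid, grp in matrix.meta[matrix.meta.gene_id.notna()].groupby("gene_id"):
        out[gid] = pooled.loc[grp.index].idxmax()
    return out


def call_attenuated(
    de: list[DEResult],
    ratios: dict[str, float],
    usage: list[UsageTestResult],
    matrix: PASCountMatrix,
    design: dict[str, str],
    control: str = "control",
    de_alpha: float = 0.05,
    cpa_alpha: float = 0.1,
    min_ratio: float = 2.0,
    gene_universe: set[str] | None = None,
) -> list[AttenuationCall]:
    """Call attenuated genes: upregulated AND (termination-loss OR PAS-loss).

    ``ratios`` maps gene_id to the control/treated intragenic signal ratio.
    The CPA criterion requires a non-major PAS (major = strongest pooled
    control-condition PAS) with usage padj < ``cpa_alpha`` and a decreased
    usage fraction in the treated condition.
    """
    ctl_samples = [s for s in matrix.samples if design.get(s) == control]
    major = _major_pas(matrix, ctl_samples)
    de_by_gene = {r.gene_id: r for r in de}
    usage_by_gene: dict[str, list[UsageTestResult]] = {}
    for r in usage:
        usage_by_gene.setdefault(r.gene_id, []).append(r)

    genes = gene_universe if gene_universe is not None else set(de_by_gene)
    calls = []
    for gid in sorted(genes):
        der = de_by_gene.get(gid)
        up = der is not None and np.isfinite(der.padj) \
            and der.log2fc > 0 and der.padj < de_alpha
        ratio = ratios.get(gid, np.nan)
        term = bool(np.isfinite(ratio) and ratio > min_ratio) or ratio == np.inf
        dec = [
            r.pas_id for r in usage_by_gene.get(gid, [])
            if r.testable and np.isfinite(r.padj) and r.padj < cpa_alpha
            and r.usage_treated < r.usage_control and r.pas_id != major.get(gid)
        ]
        calls.append(AttenuationCall(gid, up, term, bool(dec), ratio, dec))
    return calls


def call_attenuated_foldchange_variant(
    de: list[DEResult],
    ratios: dict[str, float],
    matrix: PASCountMatrix,
    design: dict[str, str],
    control: str = "control",
    treated: str = "treated",
    min_fold: float = 2.0,
    de_alpha: float = 0.05,
    min_ratio: float = 2.0,
    gene_universe: set[str] | None = None,
) -> list[AttenuationCall]:
    """Fold-change variant of the CPA gate, for high-variability datasets.

    A non-major PAS qualifies when its mean depth-normalised count drops at
    least ``min_fold``-fold between condition means; a zero treated mean is
    handled with a +0.5 continuity correction.  The upregulation and
    termination gates are unchanged.
    """
    samples = [s for s in matrix.samples if s in design]
    ctl = [s for s in samples if design[s] == control]
    trt = [s for s in samples if design[s] == treated]
    libs = matrix.counts[samples].sum(axis=0) + pd.Series(
        matrix.background_reads)[samples]
    norm = matrix.counts[samples] * (1e6 / libs)
    major = _major_pas(matrix, ctl)
    de_by_gene = {r.gene_id: r for r in de}

    genes = gene_universe if gene_universe is not None else set(de_by_gene)
    calls = []
    meta = matrix.meta[matrix.meta.gene_id.notna()]
    for gid in sorted(genes):
        der = de_by_gene.get(gid)
        up = der is not None and np.isfinite(der.padj) \
            and der.log2fc > 0 and der.padj < de_alpha
        ratio = ratios.get(gid, np.nan)
        term = bool(np.isfinite(ratio) and ratio > min_ratio) or ratio == np.inf
        dec = []
        idx = meta.index[meta.gene_id == gid]
        for pas_id in idx:
            if pas_id == major.get(gid):
                continue
            m_c = float(norm.loc[pas_id, ctl].mean())
            m_t = float(norm.loc[pas_id, trt].mean())
            if m_t == 0:
                m_c, m_t = m_c + 0.5, 0.5
            if m_t > 0 and m_c / m_t >= min_fold:
                dec.append(pas_id)
        calls.append(AttenuationCall(gid, up, term, bool(dec), ratio, dec))
    return calls


def attenuation_summary(calls: list[AttenuationCall]) -> dict[str, int]:
    """Counts per criterion with the union/overlap bookkeeping."""
    att = [c for c in calls if c.attenuated]
    term = [c for c in att if c.premature_termination]
    cpa = [c for c in att if c.premature_cpa]
    both = [c for c in att if c.premature_termination and c.premature_cpa]
    return {
        "attenuated": len(att),
        "premature_termination": len(term),
        "premature_cpa": len(cpa),
        "overlap": len(both),
    }


def group_major_pas(
    matrix: PASCountMatrix,
    design: dict[str, str] | None = None,
    max_ratio: float = 2.0,
    min_separation: int = 2000,
) -> list[MajorPASGroup]:
    """Group multi-PAS genes by whether the major PAS is proximal or distal.

    Signals are pooled depth-normalised counts over all samples.  The two
    strongest PAS are kept only when their signals differ by at most
    ``max_ratio``-fold and their summits are >= ``min_separation`` bp apart;
    PAS1 is the more 5' (proximal) of the pair.  PAS1 > PAS2 is
    proximal-major; PAS1 <= PAS2 (ties included) is distal-major.
    """
    samples = matrix.samples if design is None else \
        [s for s in matrix.samples if s in design]
    libs = matrix.counts[samples].sum(axis=0) + pd.Series(
        matrix.background_reads)[samples]
    pooled = (matrix.counts[samples] * (1e6 / libs)).sum(axis=1)

    out = []
    meta = matrix.meta[matrix.meta.gene_id.notna()]
    for gid, grp in meta.groupby("gene_id"):
        if len(grp) < 2:
            out.append(MajorPASGroup(gid, "excluded", exclusion_reason="single_pas"))
            continue
        top2 = pooled.loc[grp.index].nlargest(2)
        (id_a, sig_a), (id_b, sig_b) = top2.items()
        if min(sig_a, sig_b) <= 0 or max(sig_a, sig_b) / min(sig_a, sig_b) > max_ratio:
            out.append(MajorPASGroup(gid, "excluded", exclusion_reason="ratio"))
            continue
        sum_a, sum_b = grp.loc[id_a, "summit"], grp.loc[id_b, "summit"]
        sep = abs(int(sum_a) - int(sum_b))
        if sep < min_separation:
            out.append(MajorPASGroup(gid, "excluded", exclusion_reason="separation"))
            continue
        strand = grp.strand.iloc[0]
        a_is_prox = (sum_a < sum_b) if strand == "+" else (sum_a > sum_b)
        p1, p2 = (sig_a, sig_b) if a_is_prox else (sig_b, sig_a)
        group = "major_proximal" if p1 > p2 else "major_distal"
        out.append(MajorPASGroup(gid, group, float(p1), float(p2), sep))
    return out


def termination_window(
    track: SignalTrack,
    gene,
    span_bp: int = 10000,
    bin_size: int = 50,
) -> TerminationProfile:
    """Binned downstream signal profile and termination-peak offset.

    The profile runs from the gene's effective 3' end to ``span_bp``
    downstream (strand-aware) in ``bin_size`` bins; the argmax offset is the
    centre of the strongest bin.  A gene within ``span_bp`` of the chromosome
    end is truncated and flagged; an all-zero window has no defined peak.
    """
    g = gene.gene if hasattr(gene, "gene") else gene
    end = gene.end_coordinate() if hasattr(gene, "end_coordinate") else g.annotated_end
    sig = track.values[g.chrom]
    if track.bin_size != 1:
        sig = np.repeat(sig / track.bin_size, track.bin_size)
    n = span_bp
    window = np.full(n, np.nan)
    if g.strand == "+":
        lo, hi = end, min(sig.size, end + n)
        truncated = hi - lo < n
        if hi > lo:
            window[: hi - lo] = sig[lo:hi]
    else:
        lo, hi = max(0, end - n + 1), end + 1
        truncated = hi - lo < n
        if hi > lo:
            window[: hi - lo] = sig[lo:hi][::-1]
    nb = n // bin_size
    prof = np.nanmean(window[: nb * bin_size].reshape(nb, bin_size), axis=1)
    valid = np.nan_to_num(prof, nan=0.0)
    if valid.max() <= 0:
        arg = None
    else:
        arg = int(np.argmax(valid)) * bin_size  # offset of the peak bin start
    return TerminationProfile(g.gene_id, prof, arg, truncated)
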