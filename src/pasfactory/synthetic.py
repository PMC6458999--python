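"""Synthetic genome, 3'-end read, and signal-track generator with ground truth.

Every pipeline stage is testable without external downloads: this module
builds a toy chromosome carrying non-overlapping genes with 1-3 planted PAS,
embeds A-rich decoy stretches that would be miscalled as PAS were it not for
the internal-priming mask, simulates negative-binomial replicate counts at
each PAS (with planted usage shifts, fold-changes, and attenuation events in
the treated condition), and synthesises nascent-transcription and ChIP-like
signal tracks.  The ``TruthLedger`` records everything planted so recovery,
precision/recall and error-control properties can be scored exactly.

Everything is deterministic under ``(seed, config)``.

What the generator emulates, and what it does not: read counts are
gamma-Poisson (negative binomial) around planted means with uniform +/-5 nt
positional jitter, decoy 3' ends arise only inside gene bodies at planted
A-runs, and the background genome is scrubbed of accidental A/T-rich loci so
mask efficacy is measurable against the ledger alone.  There is no
sequencing-error model, no mappability structure, and no overlapping-gene
ambiguity — real annotations are messier on all three counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GeneModel
from .pas_calling import End3Track, _rich_mask
from .signal_tracks import SignalTrack

__all__ = [
    "SimConfig",
    "GeneTruth",
    "TruthLedger",
    "simulate_genome",
    "simulate_end3_reads",
    "simulate_signal_tracks",
    "simulate_mnet_tracks",
    "simulate_chip_tracks",
    "simulate_global_change_pair",
    "write_fasta",
    "write_gtf",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the simulated experiment.

    Defaults describe a two-condition (control vs depletion) design with four
    biological replicates per condition on a single ~6.5-Mb chromosome of 200
    genes, matching the scale at which every recovery property is scored.
    """

    n_genes: int = 200
    chrom: str = "chrSim"
    chrom_length: int = 6_500_000
    gene_min_bp: int = 6_000
    gene_max_bp: int = 30_000
    min_gap_bp: int = 7_000      # > 6-kb isolation criterion by construction
    max_gap_bp: int = 12_000
    noncoding_fraction: float = 0.1
    pas_per_gene_probs: tuple = (0.25, 0.45, 0.30)  # P(1), P(2), P(3)
    min_pas_spacing: int = 2_500

    replicates: int = 4
    conditions: tuple = ("control", "treated")
    mean_expression: float = 500.0   # reads per gene per replicate (median)
    expression_sigma: float = 0.3    # lognormal spread of gene expression
    nb_dispersion: float = 0.05
    library_factor_range: tuple = (0.8, 1.25)
    end_jitter: int = 5
    background_rate: float = 0.02    # uniform body reads, fraction of gene mean

    decoy_rate: float = 0.5          # expected decoys per gene
    decoy_strength: float = 0.15     # decoy reads as a fraction of gene mean
    decoy_run_length: int = 8

    n_shifted: int = 30
    shift_delta: float = 0.3         # planted usage-fraction change
    shift_distal_fraction: float = 1.0
    n_attenuated: int = 30
    attenuation_ratio: float = 3.0   # target control/treated intragenic ratio
    cpa_fold: float = 4.0            # usage drop of the premature PAS
    attenuation_fc: float = 2.5      # upregulation of attenuated genes
    n_de_up: int = 10
    n_de_down: int = 10
    de_fold: float = 4.0

    # signal tracks
    signal_baseline: float = 0.05    # nascent reads per base per unit expression/500
    term_peak_offset: int = 2_000    # termination peak position downstream of PAS
    term_peak_width: int = 500
    term_peak_reads: float = 400.0   # reads in the post-PAS termination peak
    signal_replicates: int = 2

    # ChIP
    chip_bin: int = 50
    chip_background: float = 10.0    # Poisson reads per bin
    chip_fold: float = 10.0
    n_shared_regions: int = 30
    n_unique_regions: int = 10
    region_width: int = 2_000
    spike_in_fraction: float = 0.05

    seed: int = 0


@dataclass
class GeneTruth:
    gene_id: str
    pas_summits: list[int]                 # 5'->3' in transcription direction
    expression: float
    usage: dict[str, np.ndarray]           # condition -> fractions (sum 1)
    fc: dict[str, float]                   # condition -> fold-change vs base
    role: str = "null"                     # null|shifted|attenuated|de_up|de_down
    mechanism: str | None = None           # termination|cpa|both (attenuated)
    decoys: list[int] = field(default_factory=list)


@dataclass
class TruthLedger:
    config: SimConfig
    genes: dict[str, GeneTruth]
    decoy_sites: list[tuple[int, str]]     # (position, strand)
    shifted_genes: dict[str, str]          # gene_id -> distal|proximal
    attenuated_genes: dict[str, str]       # gene_id -> mechanism
    de_genes: dict[str, float]             # gene_id -> fold (treated/control)
    enriched_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    spike_in_fraction: dict[str, float] = field(default_factory=dict)

    def planted_pas(self) -> list[tuple[str, int]]:
        return [(gid, s) for gid, gt in self.genes.items() for s in gt.pas_summits]


# ---------------------------------------------------------------------------
# genome

def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel], TruthLedger]:
    rng = np.random.default_rng(config.seed)
    genes, truths = _place_genes(config, rng)
    _assign_roles(config, rng, genes, truths)
    seq, decoys = _build_sequence(config, rng, genes, truths)
    ledger = TruthLedger(
        config=config,
        genes={t.gene_id: t for t in truths},
        decoy_sites=decoys,
        shifted_genes={t.gene_id: ("distal" if t.usage["treated"][-1] > t.usage["control"][-1]
                                   else "proximal")
                       for t in truths if t.role == "shifted"},
        attenuated_genes={t.gene_id: t.mechanism for t in truths if t.role == "attenuated"},
        de_genes={t.gene_id: t.fc["treated"] for t in truths
                  if t.role in ("de_up", "de_down", "attenuated")},
    )
    return {config.chrom: seq}, genes, ledger


def _place_genes(config: SimConfig, rng) -> tuple[list[GeneModel], list[GeneTruth]]:
    genes, truths = [], []
    cursor = 20_000
    for i in range(config.n_genes):
        length = int(rng.integers(config.gene_min_bp, config.gene_max_bp + 1))
        if cursor + length > config.chrom_length - 20_000:
            raise ValueError(
                f"cannot place {config.n_genes} genes on a {config.chrom_length}-bp "
                f"chromosome without violating the isolation gap; placed {i}")
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "non_coding" if rng.random() < config.noncoding_fraction \
            else "protein_coding"
        gid = f"G{i:04d}"
        start, end = cursor, cursor + length
        n_pas = 1 + int(rng.choice(3, p=config.pas_per_gene_probs))
        summits = _plant_summits(rng, start, end, strand, n_pas, config.min_pas_spacing)

        expr = float(config.mean_expression
                     * np.exp(rng.normal(0.0, config.expression_sigma)))
        usage = _dirichlet_usage(rng, len(summits))
        truths.append(GeneTruth(
            gid, summits, expr,
            usage={c: usage.copy() for c in config.conditions},
            fc={c: 1.0 for c in config.conditions},
        ))
        genes.append(GeneModel(gid, config.chrom, start, end, strand, biotype))
        cursor = end + int(rng.integers(config.min_gap_bp, config.max_gap_bp + 1))
    return genes, truths


def _plant_summits(rng, start: int, end: int, strand: str, n_pas: int,
                   spacing: int) -> list[int]:
    """Summits 5'->3'; the most 3' summit sits ~200 bp inside the annotated end."""
    length = end - start
    while n_pas > 1 and 1_300 + (n_pas - 1) * spacing + 400 > length:
        n_pas -= 1
    offsets = [200]  # distance from the 3' end
    for _ in range(n_pas - 1):
        nxt = offsets[-1] + int(rng.integers(spacing, spacing + 2_000))
        if nxt > length - 1_300:  # keep every summit well inside the span
            nxt = offsets[-1] + spacing
            if nxt > length - 1_300:
                break
        offsets.append(nxt)
    offsets = offsets[::-1]  # 5'->3'
    if strand == "+":
        return [end - 1 - o for o in offsets]
    return [start + o for o in offsets]


def _dirichlet_usage(rng, k: int) -> np.ndarray:
    if k == 1:
        return np.array([1.0])
    u = rng.dirichlet(np.full(k, 8.0))  # moderately even usage
    return np.clip(u, 0.08, None) / np.clip(u, 0.08, None).sum()


def _assign_roles(config: SimConfig, rng, genes: list[GeneModel],
                  truths: list[GeneTruth]) -> None:
    by_id = {g.gene_id: g for g in genes}
    multi = [t for t in truths
             if len(t.pas_summits) >= 2
             and by_id[t.gene_id].biotype == "protein_coding"
             and by_id[t.gene_id].length > 5_000]
    rng.shuffle(multi)
    need = config.n_shifted + config.n_attenuated + config.n_de_up + config.n_de_down
    if len(multi) < need:
        raise ValueError(f"only {len(multi)} eligible multi-PAS genes for {need} roles")
    it = iter(multi)

    for j in range(config.n_shifted):
        t = next(it)
        t.role = "shifted"
        distal = rng.random() < config.shift_distal_fraction
        t.usage["control"] = _shift_base_usage(len(t.pas_summits), distal)
        t.usage["treated"] = _apply_shift(t.usage["control"], config.shift_delta, distal)

    mechanisms = (["termination", "cpa", "both"] * config.n_attenuated)[: config.n_attenuated]
    for mech in mechanisms:
        t = next(it)
        t.role, t.mechanism = "attenuated", mech
        t.fc["treated"] = config.attenuation_fc
        if mech in ("cpa", "both"):
            # premature (most 5') PAS prominent in control but never the major
            # one — the full-length (most 3') PAS stays strongest — and it
            # collapses cpa_fold-fold on depletion
            k = len(t.pas_summits)
            u = np.empty(k)
            u[0], u[-1] = 0.35, 0.50
            if k > 2:
                u[1:-1] = 0.15 / (k - 2)
            t.usage["control"] = u / u.sum()
            v = u.copy()
            v[0] = u[0] / config.cpa_fold
            v[1:] *= (1 - v[0]) / v[1:].sum()
            t.usage["treated"] = v / v.sum()

    for _ in range(config.n_de_up):
        t = next(it)
        t.role, t.fc["treated"] = "de_up", config.de_fold
    for _ in range(config.n_de_down):
        t = next(it)
        t.role, t.fc["treated"] = "de_down", 1.0 / config.de_fold


def _shift_base_usage(k: int, distal_shift: bool) -> np.ndarray:
    """Control usage leaving room for the planted delta on the last PAS."""
    u = np.full(k, 0.2 / max(k - 2, 1)) if k > 2 else np.zeros(k)
    if k == 2:
        u = np.array([0.65, 0.35]) if distal_shift else np.array([0.35, 0.65])
    else:
        u[0], u[-1] = (0.55, 0.25) if distal_shift else (0.25, 0.55)
    return u / u.sum()


def _apply_shift(u: np.ndarray, delta: float, distal: bool) -> np.ndarray:
    v = u.copy()
    if distal:
        v[-1] += delta
        v[0] -= delta
    else:
        v[-1] -= delta
        v[0] += delta
    v = np.clip(v, 0.02, None)
    return v / v.sum()


def _build_sequence(config: SimConfig, rng, genes: list[GeneModel],
                    truths: list[GeneTruth]) -> tuple[str, list[tuple[int, str]]]:
    n = config.chrom_length
    seq = rng.choice(BASES, size=n)

    # plant decoy A-runs (T-runs for minus-strand genes) inside gene bodies,
    # well away from planted PAS so the mask's unmask windows never cover them
    decoys: list[tuple[int, str]] = []
    by_id = {t.gene_id: t for t in truths}
    run = config.decoy_run_length
    for g in genes:
        t = by_id[g.gene_id]
        k = rng.poisson(config.decoy_rate)
        tries = 0
        while len(t.decoys) < k and tries < 50:
            tries += 1
            pos = int(rng.integers(g.start + 500, g.end - 500 - run))
            if min((abs(pos - s) for s in t.pas_summits), default=1e9) < 600:
                continue
            if any(abs(pos - d) < 200 for d in t.decoys):
                continue
            t.decoys.append(pos)
            decoys.append((pos, g.strand))
            base = ord("A") if g.strand == "+" else ord("T")
            seq[pos: pos + run] = base

    # scrub accidental A/T-rich loci everywhere except the planted decoys,
    # so the only maskable positions are the ones the ledger knows about
    protected = np.zeros(n, dtype=bool)
    for pos, _ in decoys:
        protected[max(0, pos - 12): pos + run + 12] = True
    for _ in range(6):
        dirty = False
        for base, other in ((ord("A"), ord("C")), (ord("T"), ord("G"))):
            m = _rich_mask(seq == base, 6, 10, 6) & ~protected
            hit = m & (seq == base)
            if hit.any():
                dirty = True
                idx = np.flatnonzero(hit)
                # break runs/windows sparsely rather than flattening them
                seq[idx[::2]] = other
        if not dirty:
            break
    return seq.tobytes().decode("ascii"), decoys


# ---------------------------------------------------------------------------
# 3'-end reads

def simulate_end3_reads(
    genome: dict[str, str],
    genes: list[GeneModel],
    ledger: TruthLedger,
    config: SimConfig | None = None,
) -> tuple[list[End3Track], dict[str, str]]:
    """Per-replicate 3'-end count tracks plus the sample->condition design.

    PAS counts are NegBin(mean = expression x usage x fold-change x library
    factor, dispersion) with uniform +/- ``end_jitter`` positional noise;
    decoy reads at planted A-runs scale with the gene's local transcription;
    a small uniform gene-body background emulates stray priming.
    """
    config = config or ledger.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    by_id = {g.gene_id: g for g in genes}
    tracks, design = [], {}
    disp = config.nb_dispersion
    for cond in config.conditions:
        for r in range(config.replicates):
            sample = f"{cond}_rep{r + 1}"
            design[sample] = cond
            lib = float(rng.uniform(*config.library_factor_range))
            track = End3Track.zeros(chrom_sizes, sample=sample, condition=cond)
            arr = {"+": track.plus[config.chrom], "-": track.minus[config.chrom]}
            for gid, t in ledger.genes.items():
                g = by_id[gid]
                gmean = t.expression * t.fc[cond] * lib
                for summit, frac in zip(t.pas_summits, t.usage[cond]):
                    c = _nb(rng, gmean * frac, disp)
                    if c:
                        pos = summit + rng.integers(-config.end_jitter,
                                                    config.end_jitter + 1, size=c)
                        np.add.at(arr[g.strand], np.clip(pos, 0, len(arr[g.strand]) - 1), 1)
                for dpos in t.decoys:
                    c = rng.poisson(gmean * config.decoy_strength / max(len(t.decoys), 1))
                    if c:
                        pos = dpos + rng.integers(0, config.decoy_run_length, size=c)
                        np.add.at(arr[g.strand], pos, 1)
                c = rng.poisson(gmean * config.background_rate)
                if c:
                    pos = rng.integers(g.start, g.end, size=c)
                    np.add.at(arr[g.strand], pos, 1)
            tracks.append(track)
    return tracks, design


def _nb(rng, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 1e-12:
        return int(rng.poisson(mean))
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return int(rng.poisson(lam))


def simulate_count_matrix(
    n_genes: int = 500,
    pas_per_gene: int = 2,
    replicates: int = 4,
    mean_expression: float = 500.0,
    dispersion: float = 0.05,
    usage_delta: float = 0.0,
    shifted_fraction: float = 0.0,
    de_fold: float = 1.0,
    de_fraction: float = 0.0,
    seed: int = 0,
):
    """PAS count matrix drawn directly at the count level (no genome).

    A fast harness for statistical calibration studies of the usage and DE
    tests: every gene carries ``pas_per_gene`` PAS with Dirichlet usage,
    NegBin(mean x usage, dispersion) replicate counts, and optional planted
    distal usage shifts (first ``shifted_fraction`` of genes, proximal usage
    down by ``usage_delta``) and fold-changes (next ``de_fraction`` of genes).
    Returns ``(PASCountMatrix, design, shifted_ids, de_ids)``.
    """
    import pandas as pd

    from .pas_calling import PASCountMatrix

    rng = np.random.default_rng(seed)
    samples = [f"{c}_rep{r + 1}" for c in ("control", "treated")
               for r in range(replicates)]
    design = {s: s.split("_")[0] for s in samples}
    n_shift = int(round(n_genes * shifted_fraction))
    n_de = int(round(n_genes * de_fraction))
    rows, meta_rows = [], []
    shifted_ids, de_ids = [], []
    pos = 0
    for i in range(n_genes):
        gid = f"G{i:04d}"
        u = _dirichlet_usage(rng, pas_per_gene)
        u_trt = u.copy()
        fc = 1.0
        if i < n_shift:
            shifted_ids.append(gid)
            u = _shift_base_usage(pas_per_gene, True)
            u_trt = _apply_shift(u, usage_delta, True)
        elif i < n_shift + n_de:
            de_ids.append(gid)
            fc = de_fold
        expr = mean_expression * np.exp(rng.normal(0, 0.3))
        for k in range(pas_per_gene):
            counts = []
            for s in samples:
                m = expr * (fc if design[s] == "treated" else 1.0)
                frac = (u_trt if design[s] == "treated" else u)[k]
                counts.append(_nb(rng, m * frac, dispersion))
            pid = f"PAS{i:04d}_{k}"
            rows.append(counts)
            meta_rows.append({"pas_id": pid, "chrom": "chrSim", "start": pos,
                              "end": pos + 30, "strand": "+", "summit": pos + 15,
                              "gene_id": gid, "summed_signal": float(sum(counts)),
                              "order_index": k + 1})
            pos += 3000
    meta = pd.DataFrame(meta_rows).set_index("pas_id")
    cmat = pd.DataFrame(rows, index=meta.index, columns=samples)
    background = {s: 0 for s in samples}
    return PASCountMatrix(cmat, meta, [], background), design, shifted_ids, de_ids


# ---------------------------------------------------------------------------
# signal tracks

def simulate_mnet_tracks(
    genes: list[GeneModel],
    ledger: TruthLedger,
    config: SimConfig | None = None,
) -> dict[str, list[SignalTrack]]:
    """Nascent 3'-end (termination-marking) tracks per condition.

    Signal density is a small gene-body baseline proportional to expression,
    plus a Gaussian termination peak centred ``term_peak_offset`` downstream
    of the most 3' PAS, plus — for attenuated genes in the control condition
    only — an intragenic termination peak sized so the expected
    control/treated mean over the 5' four-fifths of the body equals the
    configured attenuation ratio.  Per-base counts are Poisson.
    """
    config = config or ledger.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.chrom_length
    out: dict[str, list[SignalTrack]] = {}
    for cond in config.conditions:
        lam = np.zeros(n)
        for g in genes:
            t = ledger.genes[g.gene_id]
            scale = t.expression / 500.0
            base = config.signal_baseline * scale
            lam[g.start: g.end] += base
            # termination peak downstream of the most 3' PAS
            end3 = t.pas_summits[-1]
            center = end3 + config.term_peak_offset if g.strand == "+" \
                else end3 - config.term_peak_offset
            _add_gauss(lam, center, config.term_peak_width,
                       config.term_peak_reads * scale * t.fc[cond])
            if (t.role == "attenuated" and cond == "control"
                    and t.mechanism in ("termination", "both")):
                # premature termination peak 5' of the first PAS, so it lies
                # inside the measured gene body whichever PAS carries the most
                # signal; area sized so E[ctrl body mean] / E[trt] >= R
                L = g.length
                prox = t.pas_summits[0]
                d_prox = abs(prox - g.tss)
                center = g.tss + d_prox // 2 if g.strand == "+" \
                    else g.tss - d_prox // 2
                width = max(150, min(600, d_prox // 4))
                area = 0.8 * L * base * (config.attenuation_ratio - 1.0)
                _add_gauss(lam, center, width, area)
        for r in range(config.signal_replicates):
            counts = rng.poisson(lam).astype(float)
            out.setdefault(cond, []).append(SignalTrack(
                {config.chrom: counts}, bin_size=1,
                sample=f"mnet_{cond}_rep{r + 1}",
                total_reads=int(counts.sum()),
            ))
    return out


def _add_gauss(lam: np.ndarray, center: int, width: int, area: float) -> None:
    if area <= 0:
        return
    lo, hi = max(0, center - 4 * width), min(lam.size, center + 4 * width)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    prof = np.exp(-0.5 * ((x - center) / width) ** 2)
    lam[lo:hi] += area * prof / (width * np.sqrt(2 * np.pi))


def simulate_chip_tracks(
    ledger: TruthLedger,
    config: SimConfig | None = None,
    antibodies: tuple = ("ab_int", "ab_ct"),
) -> dict[str, dict]:
    """IP/input 50-bp bin counts per antibody over a Poisson background.

    ``n_shared_regions`` enriched blocks appear in both antibodies (the planted
    dual-antibody truth); each antibody additionally carries
    ``n_unique_regions`` private blocks that a correct intersection must never
    report.  Spike-in read counts are drawn from the configured fraction.
    """
    config = config or ledger.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    nb = config.chrom_length // config.chip_bin
    wb = config.region_width // config.chip_bin

    def draw_regions(k: int, occupied: list) -> list[tuple[int, int]]:
        regions = []
        tries = 0
        while len(regions) < k and tries < 1000:
            tries += 1
            s = int(rng.integers(10, nb - wb - 10))
            if all(s + wb + 10 < a or b + 10 < s for a, b in occupied):
                regions.append((s, s + wb))
                occupied.append((s, s + wb))
        return regions

    occupied: list[tuple[int, int]] = []
    shared = draw_regions(config.n_shared_regions, occupied)
    unique = {ab: draw_regions(config.n_unique_regions, occupied) for ab in antibodies}
    ledger.enriched_regions = {
        "shared": [(a * config.chip_bin, b * config.chip_bin) for a, b in shared],
        **{ab: [(a * config.chip_bin, b * config.chip_bin) for a, b in unique[ab]]
           for ab in antibodies},
    }

    out = {}
    for ab in antibodies:
        lam = np.full(nb, config.chip_background)
        for s, e in shared + unique[ab]:
            lam[s:e] *= config.chip_fold
        ip = rng.poisson(lam).astype(float)
        inp = rng.poisson(np.full(nb, config.chip_background)).astype(float)
        total = int(ip.sum())
        spike = int(rng.poisson(total * config.spike_in_fraction))
        ledger.spike_in_fraction[ab] = config.spike_in_fraction
        out[ab] = {
            "ip": SignalTrack({config.chrom: ip}, bin_size=config.chip_bin,
                              sample=f"{ab}_ip", total_reads=total, spike_reads=spike),
            "input": SignalTrack({config.chrom: inp}, bin_size=config.chip_bin,
                                 sample=f"{ab}_input", total_reads=int(inp.sum())),
        }
    return out


def simulate_global_change_pair(
    config: SimConfig | None = None,
    global_fold: float = 2.0,
    seed: int = 0,
) -> dict[str, SignalTrack]:
    """Two ChIP samples with identical enrichment shape but a global IP loss.

    Sample "high" has ``global_fold`` times the chromatin-IP yield of sample
    "low"; both are sequenced to the same total read count with a constant
    spike-in chromatin fraction, so the spike-in read count absorbs the yield
    difference.  Depth-only scaling hides the global change; spike-in
    calibration recovers it.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    nb = config.chrom_length // config.chip_bin
    shape = np.full(nb, config.chip_background)
    idx = rng.choice(nb - 40, size=20, replace=False)
    for s in idx:
        shape[s: s + 40] *= config.chip_fold
    shape /= shape.sum()

    n_reads = 2_000_000
    spike_mass = config.spike_in_fraction  # spike chromatin per unit target yield
    out = {}
    for name, yield_ in (("high", global_fold), ("low", 1.0)):
        frac_spike = spike_mass / (yield_ + spike_mass)
        spike_reads = int(rng.poisson(n_reads * frac_spike))
        genome_reads = n_reads - spike_reads
        counts = rng.poisson(shape * genome_reads).astype(float)
        out[name] = SignalTrack(
            {config.chrom: counts}, bin_size=config.chip_bin, sample=name,
            total_reads=n_reads, spike_reads=spike_reads,
        )
    return out


def simulate_signal_tracks(
    genes: list[GeneModel],
    ledger: TruthLedger,
    config: SimConfig | None = None,
) -> dict:
    """All signal-track sets: nascent-transcription and dual-antibody ChIP."""
    return {
        "mnet": simulate_mnet_tracks(genes, ledger, config),
        "chip": simulate_chip_tracks(ledger, config),
    }


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_gtf(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
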