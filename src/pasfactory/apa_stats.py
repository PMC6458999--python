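"""Differential PAS-usage testing, APA shift classification, and gene-level DE.

Differential PAS usage is tested per PAS with a beta-binomial likelihood-ratio
test of the PAS count against the gene-total count, with a condition-dependent
usage proportion under the alternative and a common per-gene overdispersion
estimated by the method of moments.  Gene-level differential expression uses
PAS-summed raw counts, median-of-ratios size factors, and a negative-binomial
Wald test with moment-estimated, trend-shrunk dispersion.  Both tests are
Benjamini-Hochberg adjusted (across PAS and across genes, separately).

Shift-direction classification follows the usage results: genes with no
significantly changed PAS are "no shift"; otherwise the two most significant
PAS (or the single significant PAS paired with the most frequently used other
PAS, measured on pooled control counts) are ordered proximal/distal along the
direction of transcription, and the distal/proximal usage ratio per condition
decides the call — a higher ratio in treated cells is a distal shift, the
opposite a proximal shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .pas_calling import PASCountMatrix

__all__ = [
    "UsageTestResult",
    "APACall",
    "DEResult",
    "test_pas_usage",
    "classify_apa_shift",
    "test_differential_expression",
    "pas_usage_fraction",
]


@dataclass
class UsageTestResult:
    gene_id: str
    pas_id: str
    usage_control: float
    usage_treated: float
    statistic: float
    p: float
    padj: float = np.nan
    testable: bool = True


@dataclass
class APACall:
    gene_id: str
    category: str  # single_pas | no_shift | distal | proximal
    proximal_id: str | None = None
    distal_id: str | None = None
    ratio_control: float = np.nan
    ratio_treated: float = np.nan
    continuity_corrected: bool = False


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float
    p: float
    padj: float = np.nan


# ---------------------------------------------------------------------------
# beta-binomial machinery

def _bb_loglik(y: np.ndarray, n: np.ndarray, p: float, rho: float) -> float:
    """Beta-binomial log-likelihood; collapses to binomial as rho -> 0."""
    p = min(max(p, 1e-12), 1 - 1e-12)
    if rho < 1e-9:
        return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return float(np.sum(special.betaln(y + a, n - y + b) - special.betaln(a, b)))


def _bb_fit_p(y: np.ndarray, n: np.ndarray, rho: float) -> tuple[float, float]:
    """MLE of the usage proportion at fixed overdispersion; returns (p, loglik)."""
    if n.sum() == 0:
        return 0.5, 0.0
    p0 = float(y.sum() / n.sum())
    if rho < 1e-9:
        return p0, _bb_loglik(y, n, p0, rho)
    res = optimize.minimize_scalar(
        lambda p: -_bb_loglik(y, n, p, rho),
        bounds=(1e-9, 1 - 1e-9), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), -float(res.fun)


def _gene_overdispersion(Y: np.ndarray, N: np.ndarray, cond: np.ndarray) -> float:
    """Method-of-moments beta-binomial correlation, pooled over a gene's PAS.

    Uses within-condition proportions so planted condition effects do not
    inflate the estimate.  With the proportion estimated from the same m
    replicates, the summed Pearson residuals lose one degree of freedom:
    E[sum_i (y_i - n_i*phat)^2 / (n_i*phat*(1-phat))] ~= (m-1)(1 + (nbar-1)rho),
    hence the (m-1) scaling below; without it rho is biased low and the LRT
    anticonservative at few replicates.
    """
    zsum, dof, w = 0.0, 0.0, []
    for c in np.unique(cond):
        idx = cond == c
        nsub = N[idx]
        m = int(idx.sum())
        if nsub.sum() == 0 or m < 2:
            continue
        for j in range(Y.shape[0]):
            ph = Y[j, idx].sum() / nsub.sum()
            if ph <= 0 or ph >= 1:
                continue
            denom = nsub * ph * (1 - ph)
            ok = denom > 0
            if ok.sum() < 2:
                continue
            zsum += float(((Y[j, idx][ok] - nsub[ok] * ph) ** 2 / denom[ok]).sum())
            dof += ok.sum() - 1
            w.extend((nsub[ok] - 1).tolist())
    if dof <= 0 or not w or np.mean(w) <= 0:
        return 0.0, 0.0
    rho = (zsum / dof - 1.0) / np.mean(w)
    return float(min(max(rho, 0.0), 0.99)), float(dof)


def _shrink_overdispersion(rho_raw: dict[str, float], dof: dict[str, float],
                           prior_dof: float = 20.0) -> dict[str, float]:
    """Shrink noisy per-gene moment estimates toward the across-gene median.

    A per-gene estimate rests on a handful of residual degrees of freedom;
    genes whose estimate happens to fall low would otherwise get inflated
    likelihood-ratio statistics.
    """
    if not rho_raw:
        return {}
    center = float(np.median(list(rho_raw.values())))
    return {
        g: (dof.get(g, 0.0) * r + prior_dof * center) / (dof.get(g, 0.0) + prior_dof)
        for g, r in rho_raw.items()
    }


def test_pas_usage(
    matrix: PASCountMatrix,
    design: dict[str, str],
    control: str = "control",
    treated: str = "treated",
) -> list[UsageTestResult]:
    """Beta-binomial LRT of each PAS's usage against its gene total.

    Only genes with >= 2 assigned PAS are tested.  Genes with a zero total in
    either condition are flagged untestable and excluded from the BH
    adjustment, which runs across all tested PAS.
    """
    samples = [s for s in matrix.samples if s in design]
    cond = np.array([design[s] for s in samples])
    for lab in (control, treated):
        if (cond == lab).sum() < 2:
            raise ValueError(f"need >= 2 replicates in condition {lab!r}")

    results: list[UsageTestResult] = []
    meta = matrix.meta[matrix.meta.gene_id.notna()]
    per_gene: dict[str, tuple] = {}
    rho_raw: dict[str, float] = {}
    rho_dof: dict[str, float] = {}
    for gid, grp in meta.groupby("gene_id"):
        if len(grp) < 2:
            continue
        Y = matrix.counts.loc[grp.index, samples].to_numpy(dtype=float)
        N = Y.sum(axis=0)
        per_gene[gid] = (grp.index, Y, N)
        if N[cond == control].sum() > 0 and N[cond == treated].sum() > 0:
            rho_raw[gid], rho_dof[gid] = _gene_overdispersion(Y, N, cond)
    rho_use = _shrink_overdispersion(rho_raw, rho_dof)

    for gid, (idx, Y, N) in per_gene.items():
        ctl, trt = cond == control, cond == treated
        if N[ctl].sum() == 0 or N[trt].sum() == 0:
            for pas_id in idx:
                results.append(UsageTestResult(gid, pas_id, np.nan, np.nan,
                                               np.nan, np.nan, testable=False))
            continue
        rho = rho_use[gid]
        for j, pas_id in enumerate(idx):
            y = Y[j]
            _, ll0 = _bb_fit_p(y, N, rho)
            _, ll1c = _bb_fit_p(y[ctl], N[ctl], rho)
            _, ll1t = _bb_fit_p(y[trt], N[trt], rho)
            stat = max(0.0, 2.0 * (ll1c + ll1t - ll0))
            p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
            results.append(UsageTestResult(
                gid, pas_id,
                usage_control=float(y[ctl].sum() / N[ctl].sum()),
                usage_treated=float(y[trt].sum() / N[trt].sum()),
                statistic=stat, p=p,
            ))

    testable = [r for r in results if r.testable]
    if testable:
        padj = multipletests([r.p for r in testable], method="fdr_bh")[1]
        for r, q in zip(testable, padj):
            r.padj = float(q)
    return results


# ---------------------------------------------------------------------------
# shift classification

def classify_apa_shift(
    results: list[UsageTestResult],
    matrix: PASCountMatrix,
    design: dict[str, str],
    control: str = "control",
    treated: str = "treated",
    alpha: float = 0.05,
) -> list[APACall]:
    """Classify each gene's APA shift direction from its usage-test results."""
    samples = [s for s in matrix.samples if s in design]
    ctl_samples = [s for s in samples if design[s] == control]
    trt_samples = [s for s in samples if design[s] == treated]

    by_gene: dict[str, list[UsageTestResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene_id, []).append(r)

    calls = []
    meta = matrix.meta
    for gid, grp in meta[meta.gene_id.notna()].groupby("gene_id"):
        if len(grp) == 1:
            calls.append(APACall(gid, "single_pas"))
            continue
        rs = [r for r in by_gene.get(gid, []) if r.testable and np.isfinite(r.padj)]
        sig = [r for r in rs if r.padj < alpha]
        if not sig:
            calls.append(APACall(gid, "no_shift"))
            continue
        if len(sig) >= 2:
            # two most significant; padj ties broken by larger usage change
            sig.sort(key=lambda r: (r.padj, -abs(r.usage_treated - r.usage_control)))
            pair = [sig[0].pas_id, sig[1].pas_id]
        else:
            # the one significant PAS vs the most used other PAS
            # (pooled control-condition counts)
            pooled_ctl = matrix.counts.loc[grp.index, ctl_samples].sum(axis=1)
            others = pooled_ctl.drop(sig[0].pas_id)
            pair = [sig[0].pas_id, others.idxmax()]

        # order the pair proximal/distal along transcription
        strand = grp.strand.iloc[0]
        s0, s1 = meta.loc[pair[0], "summit"], meta.loc[pair[1], "summit"]
        upstream_first = s0 < s1 if strand == "+" else s0 > s1
        prox, dist = (pair[0], pair[1]) if upstream_first else (pair[1], pair[0])

        p_ctl = float(matrix.counts.loc[prox, ctl_samples].sum())
        d_ctl = float(matrix.counts.loc[dist, ctl_samples].sum())
        p_trt = float(matrix.counts.loc[prox, trt_samples].sum())
        d_trt = float(matrix.counts.loc[dist, trt_samples].sum())
        corrected = min(p_ctl, p_trt) == 0
        if corrected:
            p_ctl, d_ctl, p_trt, d_trt = (x + 0.5 for x in (p_ctl, d_ctl, p_trt, d_trt))
        r_ctl, r_trt = d_ctl / p_ctl, d_trt / p_trt
        calls.append(APACall(
            gid, "distal" if r_trt > r_ctl else "proximal",
            proximal_id=prox, distal_id=dist,
            ratio_control=r_ctl, ratio_treated=r_trt,
            continuity_corrected=corrected,
        ))
    return calls


# ---------------------------------------------------------------------------
# differential expression

def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median per sample of ratios to row geomeans."""
    logc = np.log(counts.where(counts > 0))
    loggeo = logc.mean(axis=1)
    ok = np.isfinite(loggeo)
    if not ok.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sf = np.exp((logc.loc[ok].sub(loggeo[ok], axis=0)).median(axis=0))
    return sf / np.exp(np.log(sf).mean())


def test_differential_expression(
    matrix: PASCountMatrix | pd.DataFrame,
    design: dict[str, str],
    control: str = "control",
    treated: str = "treated",
    dispersion_floor: float = 1e-8,
) -> list[DEResult]:
    """Negative-binomial Wald test on PAS-summed gene counts.

    Size factors are median-of-ratios; per-gene dispersions are estimated by
    the method of moments on within-condition residuals, shrunk halfway toward
    a 1/mean parametric trend fitted across genes; the Wald test compares the
    condition coefficient of a log-link NB fit to zero.  All-zero genes are
    excluded.  log2 fold-changes are treated over control.
    """
    gc = matrix.gene_counts() if isinstance(matrix, PASCountMatrix) else matrix
    if gc.empty:
        return []
    samples = [s for s in gc.columns if s in design]
    gc = gc[samples]
    cond = np.array([design[s] for s in samples])
    for lab in (control, treated):
        if (cond == lab).sum() < 2:
            raise ValueError(f"need >= 2 replicates in condition {lab!r}")
    gc = gc.loc[gc.sum(axis=1) > 0]
    sf = median_of_ratios(gc)
    norm = gc / sf

    ctl, trt = cond == control, cond == treated
    mu = norm.mean(axis=1).to_numpy()
    # within-condition residual variance (unbiased)
    var_w = (norm.loc[:, np.array(samples)[ctl]].var(axis=1, ddof=1)
             * (ctl.sum() - 1)
             + norm.loc[:, np.array(samples)[trt]].var(axis=1, ddof=1)
             * (trt.sum() - 1)) / (len(samples) - 2)
    alpha_mom = np.maximum((var_w.to_numpy() - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)

    # parametric trend alpha = a0 + a1/mean, fitted on positive MoM estimates
    pos = alpha_mom > 0
    if pos.sum() >= 10:
        X = np.column_stack([np.ones(pos.sum()), 1.0 / mu[pos]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[pos], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0, a1 = float(np.mean(alpha_mom)), 0.0
    alpha_trend = a0 + a1 / np.maximum(mu, 1e-12)
    alpha_use = np.maximum(0.5 * alpha_mom + 0.5 * alpha_trend, dispersion_floor)

    import statsmodels.api as sm

    x = np.column_stack([np.ones(len(samples)), trt.astype(float)])
    offset = np.log(sf.to_numpy())
    results = []
    for i, gid in enumerate(gc.index):
        y = gc.loc[gid].to_numpy(dtype=float)
        try:
            fam = sm.families.NegativeBinomial(alpha=float(alpha_use[i]))
            fit = sm.GLM(y, x, family=fam, offset=offset).fit(maxiter=100, tol=1e-10)
            b1 = float(fit.params[1])
            se = float(fit.bse[1])
        except Exception:
            m_c = max(y[ctl].mean(), 0.0) + 0.5
            m_t = max(y[trt].mean(), 0.0) + 0.5
            b1, se = float(np.log(m_t / m_c)), np.nan
        if not np.isfinite(se) or se == 0:
            p = 1.0 if b1 == 0 else np.nan
        else:
            z = b1 / se
            p = float(2 * stats.norm.sf(abs(z)))
        results.append(DEResult(gid, float(mu[i]), b1 / np.log(2), p))

    finite = [r for r in results if np.isfinite(r.p)]
    if finite:
        padj = multipletests([r.p for r in finite], method="fdr_bh")[1]
        for r, q in zip(finite, padj):
            r.padj = float(q)
    return results


def pas_usage_fraction(
    matrix: PASCountMatrix,
    gene_id: str,
    pas_id: str,
    design: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample usage fraction of one PAS: count(PAS) / count(gene total).

    Returns one row per sample with the fraction, plus condition mean and SD
    columns when a design is supplied.  A sample with zero gene total is
    flagged undefined (NaN fraction).
    """
    idx = matrix.meta.index[matrix.meta.gene_id == gene_id]
    if pas_id not in idx:
        raise KeyError(f"{pas_id} is not an assigned PAS of {gene_id}")
    totals = matrix.counts.loc[idx].sum(axis=0)
    frac = matrix.counts.loc[pas_id] / totals.where(totals > 0)
    out = pd.DataFrame({"fraction": frac, "gene_total": totals})
    out["undefined"] = totals == 0
    if design:
        out["condition"] = [design.get(s, "") for s in out.index]
        grp = out.groupby("condition")["fraction"]
        out = out.join(grp.transform("mean").rename("condition_mean"))
        out = out.join(grp.transform("std").rename("condition_sd"))
    return out
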