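"""Factorial linear model with empirical-Bayes variance moderation.

Per-gene cell-means OLS over the treatment x genotype layout, a scaled-F
prior on the residual variances estimated by matching moments of log(s^2)
(digamma/trigamma relations), moderated t contrasts, and Benjamini-Hochberg
step-up adjustment.  The hyperparameter estimator is the standard
closed-form moments method for this model class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .io_core import ExpressionMatrix

logger = logging.getLogger("abatrans")


@dataclass
class ModelFit:
    """Cell-means fit: coefficients, pooled residual variance, residual df."""

    gene_ids: list[str]
    cells: list[tuple[str, str]]           # (genotype, treatment) per column of coef
    coef: np.ndarray                       # (G, C) cell means, log2 units
    s2: np.ndarray                         # (G,) residual variance
    df_resid: int
    n_per_cell: np.ndarray                 # (C,) replicate counts

    def contrast_se_multiplier(self, contrast: np.ndarray) -> float:
        return float(np.sqrt(np.sum(np.asarray(contrast) ** 2 / self.n_per_cell)))


@dataclass
class ModerationPrior:
    """Scaled-F prior (d0, s0^2); d0 = +inf means full shrinkage to s0^2.

    d0 = 0 is tolerated as the no-moderation limit (ordinary t).
    """

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df must be >= 0")
        if not self.s02 > 0:
            raise ValueError("prior variance must be > 0")


@dataclass
class LimmaCall:
    category: str
    direction: str
    log2fc_aba: float
    p_aba: float
    fdr_aba: float
    p_genotype: dict[str, float] = field(default_factory=dict)


@dataclass
class LimmaCallSet:
    calls: dict[str, LimmaCall]

    def genes(self, category: str | None = None) -> set[str]:
        if category is None:
            return set(self.calls)
        return {g for g, c in self.calls.items() if c.category == category}

    @property
    def aba_called(self) -> set[str]:
        return set(self.calls)


def fit_factorial(matrix: ExpressionMatrix) -> ModelFit:
    """Per-gene OLS cell means over the genotype x treatment layout."""
    if len(matrix.design.tissues) != 1:
        raise ValueError("fit_factorial expects a single-tissue matrix")
    cells = sorted({s.condition for s in matrix.design.samples})
    cell_idx = {c: i for i, c in enumerate(cells)}
    assign = np.array([cell_idx[s.condition] for s in matrix.design.samples])
    n_per_cell = np.bincount(assign, minlength=len(cells))
    if (n_per_cell == 0).any():
        g, t = cells[int(np.argmin(n_per_cell))]
        raise ValueError(f"empty design cell genotype={g}, treatment={t}")

    G, S = matrix.values.shape
    coef = np.empty((G, len(cells)))
    for c in range(len(cells)):
        coef[:, c] = matrix.values[:, assign == c].mean(axis=1)
    resid = matrix.values - coef[:, assign]
    df_resid = S - len(cells)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom (need replicates)")
    s2 = (resid**2).sum(axis=1) / df_resid
    return ModelFit(list(matrix.gene_ids), cells, coef, s2, df_resid, n_per_cell)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: int | np.ndarray, min_genes: int = 30) -> ModerationPrior:
    """Moments-on-log(s^2) estimate of the scaled-F prior (d0, s0^2)."""
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df_arr >= 1)
    if not ok.any():
        raise ValueError("all residual variances are zero; cannot estimate prior")
    n_zero = int((~ok).sum())
    if n_zero:
        logger.warning("%d gene(s) with zero variance excluded from prior estimation", n_zero)
    if ok.sum() < min_genes:
        raise ValueError(f"need >= {min_genes} genes with positive variance and df >= 1")
    s2, df_arr = s2[ok], df_arr[ok]

    z = np.log(s2)
    if np.ptp(z) == 0:
        # degenerate: no sampling noise to deconvolve, take the value as-is
        return ModerationPrior(math.inf, float(s2[0]))
    e = z - special.digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df_arr / 2.0).mean())
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return ModerationPrior(d0, s02)


def moderated_t(
    fit: ModelFit, prior: ModerationPrior, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t, p, log2FC) for one contrast over the cell means.

    Posterior variance s~^2 = (d0 s0^2 + d s^2) / (d0 + d); p two-sided on
    d + d0 df, collapsing to a z-like test when d0 is infinite.
    """
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (len(fit.cells),):
        raise ValueError(f"contrast must have length {len(fit.cells)}")
    log2fc = fit.coef @ contrast
    se_mult = fit.contrast_se_multiplier(contrast)
    if math.isinf(prior.d0):
        s2_post = np.full_like(fit.s2, prior.s02)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s02 + fit.df_resid * fit.s2) / (prior.d0 + fit.df_resid)
        df_total = fit.df_resid + prior.d0
    se = se_mult * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    # zero posterior variance: exact effect or exact null
    zero = se == 0
    t[zero & (log2fc != 0)] = np.sign(log2fc[zero & (log2fc != 0)]) * np.inf
    t[zero & (log2fc == 0)] = 0.0
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, log2fc


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


@dataclass
class CallThresholds:
    p_aba: float = 1e-4
    p_genotype: float = 0.01
    fdr: float = 1e-3


def _aba_contrast(cells: list[tuple[str, str]]) -> np.ndarray:
    for cell in (("wt", "ABA"), ("wt", "control")):
        if cell not in cells:
            raise ValueError(f"design has no cell genotype={cell[0]}, treatment={cell[1]}")
    c = np.zeros(len(cells))
    c[cells.index(("wt", "ABA"))] = 1.0
    c[cells.index(("wt", "control"))] = -1.0
    return c


def _genotype_contrasts(cells: list[tuple[str, str]]) -> dict[str, np.ndarray]:
    contrasts = {}
    for genotype in ("gpa1", "agb1", "agb1_gpa1"):
        for treatment in ("control", "ABA"):
            if (genotype, treatment) not in cells:
                continue
            c = np.zeros(len(cells))
            c[cells.index((genotype, treatment))] = 1.0
            c[cells.index(("wt", treatment))] = -1.0
            contrasts[f"{genotype}_{treatment}_vs_wt"] = c
    return contrasts


def call_de(
    fit: ModelFit,
    prior: ModerationPrior,
    thresholds: CallThresholds | None = None,
) -> LimmaCallSet:
    """Apply the contrast threshold rules and produce the linear-model call set.

    A gene is hormone-responsive when its treated-vs-control wild-type
    contrast passes both the raw p threshold and the genome-wide BH FDR
    cut-off; it is G-protein dependent when additionally at least one
    mutant-vs-wild-type contrast passes the genotype p threshold.
    """
    thr = thresholds or CallThresholds()
    _, p_aba, lfc_aba = moderated_t(fit, prior, _aba_contrast(fit.cells))
    fdr_aba = bh_adjust(p_aba)
    geno = {
        name: moderated_t(fit, prior, c)[1]
        for name, c in _genotype_contrasts(fit.cells).items()
    }

    calls: dict[str, LimmaCall] = {}
    for g, gene in enumerate(fit.gene_ids):
        if not (p_aba[g] < thr.p_aba and fdr_aba[g] < thr.fdr):
            continue
        geno_p = {name: float(ps[g]) for name, ps in geno.items()}
        dependent = any(p < thr.p_genotype for p in geno_p.values())
        category = "gprotein_dependent_aba" if dependent else "gprotein_independent_aba"
        direction = "induced" if lfc_aba[g] > 0 else "repressed"
        calls[gene] = LimmaCall(
            category, direction, float(lfc_aba[g]), float(p_aba[g]), float(fdr_aba[g]), geno_p
        )
    return LimmaCallSet(calls)


def run_de(
    matrix: ExpressionMatrix, thresholds: CallThresholds | None = None
) -> LimmaCallSet:
    """Convenience pipeline: fit, estimate prior, call."""
    fit = fit_factorial(matrix)
    prior = estimate_prior(fit.s2, fit.df_resid)
    return call_de(fit, prior, thresholds)


def wt_aba_test(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Moderated treated-vs-control test on the wild-type subset.

    Returns per-gene (log2FC, BH-adjusted p).  Degenerate zero-variance
    inputs (noise-free simulations) are handled exactly: p = 0 where the
    effect is non-zero, 1 otherwise.
    """
    idx = matrix.design.sample_indices(genotype="wt")
    if not idx:
        raise ValueError("matrix has no wild-type samples")
    sub = matrix.subset_samples(idx)
    fit = fit_factorial(sub)
    contrast = _aba_contrast(fit.cells)
    try:
        prior = estimate_prior(fit.s2, fit.df_resid)
    except ValueError:
        lfc = fit.coef @ contrast
        p = np.where(lfc != 0, 0.0, 1.0)
        return lfc, p
    _, p, lfc = moderated_t(fit, prior, contrast)
    return lfc, bh_adjust(p)
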