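"""Boolean regulatory-mode classification.

Genes are matched against idealized 0/1 expression templates of the composed
form ``B(hormone, A(GPA1, AGB1))`` evaluated on the 8 genotype x treatment
conditions.  A correlation score (Pearson r across the 8 condition means,
times the absolute log2 amplitude between template-on and template-off
conditions) assigns each gene to its best-fitting rule; calls are made above
a score threshold and the false discovery rate is estimated by column-label
permutation.

The exact scoring function of the original method is reconstructed here as
``r * |delta|``; it is shift-invariant (constant offsets are absorbed) and
scales linearly with effect amplitude, which makes a threshold of 1.5 on the
log2 scale interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import ExpressionMatrix, SampleDesign, GENOTYPES, TREATMENTS
from . import moderated_de

logger = logging.getLogger("abatrans")

#: the 8 Boolean states in canonical order; index = ABA*4 + GPA1*2 + AGB1.
STATES: list[tuple[int, int, int]] = [
    (aba, gpa1, agb1) for aba in (0, 1) for gpa1 in (0, 1) for agb1 in (0, 1)
]

_STATE_TO_GENOTYPE = {(1, 1): "wt", (0, 1): "gpa1", (1, 0): "agb1", (0, 0): "agb1_gpa1"}

#: condition (genotype, treatment) for each of the 8 state indices.
CONDITIONS: list[tuple[str, str]] = [
    (_STATE_TO_GENOTYPE[(g, b)], "ABA" if a else "control") for a, g, b in STATES
]

ABA_TRUTH = tuple(a for a, _, _ in STATES)
NOT_ABA_TRUTH = tuple(1 - a for a, _, _ in STATES)

CATEGORIES = ("gprotein_independent_aba", "gprotein_dependent_aba", "gprotein_only", "none")


def _bool2(index: int, x: int, y: int) -> int:
    """The index-th two-input Boolean function: bit (2x + y) of index."""
    return (index >> (2 * x + y)) & 1


@dataclass(frozen=True)
class BooleanRule:
    """A composed rule with its 8-condition truth vector."""

    b_index: int
    a_index: int
    truth: tuple[int, ...]
    aba_only: bool

    @property
    def depends_on_aba(self) -> bool:
        t = self.truth
        return any(t[4 + i] != t[i] for i in range(4))

    @property
    def depends_on_gprotein(self) -> bool:
        t = self.truth
        return any(len({t[a * 4 + i] for i in range(4)}) > 1 for a in (0, 1))

    @property
    def complement_truth(self) -> tuple[int, ...]:
        return tuple(1 - v for v in self.truth)


def enumerate_rules() -> list[BooleanRule]:
    """All distinct non-constant truth vectors of B(ABA, A(GPA1, AGB1)).

    Deduplicated by truth vector (first composition index kept); hormone-only
    rules (truth = ABA and truth = not ABA) are ordered first so that argmax
    tie-breaking prefers them.
    """
    seen: dict[tuple[int, ...], tuple[int, int]] = {}
    for b_index in range(16):
        for a_index in range(16):
            truth = tuple(
                _bool2(b_index, aba, _bool2(a_index, gpa1, agb1))
                for aba, gpa1, agb1 in STATES
            )
            if len(set(truth)) == 1:
                continue  # constant templates are unassignable
            seen.setdefault(truth, (b_index, a_index))
    rules = [
        BooleanRule(b, a, truth, truth in (ABA_TRUTH, NOT_ABA_TRUTH))
        for truth, (b, a) in seen.items()
    ]
    rules.sort(key=lambda r: (not r.aba_only, r.b_index, r.a_index))
    return rules


def condition_index_map(design: SampleDesign) -> np.ndarray:
    """Per-sample index into the 8 canonical conditions; errors if any is absent."""
    cond_to_idx = {c: i for i, c in enumerate(CONDITIONS)}
    idx = np.array([cond_to_idx[s.condition] for s in design.samples], dtype=int)
    present = set(idx.tolist())
    missing = [CONDITIONS[i] for i in range(8) if i not in present]
    if missing:
        g, t = missing[0]
        raise ValueError(f"design is missing condition genotype={g}, treatment={t}")
    return idx


def rule_template(rule: BooleanRule, design: SampleDesign) -> np.ndarray:
    """Per-sample 0/1 vector; replicates share their condition's truth value."""
    idx = condition_index_map(design)
    return np.array(rule.truth, dtype=float)[idx]


def condition_means(values: np.ndarray, design: SampleDesign) -> np.ndarray:
    """(G, 8) matrix of per-condition means in canonical condition order."""
    idx = condition_index_map(design)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    means = np.empty((values.shape[0], 8))
    for c in range(8):
        means[:, c] = values[:, idx == c].mean(axis=1)
    return means


def _scores_from_means(means: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """Score matrix (G, R): Pearson r over the 8 conditions times |delta|."""
    mc = means - means.mean(axis=1, keepdims=True)
    tc = truths - truths.mean(axis=1, keepdims=True)
    m_norm = np.linalg.norm(mc, axis=1)
    t_norm = np.linalg.norm(tc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mc @ tc.T) / np.outer(m_norm, t_norm)
    r[m_norm == 0, :] = 0.0  # flat gene: zero variance across conditions
    n_on = truths.sum(axis=1)
    delta = means @ truths.T / n_on - means @ (1 - truths).T / (8 - n_on)
    return r * np.abs(delta)


def correlation_score(
    gene_values: np.ndarray,
    template: np.ndarray,
    design: SampleDesign | None = None,
) -> float:
    """Score one gene against one 0/1 template.

    With a design the per-sample vectors are collapsed to the 8 condition
    means first; without one the inputs are taken as already per-condition.
    """
    gene_values = np.asarray(gene_values, dtype=float)
    template = np.asarray(template, dtype=float)
    if gene_values.shape != template.shape:
        raise ValueError("gene values and template must have the same length")
    if design is not None:
        idx = condition_index_map(design)
        means = condition_means(gene_values[None, :], design)[0]
        truth = np.empty(8)
        for c in range(8):
            vals = np.unique(template[idx == c])
            if len(vals) != 1:
                raise ValueError("template is not constant within a condition")
            truth[c] = vals[0]
    else:
        means, truth = gene_values, template
    if len(set(truth.tolist())) == 1:
        raise ValueError("template must be non-constant")
    return float(_scores_from_means(means[None, :], truth[None, :])[0, 0])


@dataclass
class BooleanCall:
    rule: BooleanRule
    score: float
    category: str
    direction: str


@dataclass
class BooleanCallSet:
    calls: dict[str, BooleanCall]
    threshold: float
    fdr_estimate: float | None = None

    def genes(self, category: str | None = None) -> set[str]:
        if category is None:
            return set(self.calls)
        return {g for g, c in self.calls.items() if c.category == category}

    @property
    def aba_called(self) -> set[str]:
        return {
            g for g, c in self.calls.items()
            if c.category in ("gprotein_independent_aba", "gprotein_dependent_aba")
        }


def _best_scores(matrix: ExpressionMatrix, rules: list[BooleanRule]):
    truths = np.array([r.truth for r in rules], dtype=float)
    means = condition_means(matrix.values, matrix.design)
    scores = _scores_from_means(means, truths)
    best_idx = np.argmax(scores, axis=1)  # first max wins: hormone-only rules lead
    best = scores[np.arange(scores.shape[0]), best_idx]
    return best, best_idx, means


def _wt_delta(means: np.ndarray) -> np.ndarray:
    """Wild-type treatment-minus-control log2 difference from condition means."""
    wt_aba = CONDITIONS.index(("wt", "ABA"))
    wt_ctl = CONDITIONS.index(("wt", "control"))
    return means[:, wt_aba] - means[:, wt_ctl]


def classify(
    matrix: ExpressionMatrix,
    threshold: float = 1.5,
    n_perm: int = 20,
    seed: int = 0,
    wt_fold_change: float = 1.0,
    wt_fdr: float = 0.05,
) -> BooleanCallSet:
    """Assign each gene its best rule and category; one tissue at a time.

    Co-regulated genes are only reported as G-protein dependent when the
    wild-type shows more than ``2**wt_fold_change``-fold hormone response at
    FDR < ``wt_fdr`` (moderated t on the wild-type subset).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(matrix.design.tissues) != 1:
        raise ValueError("classify expects a single-tissue matrix")
    rules = enumerate_rules()
    best, best_idx, means = _best_scores(matrix, rules)
    wt_delta = _wt_delta(means)
    wt_lfc, wt_q = moderated_de.wt_aba_test(matrix)

    calls: dict[str, BooleanCall] = {}
    for g, gene in enumerate(matrix.gene_ids):
        if best[g] < threshold:
            continue
        rule = rules[best_idx[g]]
        if rule.aba_only:
            category = "gprotein_independent_aba"
        elif rule.depends_on_aba:
            strong_wt = abs(wt_lfc[g]) > wt_fold_change and wt_q[g] < wt_fdr
            category = "gprotein_dependent_aba" if strong_wt else "none"
        else:
            category = "gprotein_only"
        if wt_delta[g] > 0:
            direction = "induced"
        elif wt_delta[g] < 0:
            direction = "repressed"
        else:
            on = np.array(rule.truth, dtype=float)
            direction = "induced" if on[4:].mean() > on[:4].mean() else "repressed"
        calls[gene] = BooleanCall(rule, float(best[g]), category, direction)

    fdr = permutation_fdr(matrix, threshold=threshold, n_perm=n_perm, seed=seed)
    return BooleanCallSet(calls, threshold, fdr)


def permutation_fdr(
    matrix: ExpressionMatrix,
    threshold: float = 1.5,
    n_perm: int = 20,
    seed: int = 0,
) -> float:
    """FDR estimate by full-column label permutation.

    Each permutation shuffles sample columns against the design (preserving
    gene-wise covariance) and recounts genes whose best score clears the
    threshold.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rules = enumerate_rules()
    truths = np.array([r.truth for r in rules], dtype=float)
    means = condition_means(matrix.values, matrix.design)
    real_called = int((_scores_from_means(means, truths).max(axis=1) >= threshold).sum())

    rng = np.random.default_rng(seed)
    idx = condition_index_map(matrix.design)
    perm_counts = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(matrix.values.shape[1])
        pm = np.empty((matrix.values.shape[0], 8))
        for c in range(8):
            pm[:, c] = matrix.values[:, perm[idx == c]].mean(axis=1)
        perm_counts[p] = (_scores_from_means(pm, truths).max(axis=1) >= threshold).sum()
    if real_called == 0:
        if perm_counts.sum() == 0:
            logger.warning("no genes called on real or permuted data; FDR reported as 0")
            return 0.0
        logger.warning("no genes called on real data; FDR denominator clamped to 1")
    return float(perm_counts.mean() / max(1, real_called))
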