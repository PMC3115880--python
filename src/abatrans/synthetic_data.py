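"""Synthetic data with planted truth for every downstream stage.

Three generators: expression matrices with planted Boolean regulatory modes
and Gaussian replicate noise on the log2 scale, promoter sets with motif
words planted at controlled frequencies and positions, and collections of
study gene sets sharing a planted core.

Seeding: the single user seed is expanded into independent per-component
streams via ``np.random.default_rng([tag, seed])`` with fixed component tags
(0 = expression, 1 = promoters, 2 = study sets), so partial reruns are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boolean_classifier import CONDITIONS, STATES, ABA_TRUTH, NOT_ABA_TRUTH
from .io_core import ExpressionMatrix, GeneSet, PromoterSet, Sample, SampleDesign

_EXPR_TAG, _PROM_TAG, _SETS_TAG = 0, 1, 2

MODES = (
    "aba_induced_only",
    "aba_repressed_only",
    "aba_gprotein_dependent",
    "gprotein_only",
    "null",
)

#: planted 8-condition truth vector per non-null mode (state order as in
#: boolean_classifier.STATES).
PLANTED_TRUTH = {
    "aba_induced_only": ABA_TRUTH,
    "aba_repressed_only": NOT_ABA_TRUTH,
    # responds only when hormone is present AND both subunits are intact
    "aba_gprotein_dependent": tuple(a * g * b for a, g, b in STATES),
    # follows one subunit regardless of treatment
    "gprotein_only": tuple(g for _, g, _ in STATES),
}

PLANTED_DIRECTION = {
    "aba_induced_only": "induced",
    "aba_repressed_only": "repressed",
    "aba_gprotein_dependent": "induced",
    "gprotein_only": "unsigned",
    "null": "unsigned",
}


@dataclass
class SimConfig:
    n_genes: int
    frac_aba_induced: float = 0.0
    frac_aba_repressed: float = 0.0
    frac_aba_gprotein_dependent: float = 0.0
    frac_gprotein_only: float = 0.0
    effect_size: float = 2.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    replicates: int = 3
    tissue: str = "guard_cell"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = self.fractions
        if any(f < 0 for f in fracs.values()):
            raise ValueError("fractions must be non-negative")
        if sum(fracs.values()) > 1 + 1e-12:
            raise ValueError("fractions must sum to <= 1")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "aba_induced_only": self.frac_aba_induced,
            "aba_repressed_only": self.frac_aba_repressed,
            "aba_gprotein_dependent": self.frac_aba_gprotein_dependent,
            "gprotein_only": self.frac_gprotein_only,
        }


@dataclass
class TruthEntry:
    mode: str
    truth: tuple[int, ...] | None
    direction: str


@dataclass
class TruthTable:
    entries: dict[str, TruthEntry]

    def genes(self, mode: str) -> set[str]:
        return {g for g, e in self.entries.items() if e.mode == mode}

    def mode_counts(self) -> dict[str, int]:
        counts = {m: 0 for m in MODES}
        for e in self.entries.values():
            counts[e.mode] += 1
        return counts


def allocate_modes(cfg: SimConfig) -> list[str]:
    """Per-gene mode labels: floor(fraction * n) per mode, remainder null."""
    labels: list[str] = []
    for mode, frac in cfg.fractions.items():
        labels.extend([mode] * int(np.floor(frac * cfg.n_genes)))
    labels.extend(["null"] * (cfg.n_genes - len(labels)))
    return labels


def _design(cfg: SimConfig) -> SampleDesign:
    samples = []
    for genotype, treatment in CONDITIONS:
        for rep in range(1, cfg.replicates + 1):
            sid = f"{cfg.tissue}_{genotype}_{treatment}_{rep}"
            samples.append(Sample(sid, cfg.tissue, genotype, treatment, rep))
    return SampleDesign(samples)


def simulate_experiment(cfg: SimConfig) -> tuple[ExpressionMatrix, TruthTable]:
    """Expression matrix with planted modes; deterministic given cfg.seed."""
    rng = np.random.default_rng([_EXPR_TAG, cfg.seed])
    design = _design(cfg)
    labels = allocate_modes(cfg)
    gene_ids = [f"SYN{i + 1:05d}" for i in range(cfg.n_genes)]

    cond_idx = [CONDITIONS.index(s.condition) for s in design.samples]
    means = np.full((cfg.n_genes, len(design)), cfg.baseline_mean)
    entries: dict[str, TruthEntry] = {}
    for g, (gene, mode) in enumerate(zip(gene_ids, labels)):
        truth = PLANTED_TRUTH.get(mode)
        if truth is not None:
            template = np.array([truth[c] for c in cond_idx], dtype=float)
            means[g] += cfg.effect_size * template
        entries[gene] = TruthEntry(mode, truth, PLANTED_DIRECTION[mode])

    values = means + rng.normal(0.0, cfg.noise_sd, size=means.shape) if cfg.noise_sd > 0 else means
    return ExpressionMatrix(gene_ids, values, design), TruthTable(entries)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class PlantSpec:
    """One motif word planted at per-set frequencies in a position window."""

    word: str
    foreground_fraction: float
    background_fraction: float = 0.0
    window: tuple[int, int] | str = "uniform"   # [lo, hi] in -length..-1

    def __post_init__(self) -> None:
        self.word = self.word.upper()
        if set(self.word) - set("ACGT"):
            raise ValueError(f"planted word {self.word!r} must be over ACGT")
        for f in (self.foreground_fraction, self.background_fraction):
            if not 0 <= f <= 1:
                raise ValueError("plant fractions must lie in [0, 1]")


@dataclass
class PromoterSimConfig:
    n_genes: int
    n_foreground: int
    length: int = 1000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    plant_spec: list[PlantSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_foreground <= self.n_genes:
            raise ValueError("n_foreground must lie in [0, n_genes]")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        for spec in self.plant_spec:
            lo, hi = self._window_bounds(spec)
            if hi - lo + 1 < len(spec.word):
                raise ValueError(f"window too small for word {spec.word!r}")

    def _window_bounds(self, spec: PlantSpec) -> tuple[int, int]:
        if spec.window == "uniform":
            return (-self.length, -1)
        lo, hi = spec.window
        if not (-self.length <= lo <= hi <= -1):
            raise ValueError(f"window {spec.window} outside promoter coordinates")
        return (lo, hi)


def foreground_ids(cfg: PromoterSimConfig) -> list[str]:
    return [f"PRM{i + 1:05d}" for i in range(cfg.n_foreground)]


def simulate_promoters(
    cfg: PromoterSimConfig,
) -> tuple[PromoterSet, dict[str, list[tuple[str, int]]]]:
    """Random promoters with planted words; words overwrite, never insert.

    Truth maps gene -> list of (word, start position) where the start is in
    promoter coordinates (position -1 = base immediately upstream of TSS).
    """
    rng = np.random.default_rng([_PROM_TAG, cfg.seed])
    gene_ids = [f"PRM{i + 1:05d}" for i in range(cfg.n_genes)]
    seqs = rng.choice(4, size=(cfg.n_genes, cfg.length), p=list(cfg.base_probs))

    truth: dict[str, list[tuple[str, int]]] = {g: [] for g in gene_ids}
    base_code = {b: i for i, b in enumerate("ACGT")}
    for spec in cfg.plant_spec:
        lo, hi = cfg._window_bounds(spec)
        word_codes = np.array([base_code[b] for b in spec.word])
        for g, gene in enumerate(gene_ids):
            frac = spec.foreground_fraction if g < cfg.n_foreground else spec.background_fraction
            if rng.random() >= frac:
                continue
            # start index must keep the whole word inside the window
            start_pos = int(rng.integers(lo, hi - len(spec.word) + 2))
            start_idx = start_pos + cfg.length
            seqs[g, start_idx : start_idx + len(spec.word)] = word_codes
            truth[gene].append((spec.word, start_pos))

    records = {g: "".join(_BASES[row]) for g, row in zip(gene_ids, seqs)}
    return PromoterSet(records), truth


# ---------------------------------------------------------------------------
# study-set collections
# ---------------------------------------------------------------------------


def simulate_study_collection(
    n_experiments: int,
    universe: GeneSet,
    shared_core: int,
    per_set_size: int,
    seed: int = 0,
) -> list[GeneSet]:
    """Gene sets sharing a planted core, filled at random from the universe."""
    if n_experiments < 1:
        raise ValueError("need at least one experiment")
    if not 0 <= shared_core <= per_set_size <= len(universe):
        raise ValueError(
            "sizes must satisfy 0 <= shared_core <= per_set_size <= |universe|"
        )
    rng = np.random.default_rng([_SETS_TAG, seed])
    pool = np.array(sorted(universe.genes))
    core = set(rng.choice(pool, size=shared_core, replace=False).tolist())
    rest = np.array(sorted(universe.genes - core))
    sets = []
    for i in range(n_experiments):
        fill = rng.choice(rest, size=per_set_size - shared_core, replace=False)
        sets.append(GeneSet(f"experiment_{i + 1}", core | set(fill.tolist())))
    return sets
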