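"""Core data model and flat-file I/O.

Formats handled here: tab-delimited expression matrices with a matching
design sheet, upstream-region FASTA (gene ID is the first whitespace token
of the header, optionally carrying a ``.n`` splice-variant suffix), and
one-gene-per-line set lists.  Everything downstream consumes the dataclasses
defined in this module.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("abatrans")

TISSUES = ("guard_cell", "leaf")
GENOTYPES = ("wt", "gpa1", "agb1", "agb1_gpa1")
TREATMENTS = ("ABA", "control")

#: genotype -> Boolean (GPA1, AGB1) states: 1 = intact, 0 = knocked out.
GENOTYPE_STATES = {
    "wt": (1, 1),
    "gpa1": (0, 1),
    "agb1": (1, 0),
    "agb1_gpa1": (0, 0),
}

#: treatment -> Boolean hormone state.
TREATMENT_STATES = {"ABA": 1, "control": 0}

DIRECTIONS = ("induced", "repressed", "unsigned")


class FormatError(ValueError):
    """Structural problem in an input file (bad header, missing sample...)."""


class ParseError(ValueError):
    """Unparseable cell/record, reported with its location."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    tissue: str
    genotype: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise FormatError(f"unknown tissue {self.tissue!r} for sample {self.sample_id}")
        if self.genotype not in GENOTYPES:
            raise FormatError(f"unknown genotype {self.genotype!r} for sample {self.sample_id}")
        if self.treatment not in TREATMENTS:
            raise FormatError(f"unknown treatment {self.treatment!r} for sample {self.sample_id}")
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1 for sample {self.sample_id}")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.genotype, self.treatment)

    @property
    def state(self) -> tuple[int, int, int]:
        """(ABA, GPA1, AGB1) Boolean state of this sample."""
        gpa1, agb1 = GENOTYPE_STATES[self.genotype]
        return (TREATMENT_STATES[self.treatment], gpa1, agb1)


@dataclass
class SampleDesign:
    """Ordered sample sheet for one or both tissues."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate sample_id {dup!r} in design")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def tissues(self) -> set[str]:
        return {s.tissue for s in self.samples}

    def subset(self, **criteria: str) -> "SampleDesign":
        """Samples matching all keyword criteria, e.g. subset(genotype='wt')."""
        kept = [
            s for s in self.samples
            if all(getattr(s, k) == v for k, v in criteria.items())
        ]
        return SampleDesign(kept)

    def sample_indices(self, **criteria: str) -> list[int]:
        return [
            i for i, s in enumerate(self.samples)
            if all(getattr(s, k) == v for k, v in criteria.items())
        ]


@dataclass
class ExpressionMatrix:
    """genes x samples log2 intensities plus the sample design."""

    gene_ids: list[str]
    values: np.ndarray
    design: SampleDesign

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be 2-dimensional")
        if self.values.shape[0] != len(self.gene_ids):
            raise FormatError(
                f"{self.values.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.values.shape[1] != len(self.design):
            raise FormatError(
                f"{self.values.shape[1]} columns but {len(self.design)} design samples"
            )
        if np.isnan(self.values).any():
            g, s = map(int, np.argwhere(np.isnan(self.values))[0])
            raise ParseError(
                f"missing value at gene {self.gene_ids[g]!r}, "
                f"sample {self.design.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_samples(self, indices: list[int]) -> "ExpressionMatrix":
        sub = SampleDesign([self.design.samples[i] for i in indices])
        return ExpressionMatrix(list(self.gene_ids), self.values[:, indices], sub)

    def subset_tissue(self, tissue: str) -> "ExpressionMatrix":
        return self.subset_samples(self.design.sample_indices(tissue=tissue))


@dataclass
class GeneSet:
    name: str
    genes: set[str] = field(default_factory=set)
    direction: str = "unsigned"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise FormatError(f"unknown direction {self.direction!r}")
        self.genes = {g.upper() for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


@dataclass
class PromoterSet:
    """Upstream sequences keyed by gene ID; last base sits at position -1."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        self.records = {g.upper(): s.upper() for g, s in self.records.items()}
        for g, s in self.records.items():
            bad = set(s) - set("ACGTN")
            if bad:
                raise ParseError(f"invalid base(s) {sorted(bad)} in promoter of {g}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.records

    @property
    def lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.records.items()}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = ["sample_id", "tissue", "genotype", "treatment", "replicate"]


def read_design(path: str) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"design file {path} missing column(s) {missing}")
    samples = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError as exc:
            raise ParseError(
                f"non-integer replicate {row['replicate']!r} "
                f"for sample {row['sample_id']!r}"
            ) from exc
        samples.append(
            Sample(row["sample_id"], row["tissue"], row["genotype"], row["treatment"], rep)
        )
    return SampleDesign(samples)


def write_design(design: SampleDesign, path: str) -> None:
    rows = [
        (s.sample_id, s.tissue, s.genotype, s.treatment, s.replicate)
        for s in design.samples
    ]
    pd.DataFrame(rows, columns=_DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str, design_path: str) -> ExpressionMatrix:
    """Load a tab-delimited genes x samples matrix; columns reordered to the design."""
    design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    header = list(df.columns)
    for sid in design.sample_ids:
        if sid not in header:
            raise FormatError(f"design sample {sid!r} absent from matrix header")
    extra = [c for c in header if c not in set(design.sample_ids)]
    if extra:
        raise FormatError(f"matrix column {extra[0]!r} absent from design")
    df = df[design.sample_ids]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gene, row in df.iterrows():
            for sid, cell in row.items():
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"non-numeric value {cell!r} at gene {gene!r}, sample {sid!r}"
                    ) from None
        raise  # pragma: no cover - unreachable
    gene_ids = [str(g).upper() for g in df.index]
    return ExpressionMatrix(gene_ids, values, design)


def write_expression_matrix(matrix: ExpressionMatrix, path: str) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.gene_ids, columns=matrix.design.sample_ids
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


_SPLICE_SUFFIX = re.compile(r"\.\d+$")


def read_promoter_fasta(path: str) -> PromoterSet:
    """Read upstream FASTA; splice suffixes stripped, first duplicate wins."""
    records: dict[str, str] = {}
    n_dup = 0
    for rec in SeqIO.parse(path, "fasta"):
        gene = _SPLICE_SUFFIX.sub("", rec.id).upper()
        if gene in records:
            n_dup += 1
            continue
        records[gene] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    if n_dup:
        logger.warning("%d duplicate promoter record(s) dropped (first kept)", n_dup)
    return PromoterSet(records)


def write_promoter_fasta(promoters: PromoterSet, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for gene, seq in promoters.records.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_set(path: str, name: str | None = None, direction: str = "unsigned") -> GeneSet:
    """One gene ID per line; '#' comments allowed; empty file yields empty set."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split("\t")[0].upper())
    if not genes:
        logger.warning("gene set file %s contains no genes", path)
    return GeneSet(name or str(path), genes, direction)


def write_gene_set(gene_set: GeneSet, path: str) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_set.genes):
            fh.write(gene + "\n")
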