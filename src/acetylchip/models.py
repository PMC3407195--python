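"""Shared data types, enumerations, and run configuration.

Tabular data flows through the pipeline as pandas DataFrames whose column
schemas are declared here; the dataclasses give single-record semantics for
the same entities and are what the scalar operations accept and return.

Coordinate conventions: probe intervals are 0-based half-open internally and
in BED output. Gene coordinates are transcription-oriented: ``tss`` is the
transcriptional start (+1 in promoter-array convention) and ``tes`` the
transcriptional end, so ``tes < tss`` on the minus strand.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional

import yaml


class Condition(str, enum.Enum):
    """Genotype condition: wild-type or R6/2 transgenic."""

    WT = "WT"
    TG = "TG"


class ProbeType(str, enum.Enum):
    """Probe location relative to its gene, promoter-array annotation style."""

    PROMOTER = "Promoter"
    INSIDE = "Inside"
    DOWNSTREAM = "Downstream"
    DIVERGENT_PROMOTER = "DivergentPromoter"
    UNKNOWN = "Unknown"

    @property
    def display(self) -> str:
        if self is ProbeType.DIVERGENT_PROMOTER:
            return "Divergent Promoter"
        return self.value


#: Canonical rendering order for probe types in signature labels and tables.
PROBE_TYPE_ORDER: tuple = (
    ProbeType.PROMOTER,
    ProbeType.INSIDE,
    ProbeType.DOWNSTREAM,
    ProbeType.DIVERGENT_PROMOTER,
    ProbeType.UNKNOWN,
)


class Category(str, enum.Enum):
    """Differential-acetylation category of a gene, comparing TG with WT."""

    NOT_ACETYLATED_IN_TG = "NOT_ACETYLATED_IN_TG"
    HYPOACETYLATED_IN_TG = "HYPOACETYLATED_IN_TG"
    HYPERACETYLATED_IN_TG = "HYPERACETYLATED_IN_TG"
    ECTOPICALLY_ACETYLATED_IN_TG = "ECTOPICALLY_ACETYLATED_IN_TG"
    NOT_ACETYLATED = "NOT_ACETYLATED"
    UNCHANGED = "UNCHANGED"


#: The four categories of genes whose acetylation differs between genotypes.
DIFFERENTIAL_CATEGORIES: tuple = (
    Category.NOT_ACETYLATED_IN_TG,
    Category.HYPOACETYLATED_IN_TG,
    Category.HYPERACETYLATED_IN_TG,
    Category.ECTOPICALLY_ACETYLATED_IN_TG,
)

#: Categories aggregated as "decreased acetylation in TG".
DECREASED_CATEGORIES: tuple = (
    Category.NOT_ACETYLATED_IN_TG,
    Category.HYPOACETYLATED_IN_TG,
)


class DEStatus(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    UNCHANGED = "UNCHANGED"


class FormatError(ValueError):
    """A table or track file violates its declared format (e.g. missing column)."""


class TableParseError(ValueError):
    """A table cell could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ParameterizationError(ValueError):
    """Requested simulation parameters are jointly infeasible."""


def signature_label(types: Iterable[ProbeType]) -> str:
    """Render a set of probe types as a canonical binding-signature label.

    Singletons get an " Only" suffix ("Inside Only"); larger sets are joined
    in canonical order with " & " ("Promoter & Inside"). The empty set (an
    unbound gene) renders as "None".
    """
    types = set(types)
    if not types:
        return "None"
    names = [t.display for t in PROBE_TYPE_ORDER if t in types]
    if len(names) == 1:
        return names[0] + " Only"
    return " & ".join(names)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's location; ``tss``/``tes`` are transcription-oriented."""

    gene_id: str
    chromosome: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise FormatError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise FormatError(f"gene {self.gene_id}: '+' strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise FormatError(f"gene {self.gene_id}: '-' strand requires tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)


@dataclass(frozen=True)
class GeneBindingProfile:
    """Per-gene, per-condition summary of bound probes."""

    gene_id: str
    condition: Condition
    bound_probe_ids: FrozenSet[str] = frozenset()
    bound_signal_sum: float = 0.0
    signature: FrozenSet[ProbeType] = frozenset()

    @property
    def n_bound(self) -> int:
        return len(self.bound_probe_ids)

    @property
    def bound(self) -> bool:
        return self.n_bound >= 1

    @property
    def signature_label(self) -> str:
        return signature_label(self.signature)


@dataclass(frozen=True)
class CompositeScoreRecord:
    gene_id: str
    n_wt_bound: int
    n_tg_bound: int
    score: float
    category: Category


@dataclass(frozen=True)
class GeneExpressionRecord:
    gene_id: str
    condition: Condition
    probeset_values: tuple
    mean_expression: float
    expressed: bool


@dataclass
class ContingencyResult:
    """A 2x2 bound-by-expressed table with association statistics.

    Cells: a = bound & expressed, b = bound & not expressed,
    c = not bound & expressed, d = not bound & not expressed.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = float("nan")
    ci_level: float = 0.99
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_exact: float = float("nan")
    haldane: bool = False

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise FormatError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple:
        return (self.a + self.c, self.b + self.d)


@dataclass
class RunConfig:
    """Analysis thresholds and bookkeeping shared across pipeline stages.

    Defaults are the study's stated decision rules: probe bound at p <= 0.005,
    gene expressed at mean > 100, differential expression at fold >= 1.5 and
    p <= 0.05, association confidence level 99%.
    """

    p_threshold: float = 0.005
    expression_threshold: float = 100.0
    fold_threshold: float = 1.5
    de_p_threshold: float = 0.05
    ci_level: float = 0.99
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("p_threshold", "expression_threshold", "fold_threshold",
                     "de_p_threshold", "ci_level"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be strictly positive")
        if not 0 < self.ci_level < 1:
            raise FormatError("ci_level must lie in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise FormatError("p_threshold must lie in (0, 1)")

    def meta(self) -> dict:
        """Key-value pairs recorded in every output file header."""
        return {
            "p_threshold": self.p_threshold,
            "expression_threshold": self.expression_threshold,
            "fold_threshold": self.fold_threshold,
            "de_p_threshold": self.de_p_threshold,
            "ci_level": self.ci_level,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
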