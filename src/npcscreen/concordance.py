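"""Direction-concordance classification of treatment DEGs against a genotype signature.

A differential-expression contrast table pairs each gene with a signed fold
change and an adjusted p-value.  After thresholding (p_adj <= p_max and
|FC| >= fc_min, boundaries inclusive), each treatment DEG is classified
against the genotype (e.g. trisomy-vs-euploid) DEG set purely by direction:

* absent from the genotype set            -> novel
* opposite fold-change sign               -> corrected (sub-bucketed by the
  treatment direction into corrected_down / corrected_up)
* same fold-change sign                   -> worsened

Magnitude plays no role in the call — "corrected" means the treatment moves
expression against the genotype dysregulation, not that it restores any
particular level.  Reported percentages use the overlap count as the
denominator for corrected/worsened and the full treatment DEG count for
novel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import IntegrityError, SchemaError, SignAmbiguityError

#: Per-molecule fold-change cut-offs used in the published screen
#: (adjusted p <= 0.05 throughout; ``None`` = no fold-change cut-off).
DEFAULT_THRESHOLDS: dict[str, "ThresholdSpec"] = {}

CONTRAST_COLUMNS = ["gene_id", "log2fc", "fold_change", "p_adj", "chromosome"]


class ThresholdSpec(BaseModel):
    """DEG thresholds: adjusted-p ceiling and optional linear |FC| floor."""

    model_config = ConfigDict(extra="forbid")

    p_adj_max: float = Field(default=0.05, gt=0, le=1)
    abs_fc_min: float | None = Field(default=1.5, ge=1)


DEFAULT_THRESHOLDS.update(
    {
        "genotype": ThresholdSpec(p_adj_max=0.05, abs_fc_min=1.5),
        "fasudil": ThresholdSpec(p_adj_max=0.05, abs_fc_min=1.5),
        "sphingosine": ThresholdSpec(p_adj_max=0.05, abs_fc_min=1.2),
        "egcg": ThresholdSpec(p_adj_max=0.05, abs_fc_min=1.1),
        "apigenin": ThresholdSpec(p_adj_max=0.05, abs_fc_min=1.1),
        "isoxsuprine": ThresholdSpec(p_adj_max=0.05, abs_fc_min=None),
    }
)


@dataclass(frozen=True)
class DegRecord:
    """One gene's differential-expression result in a contrast.

    ``fold_change`` is the signed linear fold change (sign = direction,
    |fold_change| = 2**|log2fc| >= 1); ``log2fc`` its base-2 logarithm with
    the same sign.
    """

    gene_id: str
    log2fc: float
    fold_change: float
    p_adj: float
    chromosome: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_adj <= 1.0):
            raise ValueError(f"gene {self.gene_id}: p_adj {self.p_adj} outside [0, 1]")

    @classmethod
    def from_log2fc(
        cls, gene_id: str, log2fc: float, p_adj: float, chromosome: str = ""
    ) -> "DegRecord":
        fc = math.copysign(2.0 ** abs(log2fc), log2fc) if log2fc != 0 else 0.0
        return cls(gene_id, float(log2fc), fc, float(p_adj), chromosome)

    @classmethod
    def from_fold_change(
        cls, gene_id: str, fold_change: float, p_adj: float, chromosome: str = ""
    ) -> "DegRecord":
        l2 = (
            math.copysign(math.log2(abs(fold_change)), fold_change)
            if fold_change != 0
            else 0.0
        )
        return cls(gene_id, l2, float(fold_change), float(p_adj), chromosome)

    @property
    def direction(self) -> int:
        """+1 for upregulated, -1 for downregulated; zero FC is ambiguous."""
        if self.fold_change == 0:
            raise SignAmbiguityError(f"gene {self.gene_id} has a zero fold change")
        return 1 if self.fold_change > 0 else -1


@dataclass
class ContrastTable:
    """A named collection of DegRecords with unique gene ids."""

    name: str
    records: list[DegRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise IntegrityError(f"duplicate gene id {rec.gene_id!r} in table {self.name!r}")
            seen.add(rec.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_gene(self) -> dict[str, DegRecord]:
        return {rec.gene_id: rec for rec in self.records}

    def gene_ids(self) -> set[str]:
        return {rec.gene_id for rec in self.records}

    @classmethod
    def from_arrays(
        cls,
        name: str,
        gene_ids: Sequence[str],
        log2fc: Sequence[float],
        p_adj: Sequence[float],
        chromosome: Sequence[str] | None = None,
    ) -> "ContrastTable":
        chrom = chromosome if chromosome is not None else [""] * len(gene_ids)
        return cls(
            name=name,
            records=[
                DegRecord.from_log2fc(str(g), float(l), float(p), str(c))
                for g, l, p, c in zip(gene_ids, log2fc, p_adj, chrom)
            ],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "log2fc": r.log2fc,
                    "fold_change": r.fold_change,
                    "p_adj": r.p_adj,
                    "chromosome": r.chromosome,
                }
                for r in self.records
            ],
            columns=CONTRAST_COLUMNS,
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def read_contrast_table(
    path,
    column_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> ContrastTable:
    """Read a TSV/CSV contrast table into a ContrastTable.

    Required columns (rename via ``column_map``, canonical -> actual):
    ``gene_id``, ``p_adj``, and at least one of ``log2fc`` / ``fold_change``
    (the missing one is derived: |FC| = 2**|log2fc|, shared sign).
    ``chromosome`` is optional.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if "gene_id" not in df.columns or "p_adj" not in df.columns:
        raise SchemaError(
            f"{path.name}: need columns gene_id and p_adj; available: {list(df.columns)}"
        )
    has_l2 = "log2fc" in df.columns
    has_fc = "fold_change" in df.columns
    if not has_l2 and not has_fc:
        raise SchemaError(
            f"{path.name}: need log2fc or fold_change; available: {list(df.columns)}"
        )
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise IntegrityError(f"{path.name}: duplicate gene id {dup.iloc[0]!r}")
    chrom = df["chromosome"].fillna("").astype(str) if "chromosome" in df.columns else [""] * len(df)
    records = []
    for i, row in df.iterrows():
        c = chrom[i] if isinstance(chrom, list) else chrom.iloc[i]
        if has_l2:
            rec = DegRecord.from_log2fc(str(row["gene_id"]), float(row["log2fc"]), float(row["p_adj"]), c)
        else:
            rec = DegRecord.from_fold_change(
                str(row["gene_id"]), float(row["fold_change"]), float(row["p_adj"]), c
            )
        records.append(rec)
    return ContrastTable(name=name or path.stem, records=records)


def apply_thresholds(table: ContrastTable, spec: ThresholdSpec) -> ContrastTable:
    """Keep records with p_adj <= p_adj_max and |FC| >= abs_fc_min (inclusive).

    The fold-change condition is vacuous when ``abs_fc_min`` is None.
    """
    kept = [
        r
        for r in table.records
        if r.p_adj <= spec.p_adj_max
        and (spec.abs_fc_min is None or abs(r.fold_change) >= spec.abs_fc_min)
    ]
    return ContrastTable(name=table.name, records=kept)


@dataclass
class ConcordancePartition:
    """Four-way direction-concordance partition of a treatment DEG set.

    The four gene sets are disjoint and their union is the treatment DEG
    set; ``corrected_down``/``corrected_up`` are bucketed by the *treatment*
    fold-change sign.
    """

    treatment_name: str
    genotype_name: str
    corrected_down: set[str]
    corrected_up: set[str]
    worsened: set[str]
    novel: set[str]

    @property
    def n_overlap(self) -> int:
        return len(self.corrected_down) + len(self.corrected_up) + len(self.worsened)

    @property
    def n_corrected(self) -> int:
        return len(self.corrected_down) + len(self.corrected_up)

    @property
    def n_treatment_degs(self) -> int:
        return self.n_overlap + len(self.novel)

    @property
    def frac_corrected(self) -> float | None:
        return self.n_corrected / self.n_overlap if self.n_overlap else None

    def category_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name in ("corrected_down", "corrected_up", "worsened", "novel"):
            for g in getattr(self, name):
                out[g] = name
        return out

    def summary(self) -> str:
        rep = concordance_report(self)
        lines = [
            f"Concordance of {self.treatment_name!r} against {self.genotype_name!r}",
            f"  treatment DEGs : {rep['n_treatment_degs']}",
            f"  overlap        : {rep['n_overlap']}",
        ]
        for key, n_key in (
            ("corrected", "n_corrected"),
            ("worsened", "n_worsened"),
            ("novel", "n_novel"),
        ):
            pct = rep[f"pct_{key}"]
            pct_s = "undefined" if pct is None else f"{pct}%"
            lines.append(f"  {key:<14} : {rep[n_key]} ({pct_s})")
        lines.append(
            f"  corrected split: {rep['n_corrected_down']} down / {rep['n_corrected_up']} up"
        )
        return "\n".join(lines)


def classify_concordance(
    treatment: ContrastTable, genotype: ContrastTable
) -> ConcordancePartition:
    """Partition treatment DEGs by direction against the genotype DEG set.

    Both tables must already be thresholded.  A zero fold change in a record
    consulted by the rule raises :class:`SignAmbiguityError`.
    """
    geno = genotype.by_gene()
    corrected_down: set[str] = set()
    corrected_up: set[str] = set()
    worsened: set[str] = set()
    novel: set[str] = set()
    for rec in treatment.records:
        g = geno.get(rec.gene_id)
        if g is None:
            novel.add(rec.gene_id)
        elif rec.direction != g.direction:
            (corrected_down if rec.direction < 0 else corrected_up).add(rec.gene_id)
        else:
            worsened.add(rec.gene_id)
    return ConcordancePartition(
        treatment_name=treatment.name,
        genotype_name=genotype.name,
        corrected_down=corrected_down,
        corrected_up=corrected_up,
        worsened=worsened,
        novel=novel,
    )


@dataclass(frozen=True)
class SharedResponse:
    """Gene overlap between two thresholded treatment contrasts."""

    shared: frozenset[str]
    same_direction: frozenset[str]
    larger_in_a: frozenset[str]  # same-direction genes with the larger |FC| in table a


def shared_response(a: ContrastTable, b: ContrastTable) -> SharedResponse:
    """Intersection of two DEG sets with direction agreement and |FC| dominance.

    ``shared`` is the gene-id intersection; ``same_direction`` the shared
    genes with equal fold-change sign; ``larger_in_a`` the same-direction
    genes whose |fold change| is strictly larger in the first table.
    """
    ra, rb = a.by_gene(), b.by_gene()
    shared = set(ra) & set(rb)
    same = {g for g in shared if ra[g].direction == rb[g].direction}
    larger = {g for g in same if abs(ra[g].fold_change) > abs(rb[g].fold_change)}
    return SharedResponse(
        shared=frozenset(shared),
        same_direction=frozenset(same),
        larger_in_a=frozenset(larger),
    )


def filter_by_chromosome(
    genes: Iterable[str], table: ContrastTable, chromosome: str
) -> tuple[set[str], int]:
    """Subset of ``genes`` whose table annotation matches ``chromosome``.

    Genes with no annotation in the table (missing record or empty
    chromosome field) are excluded with a warning; the count of such gaps
    is returned alongside the kept set.
    """
    recs = table.by_gene()
    kept: set[str] = set()
    gaps = 0
    for g in genes:
        rec = recs.get(g)
        if rec is None or rec.chromosome == "":
            gaps += 1
            continue
        if rec.chromosome == chromosome:
            kept.add(g)
    if gaps:
        warnings.warn(
            f"{gaps} queried gene(s) lack a chromosome annotation in table "
            f"{table.name!r} and were excluded",
            stacklevel=2,
        )
    return kept, gaps


def _pct(numerator: int, denominator: int) -> float | None:
    return round(100.0 * numerator / denominator, 1) if denominator else None


def concordance_report(partition: ConcordancePartition) -> dict:
    """Counts, one-decimal percentages and gene lists for a partition.

    Corrected and worsened percentages are of the overlap count; the novel
    percentage is of the total treatment DEG count.  Percentages on an
    empty denominator are reported as None, never 0/0.
    """
    n_over = partition.n_overlap
    n_tot = partition.n_treatment_degs
    return {
        "treatment": partition.treatment_name,
        "genotype": partition.genotype_name,
        "n_treatment_degs": n_tot,
        "n_overlap": n_over,
        "n_corrected": partition.n_corrected,
        "n_corrected_down": len(partition.corrected_down),
        "n_corrected_up": len(partition.corrected_up),
        "n_worsened": len(partition.worsened),
        "n_novel": len(partition.novel),
        "pct_corrected": _pct(partition.n_corrected, n_over),
        "pct_worsened": _pct(len(partition.worsened), n_over),
        "pct_novel": _pct(len(partition.novel), n_tot),
        "genes": {
            "corrected_down": sorted(partition.corrected_down),
            "corrected_up": sorted(partition.corrected_up),
            "worsened": sorted(partition.worsened),
            "novel": sorted(partition.novel),
        },
    }


def partition_to_dataframe(
    partition: ConcordancePartition,
    treatment: ContrastTable | None = None,
    genotype: ContrastTable | None = None,
) -> pd.DataFrame:
    """Long-format gene list (gene_id, category, genotype_fc, treatment_fc)."""
    t_rec = treatment.by_gene() if treatment is not None else {}
    g_rec = genotype.by_gene() if genotype is not None else {}
    rows = []
    for gene, cat in sorted(partition.category_of().items()):
        rows.append(
            {
                "gene_id": gene,
                "category": cat,
                "genotype_fc": g_rec[gene].fold_change if gene in g_rec else np.nan,
                "treatment_fc": t_rec[gene].fold_change if gene in t_rec else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "category", "genotype_fc", "treatment_fc"])
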