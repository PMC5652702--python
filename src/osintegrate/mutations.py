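"""Gene-level aggregation of impact-annotated somatic variants and phenotype set algebra."""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

#: severity ordering, ascending
IMPACT_LEVELS = ("modifier", "low", "moderate", "high")
_IMPACT_RANK = {name: i for i, name in enumerate(IMPACT_LEVELS)}

__all__ = [
    "IMPACT_LEVELS",
    "MutationRecord",
    "GeneMutationMatrix",
    "SetPartition",
    "aggregate",
    "phenotype_sets",
    "family_clusters",
]


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    specimen: str
    gene: str
    variant_id: str
    impact: str

    def __post_init__(self) -> None:
        if self.impact not in _IMPACT_RANK:
            raise ValueError(
                f"unknown impact {self.impact!r}; expected one of {IMPACT_LEVELS}"
            )


@dataclasses.dataclass
class GeneMutationMatrix:
    """Per-specimen, per-gene variant counts split by impact class.

    ``table`` is indexed by (specimen, gene) with one count column per impact
    class; a gene may carry variants of several impacts at once.
    """

    table: pd.DataFrame

    @property
    def specimens(self) -> set:
        return set(self.table.index.get_level_values("specimen"))

    @property
    def genes(self) -> set:
        return set(self.table.index.get_level_values("gene"))

    def max_impact(self) -> pd.Series:
        """Highest impact class per (specimen, gene); defined iff counts > 0."""
        ranks = pd.Series(-1, index=self.table.index, dtype=int)
        for i, level in enumerate(IMPACT_LEVELS):
            ranks[self.table[level] > 0] = i
        out = ranks[ranks >= 0].map(lambda i: IMPACT_LEVELS[i])
        out.name = "max_impact"
        return out

    def mutated_genes(self, specimen: str, min_impact: str = "modifier") -> set:
        """Genes of ``specimen`` whose max impact is >= ``min_impact``."""
        threshold = _impact_rank(min_impact)
        if specimen not in self.specimens:
            return set()
        sub = self.table.xs(specimen, level="specimen")
        keep = pd.Series(False, index=sub.index)
        for level in IMPACT_LEVELS[threshold:]:
            keep |= sub[level] > 0
        return set(sub.index[keep])


@dataclasses.dataclass
class SetPartition:
    """Disjoint Venn regions of mutated genes across the two phenotypes.

    In ``all-specimens`` membership mode a gene can be mutated somewhere yet
    belong to neither phenotype; those genes land in ``unassigned`` so the
    regions always partition the full mutated-gene universe.
    """

    aggressive_only: set
    curable_only: set
    shared_all: set
    unassigned: set
    mode: str
    min_impact: str

    def region_counts(self) -> dict:
        return {
            "aggressive_only": len(self.aggressive_only),
            "curable_only": len(self.curable_only),
            "shared_all": len(self.shared_all),
            "unassigned": len(self.unassigned),
        }

    def all_genes(self) -> set:
        return self.aggressive_only | self.curable_only | self.shared_all | self.unassigned


def _impact_rank(impact: str) -> int:
    if impact not in _IMPACT_RANK:
        raise ValueError(f"unknown impact {impact!r}; expected one of {IMPACT_LEVELS}")
    return _IMPACT_RANK[impact]


def aggregate(records: Iterable) -> GeneMutationMatrix:
    """Aggregate validated variant records to per-specimen, per-gene impact counts.

    Accepts an iterable of :class:`MutationRecord` or a DataFrame with columns
    specimen, gene, variant_id, impact.  Duplicate variant ids within a
    specimen and unknown impact labels are rejected with the offending row.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"specimen", "gene", "variant_id", "impact"}
        if not required.issubset(df.columns):
            raise ValueError(f"mutation table must have columns {sorted(required)}")
    else:
        df = pd.DataFrame(
            [(r.specimen, r.gene, r.variant_id, r.impact) for r in records],
            columns=["specimen", "gene", "variant_id", "impact"],
        )
    if df.empty:
        empty = pd.DataFrame(
            columns=list(IMPACT_LEVELS),
            index=pd.MultiIndex.from_arrays([[], []], names=["specimen", "gene"]),
            dtype=int,
        )
        return GeneMutationMatrix(table=empty)

    bad = ~df["impact"].isin(IMPACT_LEVELS)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"unknown impact {df.loc[row, 'impact']!r} at row {row}; "
            f"expected one of {IMPACT_LEVELS}"
        )
    dup = df.duplicated(subset=["specimen", "variant_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValueError(f"duplicate variant_id within a specimen at row {row}")

    counts = (
        df.groupby(["specimen", "gene", "impact"], sort=True)
        .size()
        .unstack("impact", fill_value=0)
        .reindex(columns=list(IMPACT_LEVELS), fill_value=0)
        .astype(int)
    )
    counts.index.names = ["specimen", "gene"]
    return GeneMutationMatrix(table=counts)


def phenotype_sets(
    m: GeneMutationMatrix,
    phenotype: Mapping[str, str],
    min_impact: str = "modifier",
    mode: str = "all",
) -> SetPartition:
    """Venn regions of mutated genes for aggressive vs curable specimens.

    ``mode='all'`` counts a gene as belonging to a phenotype only when it is
    mutated (max impact >= ``min_impact``) in every specimen of that
    phenotype; ``mode='any'`` requires a single specimen.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    _impact_rank(min_impact)
    unlabeled = m.specimens - set(phenotype)
    if unlabeled:
        raise ValueError(f"specimens without phenotype label: {sorted(unlabeled)}")

    spec_by_pheno = {"aggressive": [], "curable": []}
    for spec, ph in phenotype.items():
        if ph not in spec_by_pheno:
            raise ValueError(f"unknown phenotype {ph!r} for specimen {spec!r}")
        spec_by_pheno[ph].append(spec)
    for ph, specs in spec_by_pheno.items():
        if not specs:
            log.warning("phenotype %r has zero specimens; its regions are empty", ph)

    per_spec = {s: m.mutated_genes(s, min_impact) for s in phenotype}
    membership = {}
    for ph, specs in spec_by_pheno.items():
        sets = [per_spec[s] for s in specs]
        if not sets:
            membership[ph] = set()
        elif mode == "all":
            membership[ph] = set.intersection(*sets)
        else:
            membership[ph] = set.union(*sets)

    everything = set().union(*per_spec.values()) if per_spec else set()
    agg, cur = membership["aggressive"], membership["curable"]
    return SetPartition(
        aggressive_only=agg - cur,
        curable_only=cur - agg,
        shared_all=agg & cur,
        unassigned=everything - agg - cur,
        mode=mode,
        min_impact=min_impact,
    )


_FAMILY_SUFFIX = re.compile(r"\d+[A-Za-z]?$")


def default_family(gene: str) -> str:
    """Heuristic family symbol: strip a trailing numeric (+letter) suffix."""
    stem = _FAMILY_SUFFIX.sub("", gene)
    return stem if stem else gene


def family_clusters(
    genes: Iterable[str],
    family_map: Mapping[str, str] | None = None,
) -> list[tuple[str, int]]:
    """Count genes per family, sorted by count descending then family name.

    Without an explicit map, families come from :func:`default_family`.
    With a (possibly partial) map, unmapped genes form singleton families of
    themselves.
    """
    counts: dict[str, int] = {}
    for gene in genes:
        if family_map is not None:
            fam = family_map.get(gene, gene)
        else:
            fam = default_family(gene)
        counts[fam] = counts.get(fam, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
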