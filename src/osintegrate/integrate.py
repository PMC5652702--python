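"""Pathway over-representation of mutated + differentially expressed genes,
filtered for pathways containing at least one target of an effective drug.

Evidence defaults to the *union* of significant-DE and mutated genes;
aberrantly expressed genes (|log2FC| > 1 but not significant) inform node
annotation only, never the test.  Prioritization keeps pathways with
unadjusted p < p_max that contain >= 1 effective-drug target.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

from .diffexpr import DEResult
from .mutations import GeneMutationMatrix, IMPACT_LEVELS, _impact_rank
from .stats import hypergeom_upper_tail

log = logging.getLogger(__name__)

__all__ = [
    "PathwayCollection",
    "EvidenceSet",
    "PrioritizedPathway",
    "build_evidence",
    "enrich",
    "prioritize",
    "annotate_nodes",
]


@dataclasses.dataclass
class PathwayCollection:
    """Named gene sets plus the background universe they are tested against."""

    pathways: dict  # id -> (description, frozenset of genes)
    universe: frozenset

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} is empty")
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(
                    f"pathway {pid!r} has genes outside the universe: {sorted(extra)[:5]}"
                )

    def genes(self, pid: str) -> frozenset:
        return self.pathways[pid][1]

    def __len__(self) -> int:
        return len(self.pathways)


@dataclasses.dataclass
class EvidenceSet:
    specimen: str
    de_genes: set
    aberrant_genes: set
    mutated_genes: set
    drug_target_genes: set
    de_direction: dict = dataclasses.field(default_factory=dict)  # gene -> up/down
    cnv_calls: dict = dataclasses.field(default_factory=dict)  # gene -> direction

    def __post_init__(self) -> None:
        overlap = self.de_genes & self.aberrant_genes
        if overlap:
            raise ValueError(f"genes both DE and aberrant: {sorted(overlap)[:5]}")

    def test_genes(self, mode: str = "union") -> set:
        if mode == "union":
            return self.de_genes | self.mutated_genes
        if mode == "intersection":
            return self.de_genes & self.mutated_genes
        raise ValueError("evidence mode must be 'union' or 'intersection'")


@dataclasses.dataclass
class PrioritizedPathway:
    pathway_id: str
    description: str
    overlap_k: int
    pathway_size_K: int
    evidence_n: int
    universe_N: int
    p: float
    druggable: bool
    drug_targets_in_pathway: set
    overlap_genes: set
    rank: int | None = None


def build_evidence(
    de: DEResult,
    muts: GeneMutationMatrix,
    drug_targets: Iterable[str],
    specimen: str,
    min_impact: str = "moderate",
    cnv_calls: Mapping[str, str] | None = None,
    aberrant_abs_log2fc: float = 1.0,
) -> EvidenceSet:
    """Collect the per-specimen evidence feeding enrichment and annotation.

    de_genes come from the significant calls; aberrant_genes have
    |log2FC| > ``aberrant_abs_log2fc`` without significance; mutated_genes
    have max impact >= ``min_impact`` in ``specimen``; drug_target_genes are
    passed through (see :func:`osintegrate.drugscreen.effective_target_genes`).
    """
    table = de.table
    de_genes = set(table.index[table["significant"]])
    aberrant = set(
        table.index[
            (~table["significant"])
            & (table["log2_fold_change"].abs() > aberrant_abs_log2fc)
        ]
    )
    direction = {
        g: ("up" if table.at[g, "log2_fold_change"] > 0 else "down") for g in de_genes
    }
    if specimen not in muts.specimens:
        log.warning("specimen %r absent from mutation matrix; mutated set empty", specimen)
        mutated = set()
    else:
        mutated = muts.mutated_genes(specimen, min_impact)
    return EvidenceSet(
        specimen=specimen,
        de_genes=de_genes,
        aberrant_genes=aberrant,
        mutated_genes=mutated,
        drug_target_genes=set(drug_targets),
        de_direction=direction,
        cnv_calls=dict(cnv_calls or {}),
    )


def enrich(
    ev: EvidenceSet,
    pw: PathwayCollection,
    mode: str = "union",
) -> list[PrioritizedPathway]:
    """Hypergeometric upper-tail over-representation of the evidence gene set.

    Evidence genes outside the universe are dropped (logged).  Results are
    sorted by p ascending, then pathway size, then id; ranks are left unset
    until :func:`prioritize`.
    """
    evidence = ev.test_genes(mode)
    dropped = evidence - pw.universe
    if dropped:
        log.warning(
            "%d evidence gene(s) outside the universe dropped: %s",
            len(dropped), sorted(dropped)[:5],
        )
    evidence = evidence & pw.universe
    n = len(evidence)
    big_n = len(pw.universe)
    results = []
    for pid in sorted(pw.pathways):
        desc, genes = pw.pathways[pid]
        overlap = evidence & genes
        k, big_k = len(overlap), len(genes)
        p = hypergeom_upper_tail(k, big_n, big_k, n)
        targets = ev.drug_target_genes & genes
        results.append(
            PrioritizedPathway(
                pathway_id=pid,
                description=desc,
                overlap_k=k,
                pathway_size_K=big_k,
                evidence_n=n,
                universe_N=big_n,
                p=p,
                druggable=bool(targets),
                drug_targets_in_pathway=targets,
                overlap_genes=overlap,
            )
        )
    results.sort(key=lambda r: (r.p, r.pathway_size_K, r.pathway_id))
    return results


def prioritize(
    results: Iterable[PrioritizedPathway],
    p_max: float = 0.05,
) -> list[PrioritizedPathway]:
    """Keep pathways with p < p_max (strict) containing >= 1 drug target; rank them."""
    kept = [
        dataclasses.replace(r)
        for r in results
        if r.p < p_max and r.druggable
    ]
    kept.sort(key=lambda r: (r.p, r.pathway_size_K, r.pathway_id))
    for i, r in enumerate(kept, start=1):
        r.rank = i
    if not kept:
        log.info("no pathway passed p < %g with a drug target", p_max)
    return kept


def annotate_nodes(
    pathway_genes: Iterable[str],
    ev: EvidenceSet,
    muts: GeneMutationMatrix,
) -> dict:
    """Per-gene annotation records for rendering a prioritized pathway.

    Category precedence: drug_target > mutated > de_under/de_over > aberrant
    > none.  Mutation multiplicity per impact class is preserved regardless
    of category, and CNV direction is attached when provided.
    """
    table = None
    if ev.specimen in muts.specimens:
        table = muts.table.xs(ev.specimen, level="specimen")
    out = {}
    for gene in sorted(set(pathway_genes)):
        n_mut = {level: 0 for level in IMPACT_LEVELS}
        if table is not None and gene in table.index:
            for level in IMPACT_LEVELS:
                n_mut[level] = int(table.at[gene, level])
        if gene in ev.drug_target_genes:
            category = "drug_target"
        elif gene in ev.mutated_genes:
            category = "mutated"
        elif gene in ev.de_genes:
            category = "de_over" if ev.de_direction.get(gene) == "up" else "de_under"
        elif gene in ev.aberrant_genes:
            category = "aberrant"
        else:
            category = "none"
        out[gene] = {
            "category": category,
            "n_mutations": n_mut,
            "cnv": ev.cnv_calls.get(gene, "neutral"),
        }
    return out
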