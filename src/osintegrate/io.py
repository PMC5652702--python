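"""Readers and writers for every table format the pipeline touches.

Conventions: TSV for gene-keyed tables, CSV for dose-response data, GMT for
pathway collections, JSON for ground truth / manifests / annotations.  All
writers emit a header row; readers verify it.  UTF-8, Unix newlines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .diffexpr import CountMatrix, DEResult
from .integrate import PathwayCollection
from .simulate import GroundTruth

log = logging.getLogger(__name__)


def _check_columns(df: pd.DataFrame, required: set, path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")


# -- counts + groups --------------------------------------------------------


def write_counts(m: CountMatrix, path) -> None:
    out = m.counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_counts(path, groups: pd.Series) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene":
        raise ValueError(f"{path}: first column must be named 'gene'")
    return CountMatrix(counts=df, groups=groups)


def write_groups(groups: pd.Series, path) -> None:
    out = groups.rename("group").rename_axis("sample").reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, {"sample", "group"}, path)
    return pd.Series(df["group"].values, index=df["sample"].values)


# -- mutations --------------------------------------------------------------

MUTATION_COLUMNS = ["specimen", "gene", "variant_id", "impact"]


def write_mutations(table: pd.DataFrame, path) -> None:
    table[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, set(MUTATION_COLUMNS), path)
    return df[MUTATION_COLUMNS]


# -- GMT --------------------------------------------------------------------


def read_gmt(path) -> PathwayCollection:
    """Standard GMT: tab-separated id, description, then member genes.

    Duplicate genes within a line are de-duplicated with a warning; lines
    with fewer than 3 fields and empty files are rejected with the line
    number.  The universe is the union of all pathway genes.
    """
    pathways = {}
    universe = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            pid, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                log.warning("%s:%d: %d duplicate gene(s) in pathway %s",
                            path, lineno, len(genes) - len(unique), pid)
            pathways[pid] = (desc, frozenset(unique))
            universe.update(unique)
    if not pathways:
        raise ValueError(f"{path}: empty GMT file")
    return PathwayCollection(pathways=pathways, universe=frozenset(universe))


def write_gmt(pw: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid in sorted(pw.pathways):
            desc, genes = pw.pathways[pid]
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


# -- drug screen ------------------------------------------------------------


def write_target_matrix(matrix: pd.DataFrame, path) -> None:
    """Long form: compound, kinase, inhibition (non-zero entries only)."""
    long = matrix.stack().rename("inhibition").rename_axis(
        ["compound", "kinase"]
    ).reset_index()
    long = long[long["inhibition"] > 0]
    long.to_csv(path, sep="\t", index=False)


def read_target_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, {"compound", "kinase", "inhibition"}, path)
    return (
        df.pivot_table(index="compound", columns="kinase", values="inhibition",
                       fill_value=0.0, aggfunc="first")
    )


DOSE_COLUMNS = ["compound", "culture", "concentration_nM", "replicate", "viability"]


def write_dose_response(data: pd.DataFrame, path) -> None:
    data[DOSE_COLUMNS].to_csv(path, index=False)


def read_dose_response(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, set(DOSE_COLUMNS), path)
    return df[DOSE_COLUMNS]


def write_fits(fits, path) -> None:
    rows = [
        {
            "compound": f.compound,
            "culture": f.culture,
            "ic50_nM": f.ic50,
            "ic50_display": f.ic50_display,
            "r2": f.r_squared,
            "hill": f.hill,
            "top": f.top,
            "bottom": f.bottom,
            "converged": f.converged,
            "censored": f.censored,
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_target_scores(scores, path) -> None:
    rows = [
        {
            "kinase": s.kinase,
            "n_effective_hitting": s.n_effective_hitting,
            "n_panel_hitting": s.n_panel_hitting,
            "enrichment_p": s.enrichment_p,
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- DE table ---------------------------------------------------------------


def write_de(result: DEResult, path) -> None:
    out = result.table.copy()
    out["mode"] = result.mode_used
    out.to_csv(path, sep="\t")


def read_de(path) -> DEResult:
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"log2_fold_change", "p_common", "p_tagwise", "fdr_common",
                "fdr_tagwise", "significant", "mode"}
    _check_columns(df, required, path)
    mode = df["mode"].iloc[0]
    return DEResult(table=df.drop(columns="mode"), mode_used=mode, alpha=0.05)


# -- pathway results --------------------------------------------------------


def write_ranked_pathways(results, path) -> None:
    rows = [
        {
            "rank": r.rank if r.rank is not None else "",
            "pathway_id": r.pathway_id,
            "description": r.description,
            "overlap_k": r.overlap_k,
            "pathway_size_K": r.pathway_size_K,
            "evidence_n": r.evidence_n,
            "universe_N": r.universe_N,
            "p": r.p,
            "druggable": r.druggable,
            "drug_targets": ";".join(sorted(r.drug_targets_in_pathway)),
            "overlap_genes": ";".join(sorted(r.overlap_genes)),
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["rank", "pathway_id", "description", "overlap_k",
                 "pathway_size_K", "evidence_n", "universe_N", "p",
                 "druggable", "drug_targets", "overlap_genes"],
    ).to_csv(path, sep="\t", index=False)


def write_annotations(annotations: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(annotations, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- truth / json -----------------------------------------------------------


def write_truth(truth: GroundTruth, path) -> None:
    payload = dataclasses.asdict(truth)
    payload["mutated_driver_genes"] = sorted(truth.mutated_driver_genes)
    payload["effective_compounds"] = sorted(truth.effective_compounds)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    payload["mutated_driver_genes"] = set(payload["mutated_driver_genes"])
    payload["effective_compounds"] = set(payload["effective_compounds"])
    return GroundTruth(**payload)


# -- cnv / phenotypes -------------------------------------------------------


def read_cnv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, {"gene", "direction"}, path)
    bad = ~df["direction"].isin(["amplified", "deleted", "neutral"])
    if bad.any():
        raise ValueError(f"{path}: unknown CNV direction {df['direction'][bad].iloc[0]!r}")
    return dict(zip(df["gene"], df["direction"]))


def read_phenotypes(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, {"specimen", "phenotype"}, path)
    return dict(zip(df["specimen"], df["phenotype"]))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
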