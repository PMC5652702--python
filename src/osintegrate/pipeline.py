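"""Stage orchestration: simulate? -> de -> mutations -> screen -> integrate.

Every run writes its outputs plus a manifest (input hashes, parameters,
package version, seed) so results are attributable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .diffexpr import call_de, estimate_dispersion, exact_test
from .drugscreen import (
    call_efficacy,
    effective_target_genes,
    fit_screen,
    target_deconvolution,
)
from .integrate import annotate_nodes, build_evidence, enrich, prioritize
from .mutations import aggregate
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Parameters for a full pipeline run (synthetic or file-based inputs)."""

    outdir: str = "osintegrate_out"
    seed: int = 0
    # stage parameters
    alpha: float = 0.05
    shrinkage_weight: float = 10.0
    ic50_max: float = 1000.0
    r2_min: float = 0.6
    ci_threshold: float = 0.7
    p_max: float = 0.05
    min_impact: str = "moderate"
    evidence_mode: str = "union"
    inhibition_min: float = 0.5
    specimen: str | None = None  # default: first aggressive sample
    # input files (all optional; missing ones are simulated)
    counts: str | None = None
    groups: str | None = None
    mutations: str | None = None
    gmt: str | None = None
    targets: str | None = None
    dose_response: str | None = None
    cnv: str | None = None
    sim: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, lo, hi in (("alpha", 0, 1), ("p_max", 0, 1), ("r2_min", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v}")
        if self.ic50_max <= 0 or self.ci_threshold <= 0:
            raise ValueError("ic50_max and ci_threshold must be positive")
        if self.evidence_mode not in ("union", "intersection"):
            raise ValueError("evidence_mode must be 'union' or 'intersection'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order, writing every output plus ``manifest.json``.

    Returns the manifest dict.  The first failing stage aborts; partial
    outputs written before the failure are flagged in the manifest, which is
    written even on failure.
    """
    outdir = io.ensure_dir(config.outdir)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict)
        },
        "inputs": {},
        "stages": {},
        "outputs": [],
        "status": "incomplete",
    }
    for name in ("counts", "groups", "mutations", "gmt", "targets",
                 "dose_response", "cnv"):
        path = getattr(config, name)
        if path is not None:
            if not Path(path).exists():
                manifest["status"] = "failed"
                _write_manifest(manifest, outdir)
                raise FileNotFoundError(f"input file for {name!r} not found: {path}")
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def record(stage: str, files: dict, **info) -> None:
        manifest["stages"][stage] = {"outputs": sorted(files), **info}
        manifest["outputs"].extend(sorted(files))

    try:
        # -- stage: simulate (fills any input not supplied as a file) -------
        cohort = None
        if not all(getattr(config, n) for n in
                   ("counts", "groups", "mutations", "gmt", "targets", "dose_response")):
            sim_cfg = SimConfig(seed=config.seed, **config.sim)
            cohort = simulate_cohort(sim_cfg)
            io.write_counts(cohort.counts, outdir / "counts.tsv")
            io.write_groups(cohort.counts.groups, outdir / "groups.tsv")
            io.write_mutations(cohort.mutations, outdir / "mutations.tsv")
            io.write_gmt(cohort.pathways, outdir / "pathways.gmt")
            io.write_target_matrix(cohort.target_matrix, outdir / "compound_targets.tsv")
            io.write_dose_response(cohort.dose_response, outdir / "dose_response.csv")
            io.write_truth(cohort.truth, outdir / "truth.json")
            record("simulate",
                   {"counts.tsv", "groups.tsv", "mutations.tsv", "pathways.gmt",
                    "compound_targets.tsv", "dose_response.csv", "truth.json"},
                   n_genes=sim_cfg.n_genes, n_pathways=sim_cfg.n_pathways,
                   n_compounds=sim_cfg.n_compounds)

        counts = (
            io.read_counts(config.counts, io.read_groups(config.groups))
            if config.counts else cohort.counts
        )
        mut_table = io.read_mutations(config.mutations) if config.mutations else cohort.mutations
        pathways = io.read_gmt(config.gmt) if config.gmt else cohort.pathways
        target_matrix = (
            io.read_target_matrix(config.targets) if config.targets else cohort.target_matrix
        )
        dose = (
            io.read_dose_response(config.dose_response)
            if config.dose_response else cohort.dose_response
        )
        cnv = io.read_cnv(config.cnv) if config.cnv else {}

        # -- stage: de ------------------------------------------------------
        disp = estimate_dispersion(counts, shrinkage_weight=config.shrinkage_weight)
        de = call_de(
            exact_test(counts, disp, "common"),
            exact_test(counts, disp, "tagwise"),
            alpha=config.alpha,
        )
        io.write_de(de, outdir / "de.tsv")
        record("de", {"de.tsv"}, n_genes=len(de.table),
               n_significant=int(de.table["significant"].sum()), mode=de.mode_used)

        # -- stage: mutations ----------------------------------------------
        muts = aggregate(mut_table)
        log.info("mutations: %d records -> %d (specimen, gene) cells",
                 len(mut_table), len(muts.table))
        record("mutations", set(), n_records=len(mut_table), n_cells=len(muts.table))

        # -- stage: screen --------------------------------------------------
        fits = fit_screen(dose)
        calls = [call_efficacy(f, config.ic50_max, config.r2_min) for f in fits]
        scores, skipped = target_deconvolution(calls, target_matrix,
                                               config.inhibition_min)
        io.write_fits(fits, outdir / "fits.tsv")
        io.write_target_scores(scores, outdir / "target_scores.tsv")
        record("screen", {"fits.tsv", "target_scores.tsv"},
               n_fits=len(fits), n_effective=sum(c.effective for c in calls),
               skipped_compounds=skipped)

        # -- stage: integrate ------------------------------------------------
        specimen = config.specimen
        if specimen is None:
            labels = counts.group_labels()
            specimen = counts.group_samples(labels[0])[0]
        targets = effective_target_genes(calls, target_matrix, config.inhibition_min)
        ev = build_evidence(de, muts, targets, specimen,
                            min_impact=config.min_impact, cnv_calls=cnv)
        enriched = enrich(ev, pathways, mode=config.evidence_mode)
        ranked = prioritize(enriched, p_max=config.p_max)
        io.write_ranked_pathways(ranked, outdir / "ranked_pathways.tsv")
        annotations = {
            r.pathway_id: annotate_nodes(pathways.genes(r.pathway_id), ev, muts)
            for r in ranked
        }
        io.write_annotations(annotations, outdir / "annotations.json")
        record("integrate", {"ranked_pathways.tsv", "annotations.json"},
               specimen=specimen, n_pathways_tested=len(enriched),
               n_pathways_kept=len(ranked))
        manifest["status"] = "ok"
    except Exception:
        manifest["status"] = "failed"
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
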