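"""Synthetic cohorts with full ground truth for every analysis stage.

One global seed fans out (via ``numpy.random.SeedSequence.spawn``) to
independent child generators for counts, mutations, pathways and the drug
panel, so each stage is reproducible on its own and the whole cohort is
bit-identical for a fixed seed.

Counts use the NB parameterization variance = mu + phi * mu^2 (dispersion
phi); phi = 0 means Poisson.  The spiked driver pathway is composed
predominantly of true-DE and/or driver-mutated genes and always contains the
driver kinase, which every effective compound inhibits.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .integrate import PathwayCollection
from .mutations import IMPACT_LEVELS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_counts",
    "simulate_mutations",
    "simulate_pathways",
    "simulate_drug_panel",
    "simulate_cohort",
]

DRIVER_PATHWAY_ID = "PW_DRIVER"

#: invented defaults — the study design gives no per-tumor mutation rates
DEFAULT_IMPACT_PROBS = {"high": 0.02, "moderate": 0.18, "low": 0.30, "modifier": 0.50}


@dataclasses.dataclass
class SimConfig:
    n_genes: int = 2000
    n_samples_per_group: int = 5
    baseline_mean: float = 100.0
    dispersion: float = 0.2
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    n_pathways: int = 50
    pathway_size_range: tuple = (10, 40)
    driver_pathway_size: int = 20
    n_compounds: int = 50
    n_kinases: int = 30
    effective_fraction: float = 0.1
    cv_noise: float = 0.05
    seed: int = 0
    # -- secondary knobs -------------------------------------------------
    libsize_factor_range: tuple = (0.5, 1.5)
    gene_mean_log2_spread: float = 1.0
    mut_background_rate: float = 30.0
    impact_probs: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_IMPACT_PROBS)
    )
    n_driver_mut_genes: int = 8
    driver_enrichment: float = 0.8
    concentrations: tuple = (1.0, 10.0, 100.0, 1000.0)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_per_group", "n_pathways",
                     "driver_pathway_size", "n_compounds", "n_kinases",
                     "n_driver_mut_genes", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("de_fraction", "effective_fraction", "cv_noise"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0 <= v <= 1):
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v!r}")
        for name in ("baseline_mean", "mut_background_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if not (np.isfinite(self.dispersion) and self.dispersion >= 0):
            raise ValueError("dispersion must be finite and >= 0")
        if not np.isfinite(self.de_log2fc):
            raise ValueError("de_log2fc must be finite")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("pathway_size_range must be a valid integer interval")
        if not 0.6 <= self.driver_enrichment <= 1.0:
            raise ValueError("driver_enrichment must be in [0.6, 1.0]")
        if len(set(self.concentrations)) < 2:
            raise ValueError("at least 2 distinct concentrations are required")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if set(self.impact_probs) != set(IMPACT_LEVELS):
            raise ValueError(f"impact_probs must cover exactly {IMPACT_LEVELS}")
        if abs(sum(self.impact_probs.values()) - 1.0) > 1e-9:
            raise ValueError("impact_probs must sum to 1")

    def child_rngs(self) -> dict:
        names = ("counts", "mutations", "pathways", "drugs")
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.Generator(np.random.PCG64(s)) for n, s in zip(names, seqs)}


@dataclasses.dataclass
class GroundTruth:
    de_genes: dict  # gene -> signed log2 fold change (aggressive over curable)
    mutated_driver_genes: set
    driver_pathway_id: str
    effective_compounds: set
    driver_kinase: str
    kinases: list
    compounds: list
    samples: list
    groups: dict  # sample -> phenotype
    true_ic50: dict  # compound -> generative IC50 (nM)


class SyntheticCohort(NamedTuple):
    counts: CountMatrix
    truth: GroundTruth
    mutations: pd.DataFrame
    pathways: PathwayCollection
    target_matrix: pd.DataFrame
    dose_response: pd.DataFrame


# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """NB counts with group effects plus the cohort-wide ground truth.

    The aggressive group's mean is shifted by +/- ``de_log2fc`` for the DE
    genes (exactly round(de_fraction * n_genes) of them, random signs).
    Library-size factors are uniform over ``libsize_factor_range``.  All
    downstream identifiers (driver genes, kinases, effective compounds) are
    fixed here so later generators stay mutually consistent.
    """
    rng = config.child_rngs()["counts"]
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    n = config.n_samples_per_group
    samples = [f"AGG{i:02d}" for i in range(1, n + 1)] + [
        f"CUR{i:02d}" for i in range(1, n + 1)
    ]
    groups = {s: ("aggressive" if s.startswith("AGG") else "curable") for s in samples}

    n_de = round(config.de_fraction * config.n_genes)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(config.n_genes)
    lfc[de_idx] = signs * config.de_log2fc

    base = config.baseline_mean * 2.0 ** rng.uniform(
        -config.gene_mean_log2_spread, config.gene_mean_log2_spread, config.n_genes
    )
    lib = rng.uniform(*config.libsize_factor_range, size=2 * n)
    mu = base[:, None] * lib[None, :]
    mu[:, :n] *= (2.0 ** lfc)[:, None]  # aggressive columns first
    counts = _nb_draw(rng, mu, config.dispersion)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=pd.Series(groups),
    )

    de_genes = {genes[i]: float(lfc[i]) for i in sorted(de_idx)}
    kin_idx = rng.choice(config.n_genes, size=min(config.n_kinases, config.n_genes),
                         replace=False)
    kinases = [genes[i] for i in sorted(kin_idx)]
    driver_kinase = kinases[int(rng.integers(len(kinases)))]
    n_driver = min(config.n_driver_mut_genes, config.n_genes)
    drv_idx = rng.choice(config.n_genes, size=n_driver, replace=False)
    driver_genes = {genes[i] for i in drv_idx}

    cwidth = max(3, len(str(config.n_compounds)))
    compounds = [f"CP{i:0{cwidth}d}" for i in range(1, config.n_compounds + 1)]
    n_eff = round(config.effective_fraction * config.n_compounds)
    eff_idx = rng.choice(config.n_compounds, size=n_eff, replace=False)
    effective = {compounds[i] for i in eff_idx}
    true_ic50 = {
        c: float(
            10.0 ** rng.uniform(1.0, 2.7) if c in effective
            else 10.0 ** rng.uniform(4.0, 5.0)
        )
        for c in compounds
    }

    truth = GroundTruth(
        de_genes=de_genes,
        mutated_driver_genes=driver_genes,
        driver_pathway_id=DRIVER_PATHWAY_ID,
        effective_compounds=effective,
        driver_kinase=driver_kinase,
        kinases=kinases,
        compounds=compounds,
        samples=samples,
        groups=groups,
        true_ic50=true_ic50,
    )
    return matrix, truth


def simulate_mutations(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Somatic variant table: background noise plus driver hits.

    Every specimen draws Poisson(``mut_background_rate``) background variants
    uniformly over genes (with replacement, so a gene can collect several
    variants) with impact from ``impact_probs``.  Each driver gene gets one
    high- or moderate-impact variant in every aggressive specimen.
    """
    rng = config.child_rngs()["mutations"]
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    impact_names = list(IMPACT_LEVELS)
    impact_p = np.array([config.impact_probs[i] for i in impact_names])

    rows = []
    counter = 0
    for specimen in truth.samples:
        n_bg = rng.poisson(config.mut_background_rate)
        bg_genes = rng.choice(len(genes), size=n_bg, replace=True)
        bg_impacts = rng.choice(len(impact_names), size=n_bg, p=impact_p)
        for gi, ii in zip(bg_genes, bg_impacts):
            counter += 1
            rows.append((specimen, genes[gi], f"v{counter:07d}", impact_names[ii]))
        if truth.groups[specimen] == "aggressive":
            for gene in sorted(truth.mutated_driver_genes):
                counter += 1
                impact = "high" if rng.random() < 0.5 else "moderate"
                rows.append((specimen, gene, f"v{counter:07d}", impact))
    return pd.DataFrame(rows, columns=["specimen", "gene", "variant_id", "impact"])


def simulate_pathways(config: SimConfig, truth: GroundTruth) -> PathwayCollection:
    """Decoy pathways sampled uniformly plus the enriched driver pathway.

    ``n_pathways`` counts the driver: ``n_pathways - 1`` decoys are drawn
    without replacement from the gene universe.  The driver pathway reserves
    one slot for the driver kinase and fills a ``driver_enrichment`` fraction
    of the rest from true-DE and driver-mutated genes.
    """
    rng = config.child_rngs()["pathways"]
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    lo, hi = config.pathway_size_range
    if hi > config.n_genes or config.driver_pathway_size > config.n_genes:
        raise ValueError("pathway size exceeds the gene universe")

    pathways = {}
    size = config.driver_pathway_size
    pool = sorted((set(truth.de_genes) | truth.mutated_driver_genes) - {truth.driver_kinase})
    n_enriched = min(math.ceil(config.driver_enrichment * (size - 1)), len(pool), size - 1)
    chosen = set(rng.choice(pool, size=n_enriched, replace=False)) if n_enriched else set()
    filler_pool = sorted(set(genes) - chosen - {truth.driver_kinase})
    n_fill = size - 1 - len(chosen)
    filler = set(rng.choice(filler_pool, size=n_fill, replace=False)) if n_fill else set()
    pathways[DRIVER_PATHWAY_ID] = (
        "spiked driver pathway",
        frozenset(chosen | filler | {truth.driver_kinase}),
    )
    for i in range(1, config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"PW{i:04d}"] = (f"decoy pathway {i}", frozenset(members))
    return PathwayCollection(pathways=pathways, universe=frozenset(genes))


def simulate_drug_panel(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compound x kinase inhibition matrix and 4PL dose-response measurements.

    Every effective compound inhibits the driver kinase (score in [0.8, 1]);
    all compounds pick up 1 + Poisson(2) random targets with scores in
    [0.5, 1].  Viability follows a 4PL curve (top 1, bottom 0, hill 1, the
    compound's generative IC50) times multiplicative Gaussian noise with CV
    ``cv_noise``, over ``concentrations`` x ``n_replicates``.
    """
    rng = config.child_rngs()["drugs"]
    kinases = truth.kinases
    matrix = pd.DataFrame(
        0.0, index=truth.compounds, columns=kinases, dtype=float
    )
    drv = truth.driver_kinase
    for compound in truth.compounds:
        n_t = 1 + rng.poisson(2)
        targets = rng.choice(len(kinases), size=min(n_t, len(kinases)), replace=False)
        for t in targets:
            matrix.iat[matrix.index.get_loc(compound), t] = rng.uniform(0.5, 1.0)
        if compound in truth.effective_compounds:
            matrix.at[compound, drv] = rng.uniform(0.8, 1.0)
    matrix.index.name = "compound"
    matrix.columns.name = "kinase"

    rows = []
    conc = sorted(config.concentrations)
    for compound in truth.compounds:
        ic50 = truth.true_ic50[compound]
        for c in conc:
            v_true = 1.0 / (1.0 + c / ic50)  # 4PL, top 1 bottom 0 hill 1
            for rep in range(1, config.n_replicates + 1):
                noise = 1.0 + config.cv_noise * rng.standard_normal()
                rows.append(
                    (compound, "CULT1", c, rep, max(0.0, v_true * noise))
                )
    dose = pd.DataFrame(
        rows, columns=["compound", "culture", "concentration_nM", "replicate", "viability"]
    )
    return matrix, dose


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Run every generator off one config; the single entry point for tests/CLI."""
    counts, truth = simulate_counts(config)
    muts = simulate_mutations(config, truth)
    pathways = simulate_pathways(config, truth)
    target_matrix, dose = simulate_drug_panel(config, truth)
    return SyntheticCohort(counts, truth, muts, pathways, target_matrix, dose)
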