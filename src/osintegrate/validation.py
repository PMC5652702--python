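"""Self-contained validation studies behind the acceptance criteria.

Each function recomputes one property-based quantity from scratch by running
the package on synthetic inputs it generates itself.  They are shared by the
acceptance test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .diffexpr import (
    bh_adjust,
    call_de,
    estimate_dispersion,
    exact_nb_pvalue,
    exact_test,
)
from .drugscreen import (
    EfficacyCall,
    MedianEffectFit,
    call_efficacy,
    combination_index,
    effective_target_genes,
    fit_4pl,
    fit_screen,
    target_deconvolution,
)
from .integrate import build_evidence, enrich, prioritize
from .mutations import aggregate
from .pipeline import RunConfig, run_pipeline
from .simulate import SimConfig, simulate_cohort, simulate_counts, simulate_drug_panel
from .stats import hypergeom_upper_tail


# ---------------------------------------------------------------------------
# oracles


def enumeration_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Exact integer-combinatorics upper tail, independent of scipy."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(max(k, 0), min(K, n) + 1)
    ) / total


def enumeration_split_pvalue(z1: int, z2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided split p by brute-force enumeration via scipy pmf products.

    Uses scipy's nbinom/binom pmf with an arbitrary shared success
    probability (it cancels on conditioning), a different route than the
    closed-form negative hypergeometric in the implementation.
    """
    from scipy.stats import binom, nbinom

    z = z1 + z2
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if phi == 0:
        pmf = binom.pmf(k, z, n1 / (n1 + n2))
    else:
        r = 1.0 / phi
        pmf = nbinom.pmf(k, n1 * r, 0.4) * nbinom.pmf(z - k, n2 * r, 0.4)
        pmf = pmf / pmf.sum()
    return float(min(1.0, pmf[pmf <= pmf[z1] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# criteria


def enrichment_oracle_equivalence(n_max: int = 30) -> dict:
    """Max |p - enumeration| over every (N <= n_max, K, n, k) plus spot checks
    through enrich() itself."""
    worst = 0.0
    count = 0
    for N in range(1, n_max + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(0, min(K, n) + 1):
                    p = hypergeom_upper_tail(k, N, K, n)
                    o = enumeration_hypergeom_sf(k, N, K, n)
                    worst = max(worst, abs(p - o))
                    count += 1
    # the same numbers must surface through the user-facing operations
    from .integrate import EvidenceSet, PathwayCollection

    rng = np.random.default_rng(0)
    for _ in range(25):
        N = int(rng.integers(8, n_max + 1))
        universe = [f"u{i}" for i in range(N)]
        pw_genes = rng.choice(universe, size=int(rng.integers(1, N)), replace=False)
        ev_genes = rng.choice(universe, size=int(rng.integers(1, N)), replace=False)
        pw = PathwayCollection({"P": ("d", frozenset(pw_genes))}, frozenset(universe))
        ev = EvidenceSet("s", set(ev_genes), set(), set(), set())
        r = enrich(ev, pw)[0]
        worst = max(worst, abs(r.p - enumeration_hypergeom_sf(
            r.overlap_k, N, len(pw_genes), len(ev_genes))))
    return {"max_abs_error": worst, "n": count}


def exact_test_oracle_equivalence(
    totals=(1, 2, 3, 5, 8, 13, 21, 34, 50),
    phis=(0.0, 0.1, 0.5),
    designs=((1, 1), (2, 3), (5, 5)),
) -> dict:
    """Max |p - enumeration| over all splits of each total."""
    worst = 0.0
    count = 0
    for phi in phis:
        for n1, n2 in designs:
            for z in totals:
                for z1 in range(z + 1):
                    p = exact_nb_pvalue(z1, z - z1, n1, n2, phi)
                    o = enumeration_split_pvalue(z1, z - z1, n1, n2, phi)
                    worst = max(worst, abs(p - o))
                    count += 1
    return {"max_abs_error": worst, "n": count}


def type_i_error(seed: int = 0, n_seeds: int = 20, n_genes: int = 2000) -> dict:
    """Pooled per-gene rejection rate at p < 0.05 under the global null."""
    rejected = 0
    total = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed * 1000 + i, de_fraction=0.0, dispersion=0.2,
                        n_genes=n_genes, n_samples_per_group=5)
        m, _ = simulate_counts(cfg)
        d = estimate_dispersion(m)
        res = exact_test(m, d, "common")
        rejected += int((res["p"].values < 0.05).sum())
        total += len(res)
    half_band = 2.5758 * math.sqrt(0.05 * 0.95 / total)
    return {
        "rate": rejected / total,
        "n": total,
        "band_low": 0.05 - half_band,
        "band_high": 0.05 + half_band,
    }


def de_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """Sensitivity / observed FDR of the dual-FDR rule at log2FC=2, 5% true DE."""
    sens, fdrs = [], []
    fallback_consistent = True
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed * 2000 + i, n_genes=2000, de_fraction=0.05,
                        de_log2fc=2.0, dispersion=0.2, n_samples_per_group=5)
        m, truth = simulate_counts(cfg)
        d = estimate_dispersion(m)
        rc = exact_test(m, d, "common")
        rt = exact_test(m, d, "tagwise")
        res = call_de(rc, rt)
        called = res.significant_genes
        true = set(truth.de_genes)
        tp = len(called & true)
        sens.append(tp / len(true))
        fdrs.append((len(called) - tp) / max(len(called), 1))
        # fallback iff zero genes pass dual FDR, recomputed independently
        dual = (bh_adjust(rc["p"].values) < 0.05) & (bh_adjust(rt["p"].values) < 0.05)
        expected_mode = "dual_fdr" if dual.any() else "unadjusted_fallback"
        fallback_consistent &= res.mode_used == expected_mode
    return {
        "sensitivity": float(np.mean(sens)),
        "observed_fdr": float(np.mean(fdrs)),
        "fallback_rule_consistent": fallback_consistent,
        "n": n_seeds,
    }


def ic50_recovery(seed: int = 0, n_curves: int = 200, cv: float = 0.05) -> dict:
    """Median |IC50 error| on the 4-concentration x 3-replicate design."""
    rng = np.random.default_rng(seed)
    concs = [1.0, 10.0, 100.0, 1000.0]
    errs = []
    for _ in range(n_curves):
        true = 10.0 ** rng.uniform(np.log10(5), np.log10(500))
        rows = [
            ("X", "C", c, rep, max(0.0, (1 / (1 + c / true))
                                   * (1 + cv * rng.standard_normal())))
            for c in concs for rep in range(3)
        ]
        df = pd.DataFrame(rows, columns=["compound", "culture", "concentration_nM",
                                         "replicate", "viability"])
        fit = fit_4pl(df, "X", "C")
        errs.append(abs(fit.ic50 - true) / true)
    # censoring side condition: true IC50 above the top dose
    censored = 0
    for _ in range(20):
        rows = [
            ("X", "C", c, rep, max(0.0, (1 / (1 + c / 5000.0))
                                   * (1 + cv * rng.standard_normal())))
            for c in concs for rep in range(3)
        ]
        df = pd.DataFrame(rows, columns=["compound", "culture", "concentration_nM",
                                         "replicate", "viability"])
        censored += fit_4pl(df, "X", "C").censored
    return {
        "median_abs_rel_error": float(np.median(errs)),
        "censored_fraction_when_ic50_above_cmax": censored / 20,
        "n": n_curves,
    }


def combination_index_identities() -> dict:
    """Self-combination additivity and the closed-form hand example."""
    fit = MedianEffectFit("a", "c", Dm=137.0, m=1.4, r=1.0)
    worst_self = 0.0
    for fa in (0.1, 0.3, 0.5, 0.7, 0.9):
        dx = fit.dose_for_fa(fa)
        ci = combination_index(fit, fit, dx / 2, dx / 2, fa).CI
        worst_self = max(worst_self, abs(ci - 1.0))
    f1 = MedianEffectFit("a", "c", Dm=100.0, m=1.0, r=1.0)
    f2 = MedianEffectFit("b", "c", Dm=200.0, m=1.0, r=1.0)
    hand = combination_index(f1, f2, 30.0, 50.0, 0.5)
    return {
        "self_ci_max_abs_dev": worst_self,
        "hand_example_ci": hand.CI,
        "hand_example_synergy": hand.synergy_call,
        "n": 5,
    }


def deconvolution_recovery(seed: int = 0, n_seeds: int = 40) -> dict:
    """Fraction of seeds where the spiked driver kinase ranks first with the
    strictly smallest enrichment p.  Efficacy calls come from ground truth so
    the criterion isolates the deconvolution step."""
    wins = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed * 3000 + i, n_genes=400, n_compounds=50,
                        n_kinases=30)
        _, truth = simulate_counts(cfg)
        matrix, _ = simulate_drug_panel(cfg, truth)
        calls = [EfficacyCall(c, "CULT1", c in truth.effective_compounds, "")
                 for c in truth.compounds]
        scores, _ = target_deconvolution(calls, matrix)
        top = scores[0]
        others = [s.enrichment_p for s in scores if s.kinase != truth.driver_kinase]
        if top.kinase == truth.driver_kinase and top.enrichment_p < min(others):
            wins += 1
    return {"rank1_fraction": wins / n_seeds, "n": n_seeds}


def end_to_end_driver_recovery(seed: int = 0, n_seeds: int = 40) -> dict:
    """Full pipeline on synthetic cohorts with 50 decoy pathways: fraction of
    seeds where the spiked driver pathway ranks 1 after the p < 0.05 +
    druggability filter."""
    wins = 0
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed * 4000 + i, n_genes=1200, n_pathways=51,
                        baseline_mean=60.0, n_compounds=40)
        co = simulate_cohort(cfg)
        d = estimate_dispersion(co.counts)
        de = call_de(exact_test(co.counts, d, "common"),
                     exact_test(co.counts, d, "tagwise"))
        muts = aggregate(co.mutations)
        fits = fit_screen(co.dose_response)
        calls = [call_efficacy(f) for f in fits]
        targets = effective_target_genes(calls, co.target_matrix)
        ev = build_evidence(de, muts, targets, co.truth.samples[0])
        ranked = prioritize(enrich(ev, co.pathways))
        if ranked and ranked[0].pathway_id == co.truth.driver_pathway_id:
            wins += 1
    return {"rank1_fraction": wins / n_seeds, "n": n_seeds}


def determinism(tmpdir, seed: int = 0) -> dict:
    """Byte-identity of every pipeline output across two identical runs."""
    from pathlib import Path

    sim = dict(n_genes=400, n_pathways=12, n_compounds=15, baseline_mean=60.0)
    paths = []
    for name in ("run_a", "run_b"):
        out = Path(tmpdir) / name
        run_pipeline(RunConfig(outdir=str(out), seed=seed, sim=sim))
        paths.append(out)
    names = ["counts.tsv", "groups.tsv", "mutations.tsv", "pathways.gmt",
             "compound_targets.tsv", "dose_response.csv", "truth.json",
             "de.tsv", "fits.tsv", "target_scores.tsv", "ranked_pathways.tsv",
             "annotations.json"]
    identical = all(
        (paths[0] / n).read_bytes() == (paths[1] / n).read_bytes() for n in names
    )
    return {"byte_identical": identical, "n": len(names)}
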