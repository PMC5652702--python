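"""Dose-response fitting, efficacy calls, combination indices and target deconvolution.

Viability is expected as a fraction of vehicle control (values > 1 are
allowed, representing growth stimulation).  IC50 is the four-parameter
logistic midpoint (relative EC50); when the midpoint lands above the top
tested concentration the fit is censored and reported as "> Cmax".
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

from .stats import hypergeom_upper_tail

__all__ = [
    "DoseResponseFit",
    "EfficacyCall",
    "MedianEffectFit",
    "CombinationResult",
    "TargetScore",
    "four_pl",
    "fit_4pl",
    "fit_screen",
    "call_efficacy",
    "median_effect_fit",
    "combination_index",
    "target_deconvolution",
    "effective_target_genes",
]


@dataclasses.dataclass
class DoseResponseFit:
    compound: str
    culture: str
    top: float
    bottom: float
    hill: float
    ic50: float
    r_squared: float
    converged: bool
    censored: bool
    max_tested: float

    @property
    def ic50_display(self) -> str:
        if not self.converged:
            return "NA"
        if self.censored:
            return f"> {self.max_tested:g}"
        return f"{self.ic50:g}"


@dataclasses.dataclass
class EfficacyCall:
    compound: str
    culture: str
    effective: bool
    reason: str


@dataclasses.dataclass
class MedianEffectFit:
    compound: str
    culture: str
    Dm: float
    m: float
    r: float

    def dose_for_fa(self, fa: float) -> float:
        """Single-agent dose achieving affected fraction ``fa``."""
        if not 0 < fa < 1:
            raise ValueError("fa must lie strictly between 0 and 1")
        return self.Dm * (fa / (1 - fa)) ** (1.0 / self.m)


@dataclasses.dataclass
class CombinationResult:
    fa: float
    d1: float
    d2: float
    Dx1: float
    Dx2: float
    CI: float
    synergy_call: bool
    threshold: float


@dataclasses.dataclass
class TargetScore:
    kinase: str
    n_effective_hitting: int
    n_panel_hitting: int
    enrichment_p: float


def four_pl(c, top, bottom, hill, log_ic50):
    """v(c) = bottom + (top - bottom) / (1 + 10^(hill * (log10 c - log10 ic50)))."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(c) - log_ic50)))


def _select(data: pd.DataFrame, compound: str, culture: str) -> pd.DataFrame:
    sub = data[(data["compound"] == compound) & (data["culture"] == culture)]
    if sub.empty:
        raise ValueError(f"no dose-response records for ({compound!r}, {culture!r})")
    return sub


_HILL_STARTS = (0.5, 1.0, 2.0, -0.5, -1.0, -2.0)


def fit_4pl(
    data: pd.DataFrame,
    compound: str,
    culture: str,
    min_span: float = 0.1,
    n_starts: int = 6,
) -> DoseResponseFit:
    """Least-squares 4PL fit on the log-dose scale with multi-start initialization.

    Candidate starts span hill in {±0.5, ±1, ±2} crossed with log-IC50 at the
    tested dose quartiles; the ``n_starts`` candidates with the smallest
    initial SSE are refined and the best converged SSE wins, so the result is
    deterministic.  The fit is censored — reported "> Cmax" — when the
    midpoint exceeds the top tested concentration, when the fitted span
    (top - bottom) is below ``min_span`` (no dose response), or when the
    fitted curve never falls below half the fitted top within the tested
    range (the half-effect concentration is not identified by the data).
    """
    sub = _select(data, compound, culture)
    conc = sub["concentration_nM"].values.astype(float)
    viab = sub["viability"].values.astype(float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    distinct = np.unique(conc)
    if distinct.size < 2:
        raise ValueError("at least 2 distinct concentrations are required")

    logc = np.log10(conc)
    ic50_starts = np.quantile(np.log10(distinct), [0.0, 0.25, 0.5, 0.75, 1.0])
    bounds = (
        [min(viab.min(), 0.0) - 0.5, min(viab.min(), 0.0) - 0.5, -10.0, logc.min() - 3.0],
        [viab.max() + 0.5, viab.max() + 0.5, 10.0, logc.max() + 3.0],
    )
    starts = [
        (float(np.sum((viab - four_pl(conc, viab.max(), viab.min(), h, l)) ** 2)),
         hi, li, [viab.max(), viab.min(), h, l])
        for hi, h in enumerate(_HILL_STARTS)
        for li, l in enumerate(ic50_starts)
    ]
    starts.sort(key=lambda s: (s[0], s[1], s[2]))
    # near-flat data cannot identify 4 parameters; a couple of starts suffice
    # (such fits end up censored regardless)
    by_dose = [viab[conc == c].mean() for c in distinct]
    if max(by_dose) - min(by_dose) < min_span:
        n_starts = min(n_starts, 2)
    lo = np.asarray(bounds[0])
    hi = np.asarray(bounds[1])
    best = None
    for _, _, _, p0 in starts[:n_starts]:
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = least_squares(
                    lambda p: four_pl(conc, *p) - viab,
                    p0, bounds=(lo, hi), max_nfev=100,
                )
        except ValueError:
            continue
        sse = float(np.sum(res.fun ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, res.x)
        if best[0] < 1e-14:  # perfect fit; further starts cannot improve
            break

    cmax = float(distinct.max())
    if best is None:
        return DoseResponseFit(compound, culture, np.nan, np.nan, np.nan, np.nan,
                               0.0, False, False, cmax)
    sse, (top, bottom, hill, log_ic50) = best
    if bottom > top:  # canonicalize the equivalent reflected parameterization
        top, bottom, hill = bottom, top, -hill
    ic50 = float(10.0 ** log_ic50)
    sstot = float(np.sum((viab - viab.mean()) ** 2))
    r2 = 0.0 if sstot == 0 else max(0.0, 1.0 - sse / sstot)
    v_cmax = float(four_pl(cmax, top, bottom, hill, log_ic50))
    censored = ic50 > cmax or (top - bottom) < min_span or v_cmax > 0.5 * top
    return DoseResponseFit(
        compound=compound,
        culture=culture,
        top=float(top),
        bottom=float(bottom),
        hill=float(hill),
        ic50=ic50,
        r_squared=min(1.0, r2),
        converged=True,
        censored=bool(censored),
        max_tested=cmax,
    )


def fit_screen(data: pd.DataFrame) -> list[DoseResponseFit]:
    """Fit every (compound, culture) pair present in ``data``, sorted order."""
    pairs = sorted(set(zip(data["compound"], data["culture"])))
    return [fit_4pl(data, comp, cult) for comp, cult in pairs]


def call_efficacy(
    fit: DoseResponseFit,
    ic50_max: float = 1000.0,
    r2_min: float = 0.6,
) -> EfficacyCall:
    """Effective iff converged, uncensored, R^2 > r2_min and IC50 < ic50_max."""
    if not fit.converged:
        return EfficacyCall(fit.compound, fit.culture, False, "no_fit")
    if fit.censored:
        return EfficacyCall(fit.compound, fit.culture, False, "censored")
    if not fit.r_squared > r2_min:
        return EfficacyCall(fit.compound, fit.culture, False, "fit_quality")
    if not fit.ic50 < ic50_max:
        return EfficacyCall(fit.compound, fit.culture, False, "potency")
    return EfficacyCall(fit.compound, fit.culture, True, "ok")


def median_effect_fit(
    data: pd.DataFrame,
    compound: str,
    culture: str,
) -> MedianEffectFit:
    """Median-effect fit: regress log(fa/fu) on log dose; Dm is the x-intercept.

    fa = 1 - viability.  Points with fa outside (0, 1) carry no information
    for the linearization and are dropped with a warning.
    """
    sub = _select(data, compound, culture)
    conc = sub["concentration_nM"].values.astype(float)
    fa = 1.0 - sub["viability"].values.astype(float)
    usable = (fa > 0) & (fa < 1)
    if (~usable).any():
        warnings.warn(
            f"dropping {(~usable).sum()} point(s) with fa outside (0,1) for "
            f"({compound}, {culture})",
            stacklevel=2,
        )
    conc, fa = conc[usable], fa[usable]
    if np.unique(conc).size < 2:
        raise ValueError("median-effect fit needs >= 2 usable doses")
    res = linregress(np.log10(conc), np.log10(fa / (1.0 - fa)))
    if abs(res.slope) < 1e-9:
        raise ValueError("zero median-effect slope: Dm undefined")
    dm = float(10.0 ** (-res.intercept / res.slope))
    return MedianEffectFit(compound, culture, Dm=dm, m=float(res.slope),
                           r=float(res.rvalue))


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    d1: float,
    d2: float,
    fa_combo: float,
    threshold: float = 0.7,
) -> CombinationResult:
    """Chou-Talalay CI = d1/Dx1 + d2/Dx2 at the combination's affected fraction."""
    if not 0 < fa_combo < 1:
        raise ValueError("fa_combo must lie strictly between 0 and 1")
    dx1 = fit1.dose_for_fa(fa_combo)
    dx2 = fit2.dose_for_fa(fa_combo)
    ci = d1 / dx1 + d2 / dx2
    return CombinationResult(
        fa=fa_combo, d1=d1, d2=d2, Dx1=dx1, Dx2=dx2, CI=float(ci),
        synergy_call=bool(ci <= threshold), threshold=threshold,
    )


def target_deconvolution(
    calls: Iterable[EfficacyCall],
    matrix: pd.DataFrame,
    inhibition_min: float = 0.5,
) -> tuple[list[TargetScore], list[str]]:
    """Rank kinases by recurrence among effective compounds.

    ``matrix`` is compound x kinase inhibition scores.  A compound "hits" a
    kinase when its score >= ``inhibition_min``.  Each kinase gets the count
    of effective compounds hitting it and a hypergeometric upper-tail
    enrichment p (panel size N, panel hits K, effective n, effective hits k).
    Sorted by count descending, then p ascending, then name.  Effective
    compounds absent from the matrix are returned as skipped, not fatal.
    """
    effective = sorted({c.compound for c in calls if c.effective})
    skipped = [c for c in effective if c not in matrix.index]
    effective = [c for c in effective if c in matrix.index]
    hits = matrix.values >= inhibition_min
    n_panel = matrix.shape[0]
    n_eff = len(effective)
    eff_rows = [matrix.index.get_loc(c) for c in effective]
    scores = []
    for j, kinase in enumerate(matrix.columns):
        big_k = int(hits[:, j].sum())
        k = int(hits[eff_rows, j].sum()) if eff_rows else 0
        p = hypergeom_upper_tail(k, n_panel, big_k, n_eff) if n_eff else 1.0
        scores.append(TargetScore(str(kinase), k, big_k, p))
    scores.sort(key=lambda s: (-s.n_effective_hitting, s.enrichment_p, s.kinase))
    return scores, skipped


def effective_target_genes(
    calls: Iterable[EfficacyCall],
    matrix: pd.DataFrame,
    inhibition_min: float = 0.5,
) -> set:
    """Union of kinases hit (score >= threshold) by any effective compound."""
    effective = [c.compound for c in calls if c.effective and c.compound in matrix.index]
    if not effective:
        return set()
    hit_any = (matrix.loc[effective] >= inhibition_min).any(axis=0)
    return set(matrix.columns[hit_any])
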