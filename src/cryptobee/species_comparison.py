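"""Gaussian linear-model comparison of ratio means across species, caste, region.

The study model is a Gaussian GLM with identity link — i.e. ordinary
least squares — of one malar ratio on species (DNA-confirmed), caste
(queen/worker) and region (Midwest/Northeast), initially with
species:caste and species:region interactions.  Interactions that are
not significant in a marginal (Type II) ANOVA at alpha = 0.05 are
dropped and the model refit.  Estimated marginal means (EMMs) per
species x caste average the model predictions with equal weight over
region; pairwise species contrasts of EMMs are tested with Tukey's HSD
via the studentized-range distribution.

Type II sums of squares are used because the study design is unbalanced
(cell sizes 3–35); on balanced data they coincide with Type I.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .morphometrics import RATIO_NAMES, SpecimenRecord, ratio_table

ALPHA_PRUNE = 0.05

_FACTOR_TERMS = {
    "species": 'C(species)',
    "caste": 'C(caste, Treatment("queen"))',
    "region": 'C(region, Treatment("Midwest"))',
}


def _formula(response: str, terms: Sequence[str]) -> str:
    parts = []
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            parts.append(f"{_FACTOR_TERMS[a]}:{_FACTOR_TERMS[b]}")
        else:
            parts.append(_FACTOR_TERMS[t])
    return f"{response} ~ " + " + ".join(parts)


@dataclass
class LinearModelFit:
    """An OLS fit of one ratio on the design factors."""

    response: str
    terms: tuple[str, ...]
    result: "sm.regression.linear_model.RegressionResultsWrapper"
    data: pd.DataFrame

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params

    @property
    def se(self) -> pd.Series:
        return self.result.bse

    @property
    def df_resid(self) -> int:
        return int(self.result.df_resid)

    @property
    def sigma2(self) -> float:
        return float(self.result.mse_resid)

    def coefficient(self, factor: str, level: str) -> tuple[float, float]:
        """(estimate, SE) of the treatment coefficient for ``level`` of ``factor``."""
        key = [name for name in self.result.params.index
               if name.startswith("C(" + factor) and f"[T.{level}]" in name and ":" not in name]
        if len(key) != 1:
            raise KeyError(f"no unique main-effect coefficient for {factor}={level}")
        return float(self.result.params[key[0]]), float(self.result.bse[key[0]])


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df_num: int
    df_den: int
    F: float
    p: float


@dataclass(frozen=True)
class PairwiseContrast:
    pair: tuple[str, str]
    estimate: float
    se: float
    df: int
    p_tukey: float


def fit_linear_model(
    records: Sequence[SpecimenRecord] | pd.DataFrame,
    response: str,
    terms: Sequence[str] = ("species", "caste", "region",
                            "species:caste", "species:region"),
) -> LinearModelFit:
    """OLS of ``response`` (mr1|mr3|mrl) on treatment-coded factors.

    Reference levels: species=perplexus (alphabetical), caste=queen,
    region=Midwest — so the "worker" coefficient is the worker-minus-queen
    effect reported in the study tables.
    """
    if response not in RATIO_NAMES:
        raise ValueError(f"response must be one of {RATIO_NAMES}")
    df = records if isinstance(records, pd.DataFrame) else ratio_table(records)
    for t in terms:
        for f in t.split(":"):
            if df[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
    result = smf.ols(_formula(response, terms), data=df).fit()
    if np.linalg.matrix_rank(result.model.exog) < result.model.exog.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    return LinearModelFit(response, tuple(terms), result, df)


def anova_table(fit: LinearModelFit) -> list[AnovaRow]:
    """Marginal (Type II) F tests for every term in the fit."""
    tab = sm.stats.anova_lm(fit.result, typ=2)
    rows = []
    for name, row in tab.iterrows():
        if name == "Residual":
            continue
        term = (name.replace('C(species)', 'species')
                    .replace('C(caste, Treatment("queen"))', 'caste')
                    .replace('C(region, Treatment("Midwest"))', 'region'))
        rows.append(AnovaRow(term=term, df_num=int(row["df"]),
                             df_den=fit.df_resid,
                             F=float(row["F"]), p=float(row["PR(>F)"])))
    return rows


def anova_and_prune(fit: LinearModelFit, alpha: float = ALPHA_PRUNE
                    ) -> tuple[LinearModelFit, list[AnovaRow]]:
    """Drop non-significant interaction terms (p > alpha) and refit.

    Main effects are never pruned.  Returns the final fit and its
    ANOVA table (which is the input fit's table when nothing is pruned).
    """
    rows = anova_table(fit)
    keep = [t for t in fit.terms if ":" not in t]
    pruned = False
    for row in rows:
        if ":" in row.term:
            if row.p <= alpha:
                keep.append(row.term)
            else:
                pruned = True
    if not pruned:
        return fit, rows
    refit = fit_linear_model(fit.data, fit.response, tuple(keep))
    return refit, anova_table(refit)


def _grid_prediction(fit: LinearModelFit, cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """EMM estimates and SEs for rows of ``cells`` (species/caste columns),
    averaging design rows with equal weight over region levels."""
    design_info = fit.result.model.data.design_info
    regions = sorted(fit.data["region"].unique())
    L = np.zeros((len(cells), len(fit.result.params)))
    for i, cell in enumerate(cells.itertuples(index=False)):
        grid = pd.DataFrame([{**cell._asdict(), "region": rg} for rg in regions])
        (X,) = build_design_matrices([design_info], grid)
        L[i] = np.asarray(X).mean(axis=0)
    est = L @ fit.result.params.to_numpy()
    cov = fit.result.cov_params().to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
    return est, se


def estimated_marginal_means(fit: LinearModelFit, level: float = 0.95) -> pd.DataFrame:
    """EMM per species x caste, averaged with equal weight over region.

    Returns a DataFrame with columns species, caste, emmean, se, ci_lo,
    ci_hi; the CI uses t quantiles at the residual df.
    """
    species = sorted(fit.data["species"].unique())
    castes = sorted(fit.data["caste"].unique())
    cells = pd.DataFrame(
        [{"species": s, "caste": c} for s, c in itertools.product(species, castes)])
    est, se = _grid_prediction(fit, cells)
    tq = st.t.ppf(0.5 + level / 2.0, fit.df_resid)
    out = cells.copy()
    out["emmean"] = est
    out["se"] = se
    out["ci_lo"] = est - tq * se
    out["ci_hi"] = est + tq * se
    return out


def tukey_pairwise(fit: LinearModelFit, factor: str = "species"
                   ) -> list[PairwiseContrast]:
    """All pairwise EMM contrasts of ``factor`` with Tukey-HSD p-values.

    EMMs average the other design factors with equal weight.  The
    adjusted p-value is ``P(q_{k,df} >= |t| * sqrt(2))`` under the
    studentized-range distribution; for k = 2 this equals the ordinary
    two-sided t-test p-value.
    """
    levels = sorted(fit.data[factor].unique())
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    others = [f for f in ("species", "caste") if f != factor and f in fit.data]
    design_info = fit.result.model.data.design_info
    other_levels = {f: sorted(fit.data[f].unique()) for f in others}
    regions = sorted(fit.data["region"].unique())

    # per-level EMM contrast vectors averaged over all other factors
    Lrows = []
    for lev in levels:
        combos = list(itertools.product(*(other_levels[f] for f in others), regions))
        grid = pd.DataFrame(
            [{factor: lev, **dict(zip(others, combo[:-1])), "region": combo[-1]}
             for combo in combos])
        (X,) = build_design_matrices([design_info], grid)
        Lrows.append(np.asarray(X).mean(axis=0))
    Lrows = np.asarray(Lrows)
    beta = fit.result.params.to_numpy()
    cov = fit.result.cov_params().to_numpy()

    out = []
    for i, j in itertools.combinations(range(k), 2):
        ell = Lrows[i] - Lrows[j]
        estimate = float(ell @ beta)
        se = float(np.sqrt(ell @ cov @ ell))
        tval = estimate / se
        p = float(st.studentized_range.sf(abs(tval) * np.sqrt(2.0), k, fit.df_resid))
        out.append(PairwiseContrast(pair=(levels[i], levels[j]), estimate=estimate,
                                    se=se, df=fit.df_resid, p_tukey=min(1.0, p)))
    return out


def species_contrast(contrasts: Sequence[PairwiseContrast],
                     a: str, b: str) -> PairwiseContrast:
    """The a-minus-b contrast, flipping sign if stored as (b, a)."""
    for c in contrasts:
        if c.pair == (a, b):
            return c
        if c.pair == (b, a):
            return PairwiseContrast((a, b), -c.estimate, c.se, c.df, c.p_tukey)
    raise KeyError(f"no contrast for pair {(a, b)}")
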