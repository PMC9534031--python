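"""Heritabilities and genetic/phenotypic correlations from fitted components.

Narrow-sense heritability is computed on a half-sib family-mean basis,

    h2 = sf2 / (sf2 + sfR2/nR + se2/nR),

where ``sf2`` is the family variance component (which equals one quarter of
the total additive variance under a half-sib structure — no x4 rescaling is
applied here), ``sfR2`` the family x replicate interaction, ``se2`` the
residual and ``nR`` the number of environmental replicates.

Genetic covariances between traits use the polarization identity

    covA(X, Y) = [sf2(X+Y) - sf2(X-Y)] / 4

estimated from univariate REML fits on unit-variance-scaled traits; for
quadratic (balanced-ANOVA) component estimators this equals the direct
cross-product estimator exactly, it keeps the engine univariate, and unlike
the three-fit sum trick it is exactly antisymmetric under a sign flip of
either trait.  Genetic correlations are the covariance normalised by the
geometric mean of the family variances; entries outside [-1, 1] — common for
small-sample REML — are clamped and flagged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import DEFAULT_TERMS, FitResult, ModelSpec, fit_reml
from .errors import PairingError


@dataclass(frozen=True)
class HeritabilityEstimate:
    trait: str
    treatment: str
    h2: float
    se: float | None


@dataclass
class GeneticCorrelationMatrix:
    traits: list
    r: pd.DataFrame
    clamped: pd.DataFrame  # boolean flags

    def __post_init__(self):
        assert np.allclose(np.diag(self.r.to_numpy()), 1.0, equal_nan=True)


def narrow_sense_heritability(
    family_var: float,
    interaction_var: float,
    residual_var: float,
    n_replicates: int,
) -> float:
    """Family-mean narrow-sense heritability."""
    if min(family_var, interaction_var, residual_var) < 0:
        raise ValueError("variance components must be non-negative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    denom = family_var + interaction_var / n_replicates + residual_var / n_replicates
    if denom <= 0:
        raise ValueError("all components zero; heritability undefined")
    return family_var / denom


def heritability_from_fit(
    fit: FitResult, n_replicates: int, treatment: str = ""
) -> HeritabilityEstimate:
    """Heritability (and delta-method SE) from a fitted model.

    When the family x replicate term was dropped as confounded with the plot
    residual, the residual component already contains it and the formula
    reduces to sf2 / (sf2 + sresid2/nR), which is identical to the three-term
    form evaluated on the summed components.
    """
    est = fit.estimates
    sf2 = est.get("family", 0.0)
    sfr2 = est.get("family_by_replicate", 0.0)
    se2 = est.get("residual", 0.0)
    h2 = narrow_sense_heritability(sf2, sfr2, se2, n_replicates)
    se = None
    if fit.vcov is not None and "family" in fit.vcov.index:
        # delta method on the components present in the fit's covariance
        grads = {}
        denom = sf2 + sfr2 / n_replicates + se2 / n_replicates
        grads["family"] = (denom - sf2) / denom**2
        grads["family_by_replicate"] = -sf2 / (n_replicates * denom**2)
        grads["residual"] = -sf2 / (n_replicates * denom**2)
        terms = [t for t in fit.vcov.index if t in grads]
        g = np.array([grads[t] for t in terms])
        var = float(g @ fit.vcov.loc[terms, terms].to_numpy() @ g)
        se = float(np.sqrt(var)) if var > 0 else None
    return HeritabilityEstimate(fit.response, treatment, h2, se)


def _paired(data: pd.DataFrame, trait_x: str, trait_y: str) -> pd.DataFrame:
    for col in (trait_x, trait_y):
        if col not in data.columns:
            raise PairingError(f"trait column {col!r} absent from the plot table")
    paired = data.dropna(subset=[trait_x, trait_y])
    if len(paired) < 3:
        raise PairingError(
            f"traits {trait_x!r} and {trait_y!r} share only {len(paired)} plots"
        )
    return paired.reset_index(drop=True)


def pairwise_components(
    data: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    terms: tuple = DEFAULT_TERMS,
) -> dict:
    """Per-term variances of X and Y and their covariance, in original units.

    Fits X, Y and the unit-scaled sum and difference X'+Y', X'-Y' by
    univariate REML and recovers each term's covariance from the polarization
    identity cov_t = [v_t(X'+Y') - v_t(X'-Y')]/4, rescaled back by the two
    sample standard deviations.

    Returns ``{term: {"var_x", "var_y", "cov"}}`` over the fitted terms
    (including ``"residual"``).
    """
    paired = _paired(data, trait_x, trait_y)
    sx = float(paired[trait_x].std(ddof=1))
    sy = float(paired[trait_y].std(ddof=1))
    if sx == 0 or sy == 0:
        raise PairingError("a trait is constant; covariance undefined")
    work = paired.copy()
    work["_zx"] = paired[trait_x] / sx
    work["_zy"] = paired[trait_y] / sy
    work["_zsum"] = work["_zx"] + work["_zy"]
    work["_zdiff"] = work["_zx"] - work["_zy"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-term drops repeat 4x
        fit_x = fit_reml(work, ModelSpec("_zx", terms))
        fit_y = fit_reml(work, ModelSpec("_zy", terms))
        # sum/difference responses may carry a negative family "variance"
        # (it encodes a covariance); truncating it at zero would bias covA
        fit_s = fit_reml(work, ModelSpec("_zsum", terms),
                         unconstrained=("family",))
        fit_d = fit_reml(work, ModelSpec("_zdiff", terms),
                         unconstrained=("family",))
    out = {}
    for term in fit_x.estimates:
        vx, vy = fit_x.estimates[term], fit_y.estimates[term]
        vs = fit_s.estimates.get(term, 0.0)
        vd = fit_d.estimates.get(term, 0.0)
        out[term] = {
            "var_x": vx * sx * sx,
            "var_y": vy * sy * sy,
            "cov": 0.25 * (vs - vd) * sx * sy,
        }
    return out


def genetic_covariance(
    data: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    terms: tuple = DEFAULT_TERMS,
) -> tuple[float, float, float]:
    """Family (additive) covariance and the two family variances."""
    comp = pairwise_components(data, trait_x, trait_y, terms)["family"]
    return comp["cov"], comp["var_x"], comp["var_y"]


def genetic_correlation(
    data: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    terms: tuple = DEFAULT_TERMS,
    clamp: bool = False,
) -> float:
    """Genetic correlation rA(X, Y); unclamped by default (may overshoot 1)."""
    cov, vx, vy = genetic_covariance(data, trait_x, trait_y, terms)
    if vx <= 0 or vy <= 0:
        return np.nan
    r = cov / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0)) if clamp else float(r)


def genetic_correlation_matrix(
    data: pd.DataFrame,
    traits,
    terms: tuple = DEFAULT_TERMS,
) -> GeneticCorrelationMatrix:
    """Symmetric rA matrix over the given traits; overshoots clamped and flagged."""
    traits = list(traits)
    if len(traits) < 2:
        raise ValueError("need at least two traits")
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    clamped = pd.DataFrame(False, index=traits, columns=traits)
    for tx, ty in itertools.combinations(traits, 2):
        raw = genetic_correlation(data, tx, ty, terms, clamp=False)
        if np.isnan(raw):
            warnings.warn(
                f"zero family variance for {tx!r} or {ty!r}; rA undefined",
                stacklevel=2,
            )
            val = np.nan
        else:
            val = float(np.clip(raw, -1.0, 1.0))
            if val != raw:
                warnings.warn(
                    f"rA({tx}, {ty}) = {raw:.3f} outside [-1, 1]; clamped",
                    stacklevel=2,
                )
                clamped.loc[tx, ty] = clamped.loc[ty, tx] = True
        r.loc[tx, ty] = r.loc[ty, tx] = val
    return GeneticCorrelationMatrix(traits, r, clamped)


def phenotypic_correlations(
    trait_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided t-test p-values over a family x trait matrix.

    Computed on BLUP-adjusted family means; no multiplicity adjustment is
    applied.  Constant columns yield NaN with a warning.
    """
    if len(trait_matrix) < 3:
        raise ValueError("need at least 3 families")
    cols = list(trait_matrix.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for cx, cy in itertools.combinations(cols, 2):
        sub = trait_matrix[[cx, cy]].dropna()
        if sub[cx].nunique() < 2 or sub[cy].nunique() < 2:
            warnings.warn(f"constant column {cx!r} or {cy!r}; r undefined", stacklevel=2)
            r.loc[cx, cy] = r.loc[cy, cx] = np.nan
            p.loc[cx, cy] = p.loc[cy, cx] = np.nan
            continue
        res = stats.pearsonr(sub[cx], sub[cy])
        r.loc[cx, cy] = r.loc[cy, cx] = float(res.statistic)
        p.loc[cx, cy] = p.loc[cy, cx] = float(res.pvalue)
    return r, p
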