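"""Selection theory: intensities, predicted gain, Smith-Hazel index, overlap.

Predicted per-cycle genetic gain under among-half-sib-family selection follows
the breeder's equation

    dG = k * c * sf2 / sigma_PF,

where ``k`` is the standardised selection differential, ``c`` the parental
control factor (0.5 for half-sib families), ``sf2`` the family variance
component (already one quarter of the total additive variance under the
half-sib structure) and ``sigma_PF = sqrt(sf2 + sfR2/nR + se2/nR)`` the
phenotypic standard deviation among family means.

The Smith-Hazel multi-trait index solves P b = A w for the coefficient vector
b, with P and A the among-family phenotypic and additive (co)variance
matrices and w the (economic or desired-gain) weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats


@dataclass(frozen=True)
class SelectionPlan:
    """Selection pressure and the derived differential driving gain formulas."""

    pressure: float
    intensity: float = None  # type: ignore[assignment]
    parental_control: float = 0.5
    weights: tuple = (1.0, 1.0)

    def __post_init__(self):
        if not 0.0 < self.pressure < 1.0:
            raise ValueError(f"pressure must be in (0, 1), got {self.pressure}")
        if not 0.0 < self.parental_control <= 1.0:
            raise ValueError("parental control must be in (0, 1]")
        if self.intensity is None:
            object.__setattr__(self, "intensity", selection_intensity(self.pressure))
        elif self.intensity <= 0:
            raise ValueError("intensity must be positive")


@dataclass(frozen=True)
class GainEstimate:
    trait: str
    pressure: float
    intensity: float
    gain: float
    gain_percent: float
    sigma_pf: float


@dataclass
class IndexResult:
    coefficients: np.ndarray
    scores: pd.Series
    ranking: list = field(default_factory=list)


def selection_intensity(p: float, population_size: int | None = None) -> float:
    """Standardised selection differential for truncation at proportion ``p``.

    Infinite-population formula k = phi(z)/p with z the upper-p standard
    normal quantile.  With ``population_size`` N given, applies the Burrows
    finite-population correction k - (N - n)/(2 k n (N + 1)) for n = ceil(pN)
    selected families (off by default).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"selection pressure must be in (0, 1), got {p}")
    z = stats.norm.ppf(1.0 - p)
    k = float(stats.norm.pdf(z) / p)
    if population_size is not None:
        n = math.ceil(p * population_size)
        k -= (population_size - n) / (2.0 * k * n * (population_size + 1))
    return k


def family_phenotypic_sd(
    family_var: float, interaction_var: float, residual_var: float, n_replicates: int
) -> float:
    """Phenotypic standard deviation among family means, sqrt(sf2+sfR2/nR+se2/nR)."""
    if min(family_var, interaction_var, residual_var) < 0:
        raise ValueError("variance components must be non-negative")
    return math.sqrt(
        family_var + interaction_var / n_replicates + residual_var / n_replicates
    )


def predicted_gain(
    plan: SelectionPlan,
    family_var: float,
    sigma_pf: float,
    mean: float,
    trait: str = "",
) -> GainEstimate:
    """Per-cycle gain under among-family selection, absolute and % of |mean|."""
    if sigma_pf <= 0:
        raise ValueError("sigma_pf must be positive (degenerate population)")
    if mean == 0:
        raise ValueError("trait mean must be non-zero to express a percent gain")
    gain = plan.intensity * plan.parental_control * family_var / sigma_pf
    return GainEstimate(
        trait=trait,
        pressure=plan.pressure,
        intensity=plan.intensity,
        gain=gain,
        gain_percent=100.0 * gain / abs(mean),
        sigma_pf=sigma_pf,
    )


def smith_hazel_coefficients(P: np.ndarray, A: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Index coefficients b solving P b = A w.

    ``P`` must be symmetric positive definite and ``A`` symmetric; dimensions
    must agree.  The solution is checked to a 1e-8 relative residual.
    """
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    w = np.asarray(w, dtype=float)
    if P.shape != A.shape or P.shape[0] != P.shape[1] or len(w) != P.shape[0]:
        raise ValueError("P, A and w dimensions do not agree")
    if not np.allclose(P, P.T, atol=1e-8) or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("P and A must be symmetric")
    try:
        c, low = linalg.cho_factor(P)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "P is not positive definite; cannot build a Smith-Hazel index"
        ) from exc
    rhs = A @ w
    b = linalg.cho_solve((c, low), rhs)
    resid = np.linalg.norm(P @ b - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and resid / scale > 1e-8:
        raise np.linalg.LinAlgError(
            f"index system ill-conditioned: relative residual {resid / scale:.2e}"
        )
    return b


def index_scores(b: np.ndarray, trait_matrix: pd.DataFrame) -> IndexResult:
    """Family index scores b'x and the descending ranking (ties by family ID)."""
    b = np.asarray(b, dtype=float)
    if len(b) != trait_matrix.shape[1]:
        raise ValueError("coefficient length must equal the trait count")
    complete = trait_matrix.dropna()
    n_dropped = len(trait_matrix) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} families with missing trait values excluded from the index",
            stacklevel=2,
        )
    scores = pd.Series(
        complete.to_numpy() @ b, index=complete.index, name="index_score"
    )
    order = sorted(scores.index, key=lambda fam: (-scores[fam], fam))
    return IndexResult(coefficients=b, scores=scores, ranking=order)


def correlated_response(
    plan: SelectionPlan,
    h_x: float,
    h_y: float,
    r_a: float,
    sigma_py: float,
) -> float:
    """Correlated response in trait Y to selection on trait X: k c hX hY rA sigmaPY.

    ``h_x``/``h_y`` are square roots of the narrow-sense heritabilities;
    the result is signed (negative rA yields a negative response).
    """
    if not 0.0 <= h_x <= 1.0 or not 0.0 <= h_y <= 1.0:
        raise ValueError("heritability square roots must be in [0, 1]")
    if abs(r_a) > 1.0:
        raise ValueError("genetic correlation must be in [-1, 1]")
    if sigma_py < 0:
        raise ValueError("sigma_py must be non-negative")
    return plan.intensity * plan.parental_control * h_x * h_y * r_a * sigma_py


def select_top(values, p: float) -> list:
    """IDs of the top ceil(p*n) families by value; ties broken by family ID."""
    series = pd.Series(values).dropna()
    if series.empty:
        raise ValueError("no values to select from")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"selection pressure must be in (0, 1], got {p}")
    m = math.ceil(p * len(series))
    order = sorted(series.index, key=lambda fam: (-series[fam], fam))
    cut = series[order[m - 1]]
    if m < len(series) and series[order[m]] == cut:
        warnings.warn(
            "tie at the selection boundary broken deterministically by family ID",
            stacklevel=2,
        )
    return order[:m]


def selection_overlap(sets: dict) -> dict:
    """Pairwise and overall intersections of named family selections.

    Returns ``{"sizes": {name: n}, "pairwise": {"a&b": {...}}, "common":
    {...}}`` with both cardinalities and sorted memberships, JSON-ready.
    """
    if len(sets) < 2:
        raise ValueError("need at least two selections to compare")
    sets = {name: set(members) for name, members in sets.items()}
    names = sorted(sets)
    out = {
        "sizes": {name: len(sets[name]) for name in names},
        "pairwise": {},
    }
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = sorted(sets[a] & sets[b])
            out["pairwise"][f"{a}&{b}"] = {"count": len(inter), "families": inter}
    common = set.intersection(*sets.values())
    out["common"] = {"count": len(common), "families": sorted(common)}
    return out
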