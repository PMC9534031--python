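"""Derive analysis traits from plant-level dry-matter records.

Five traits are produced at the family x replicate plot (quadrant) level:

* ``shoot_dm``, ``root_dm`` — plot means of the measured dry weights (mg);
* ``rsr`` — root:shoot ratio, the plot mean of per-plant ratios (not the
  ratio of plot means — a documented, tested choice);
* ``shoot_sp``, ``root_sp`` — symbiotic potential (%), defined only for
  Rhizobium-inoculated plants:

      SP% = 100 * (DM_inoculated - DM_neg) / (DM_pos(family) - DM_neg)

  where DM_neg is the global mean of the unlabelled no-N/no-Rhizobium bulk
  and DM_pos(family) the mineral-N mean of the same family.  SP may be
  negative (plant below the seed-reserve baseline) or exceed 100%; no
  truncation is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DegenerateControlError, MissingControlError
from .simulate import NEG, NPLUS, TA1

SP_TRAITS = {"shoot_sp": "shoot", "root_sp": "root"}
PLOT_COLUMNS = (
    "treatment",
    "family",
    "replicate",
    "row",
    "column",
    "trait",
    "value",
    "n_plants",
)


def compute_rsr(root_dm: float, shoot_dm: float) -> float:
    """Root:shoot dry-matter ratio of one plant (dimensionless)."""
    if shoot_dm <= 0:
        raise ValueError(f"shoot_dm must be positive to form a ratio, got {shoot_dm}")
    return root_dm / shoot_dm


def negative_control_mean(plants: pd.DataFrame, organ: str = "shoot") -> float:
    """Mean dry matter (mg) of the unlabelled negative-control bulk."""
    if organ not in ("shoot", "root"):
        raise ValueError(f"organ must be 'shoot' or 'root', got {organ!r}")
    values = plants.loc[plants["treatment"] == NEG, f"{organ}_dm_mg"].dropna()
    if values.empty:
        raise MissingControlError("no negative-control (NEG) records present")
    return float(values.mean())


def symbiotic_potential(inoculated, uninoculated_mean: float, positive_mean: float):
    """Percent of mineral-N growth attained through symbiosis, baseline-corrected.

    Accepts a scalar or array of inoculated dry weights; linear in the
    inoculated value, so the plot mean of per-plant SPs equals the SP of the
    plot-mean dry weight.
    """
    denom = positive_mean - uninoculated_mean
    if denom == 0:
        raise DegenerateControlError(
            "positive- and negative-control means coincide; SP undefined"
        )
    return 100.0 * (np.asarray(inoculated, dtype=float) - uninoculated_mean) / denom


def _plot_means(sub: pd.DataFrame, col: str) -> pd.DataFrame:
    ok = sub.dropna(subset=[col])
    grouped = ok.groupby(["family", "replicate"], observed=True)
    out = grouped.agg(
        value=(col, "mean"),
        row=("row", "first"),
        column=("column", "first"),
        n_plants=(col, "size"),
    ).reset_index()
    return out


def derive_trait_table(plants: pd.DataFrame, sp_basis: str = "per_plant") -> pd.DataFrame:
    """Plot-level trait table from plant records.

    ``sp_basis`` selects whether SP is averaged over per-plant values
    (``"per_plant"``, default) or computed from the plot-mean dry weight
    (``"plot_mean"``); the two coincide when no plants are excluded, because
    SP is linear in the plant's dry weight.
    """
    if sp_basis not in ("per_plant", "plot_mean"):
        raise ValueError(f"unknown sp_basis {sp_basis!r}")
    plants = plants.copy()

    neg_means = {}
    try:
        for organ in ("shoot", "root"):
            neg_means[organ] = negative_control_mean(plants, organ)
    except MissingControlError:
        neg_means = {}
        warnings.warn(
            "no negative-control records; symbiotic potential not derived",
            stacklevel=2,
        )

    npos = plants[plants["treatment"] == NPLUS].dropna(subset=["family"])
    pos_means = (
        npos.groupby("family", observed=True)[["shoot_dm_mg", "root_dm_mg"]].mean()
        if not npos.empty
        else pd.DataFrame(columns=["shoot_dm_mg", "root_dm_mg"])
    )
    if npos.empty:
        warnings.warn(
            "no mineral-N (NPLUS) records; symbiotic potential not derived",
            stacklevel=2,
        )

    pieces = []
    for treatment in (TA1, NPLUS):
        sub = plants[plants["treatment"] == treatment].dropna(subset=["family"])
        if sub.empty:
            continue
        sub = sub.copy()
        for trait, col in (("shoot_dm", "shoot_dm_mg"), ("root_dm", "root_dm_mg")):
            plot = _plot_means(sub, col)
            plot["trait"] = trait
            plot["treatment"] = treatment
            pieces.append(plot)

        positive = sub["shoot_dm_mg"] > 0
        n_bad = int((~positive & sub["shoot_dm_mg"].notna()).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} {treatment} plants with non-positive shoot DM excluded "
                "from RSR",
                stacklevel=2,
            )
        sub["rsr_plant"] = np.where(
            positive, sub["root_dm_mg"] / sub["shoot_dm_mg"], np.nan
        )
        plot = _plot_means(sub, "rsr_plant")
        plot["trait"] = "rsr"
        plot["treatment"] = treatment
        pieces.append(plot)

        if treatment == TA1 and neg_means and not pos_means.empty:
            pieces.extend(_derive_sp(sub, neg_means, pos_means, sp_basis))

    if not pieces:
        return pd.DataFrame(columns=list(PLOT_COLUMNS))
    table = pd.concat(pieces, ignore_index=True)
    table = table[list(PLOT_COLUMNS)].sort_values(
        ["treatment", "trait", "family", "replicate"], kind="mergesort"
    )
    return table.reset_index(drop=True)


def _derive_sp(ta1: pd.DataFrame, neg_means: dict, pos_means: pd.DataFrame,
               sp_basis: str) -> list[pd.DataFrame]:
    pieces = []
    missing = sorted(set(ta1["family"].unique()) - set(pos_means.index))
    if missing:
        warnings.warn(
            f"{len(missing)} families lack mineral-N records; SP unavailable for "
            f"families {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=3,
        )
    for sp_trait, organ in SP_TRAITS.items():
        col = f"{organ}_dm_mg"
        neg = neg_means[organ]
        pos = ta1["family"].map(pos_means[col])
        denom = pos - neg
        degenerate = denom == 0
        if degenerate.any():
            bad = sorted(ta1.loc[degenerate, "family"].unique())
            warnings.warn(
                f"degenerate controls (positive mean equals negative mean) for "
                f"families {bad}; their {sp_trait} excluded",
                stacklevel=3,
            )
        sp_col = f"_{sp_trait}"
        with np.errstate(invalid="ignore", divide="ignore"):
            ta1[sp_col] = np.where(
                degenerate, np.nan, 100.0 * (ta1[col] - neg) / denom
            )
        if sp_basis == "per_plant":
            plot = _plot_means(ta1, sp_col)
        else:  # plot_mean basis: SP of the plot-mean dry weight
            plot = _plot_means(ta1, col)
            fam_pos = plot["family"].map(pos_means[col])
            plot["value"] = 100.0 * (plot["value"] - neg) / (fam_pos - neg)
            plot = plot[np.isfinite(plot["value"])]
        plot = plot.dropna(subset=["value"])
        plot["trait"] = sp_trait
        plot["treatment"] = TA1
        pieces.append(plot)
    return pieces


def to_wide(plot_table: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Pivot one treatment's plot table to a wide frame for model fitting.

    Returns columns family, replicate, row, column plus one column per trait.
    """
    sub = plot_table[plot_table["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no plot observations for treatment {treatment!r}")
    keys = ["family", "replicate", "row", "column"]
    wide = sub.pivot_table(
        index=keys, columns="trait", values="value", observed=True
    ).reset_index()
    wide.columns.name = None
    return wide


def write_plot_csv(plot_table: pd.DataFrame, path) -> None:
    plot_table.to_csv(path, index=False, float_format="%.10g")


def read_plot_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"treatment": str, "trait": str})
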