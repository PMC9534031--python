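"""End-to-end analysis pipeline: plant records in, report tables out.

Chains trait derivation, REML component estimation with BLUPs, heritability,
genetic and phenotypic correlations, predicted gains, the Smith-Hazel index,
selection overlap and pattern analysis, writing every stage as CSV/JSON into
an output directory.  All defaults are logged so a run is reproducible from
its log alone.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetics, pattern, selection, traits
from . import simulate as sim
from .reml import ModelSpec, fit_reml
from .simulate import NPLUS, TA1

log = logging.getLogger("cloverqg")

DM_TRAITS = ("shoot_dm", "root_dm", "rsr")
SP_TRAITS = ("shoot_sp", "root_sp")


@dataclass
class RunConfig:
    input: str | Path
    outdir: str | Path = "cloverqg_out"
    treatments: tuple = (TA1, NPLUS)
    sp_basis: str = "per_plant"
    pressures: tuple = (0.05, 0.10, 0.20)
    parental_control: float = 0.5
    index_traits: tuple = ("shoot_dm", "shoot_sp")
    index_weights: tuple = (1.0, 1.0)
    hartigan_threshold: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for p in self.pressures:
            if not 0.0 < p < 1.0:
                raise ValueError(f"selection pressure {p} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("treatments", "pressures", "index_traits", "index_weights"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    log.info("wrote %s (%d rows)", path, len(df))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return a summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run configuration: %s", asdict(config))

    plants = sim.read_plant_csv(config.input)
    log.info("read %d plant records from %s", len(plants), config.input)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        plot = traits.derive_trait_table(plants, sp_basis=config.sp_basis)
    for w in caught:
        log.warning("derive: %s", w.message)
    traits.write_plot_csv(plot, outdir / "plot_observations.csv")

    summary: dict = {"config": {k: str(v) if isinstance(v, Path) else v
                                for k, v in asdict(config).items()},
                     "treatments": {}}
    comp_rows, h2_rows, blup_rows, gain_rows = [], [], [], []
    fits: dict = {}
    adjusted: dict = {}

    for treatment in config.treatments:
        if treatment not in set(plot["treatment"]):
            log.warning("treatment %s absent from the data; skipped", treatment)
            continue
        wide = traits.to_wide(plot, treatment)
        n_reps = int(wide["replicate"].nunique())
        trait_cols = [t for t in DM_TRAITS + SP_TRAITS if t in wide.columns]
        fits[treatment] = {}
        adj_cols = {}
        for trait in trait_cols:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = fit_reml(wide, ModelSpec(trait))
            for w in caught:
                log.info("fit %s/%s: %s", treatment, trait, w.message)
            fits[treatment][trait] = fit
            for term, comp in fit.components.items():
                comp_rows.append(
                    dict(treatment=treatment, trait=trait, term=term,
                         estimate=comp.estimate,
                         se=comp.se if comp.se is not None else np.nan,
                         significant=comp.significant)
                )
            h2 = genetics.heritability_from_fit(fit, n_reps, treatment)
            h2_rows.append(dict(treatment=treatment, trait=trait, h2=h2.h2,
                                se=h2.se if h2.se is not None else np.nan))
            for fam, blup in fit.blups.items():
                blup_rows.append(dict(treatment=treatment, trait=trait,
                                      family=fam, blup=blup,
                                      adjusted_mean=fit.mu + blup))
            adj_cols[trait] = fit.adjusted_means
            log.info("fit %s/%s: logL=%.4f, %d iterations, converged=%s",
                     treatment, trait, fit.loglik, fit.iterations, fit.converged)
        adjusted[treatment] = pd.DataFrame(adj_cols)
        summary["treatments"][treatment] = {
            "n_replicates": n_reps,
            "traits": trait_cols,
            "h2": {r["trait"]: r["h2"] for r in h2_rows
                   if r["treatment"] == treatment},
        }

        # genetic correlations within the treatment
        if len(trait_cols) >= 2:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                gmat = genetics.genetic_correlation_matrix(wide, trait_cols)
            for w in caught:
                log.warning("rA %s: %s", treatment, w.message)
            gmat.r.round(10).to_csv(outdir / f"genetic_correlations_{treatment}.csv")
            log.info("wrote %s", outdir / f"genetic_correlations_{treatment}.csv")

        # phenotypic correlations on BLUP-adjusted means
        r, p = genetics.phenotypic_correlations(adjusted[treatment])
        r.round(10).to_csv(outdir / f"phenotypic_r_{treatment}.csv")
        p.to_csv(outdir / f"phenotypic_p_{treatment}.csv", float_format="%.6g")

        # predicted gains for traits with significant family variance
        for trait in trait_cols:
            fit = fits[treatment][trait]
            fam = fit.components["family"]
            if fam.significant is not True:
                log.info("gain %s/%s skipped: family variance not significant",
                         treatment, trait)
                continue
            est = fit.estimates
            sigma_pf = selection.family_phenotypic_sd(
                est.get("family", 0.0), est.get("family_by_replicate", 0.0),
                est.get("residual", 0.0), n_reps)
            mean = float(wide[trait].mean())
            for p_sel in config.pressures:
                plan = selection.SelectionPlan(
                    pressure=p_sel, parental_control=config.parental_control)
                g = selection.predicted_gain(plan, fam.estimate, sigma_pf, mean,
                                             trait=trait)
                gain_rows.append(dict(treatment=treatment, trait=trait,
                                      pressure=p_sel, intensity=g.intensity,
                                      gain=g.gain, gain_percent=g.gain_percent,
                                      sigma_pf=g.sigma_pf))

    _write_csv(pd.DataFrame(comp_rows), outdir / "variance_components.csv")
    _write_csv(pd.DataFrame(h2_rows), outdir / "heritability.csv")
    _write_csv(pd.DataFrame(blup_rows), outdir / "blups.csv")
    if gain_rows:
        _write_csv(pd.DataFrame(gain_rows), outdir / "predicted_gains.csv")

    # --- Smith-Hazel index and selection overlap (inoculated arm) ---------
    overlap_out = {}
    ta1 = fits.get(TA1, {})
    ix, iy = config.index_traits
    if ix in ta1 and iy in ta1:
        wide = traits.to_wide(plot, TA1)
        n_reps = int(wide["replicate"].nunique())
        comp = genetics.pairwise_components(wide, ix, iy)
        fam, res = comp["family"], comp["residual"]
        fr = comp.get("family_by_replicate", {"var_x": 0, "var_y": 0, "cov": 0})
        P = np.array([
            [fam["var_x"] + fr["var_x"] / n_reps + res["var_x"] / n_reps,
             fam["cov"] + fr["cov"] / n_reps + res["cov"] / n_reps],
            [fam["cov"] + fr["cov"] / n_reps + res["cov"] / n_reps,
             fam["var_y"] + fr["var_y"] / n_reps + res["var_y"] / n_reps],
        ])
        A = np.array([[fam["var_x"], fam["cov"]], [fam["cov"], fam["var_y"]]])
        b = selection.smith_hazel_coefficients(P, A, np.array(config.index_weights))
        log.info("Smith-Hazel coefficients for %s: %s", config.index_traits, b)
        matrix = adjusted[TA1][[ix, iy]]
        index = selection.index_scores(b, matrix)
        index_df = pd.DataFrame({
            "family": index.scores.index,
            "score": index.scores.to_numpy(),
        }).sort_values("score", ascending=False, kind="mergesort")
        index_df["rank"] = np.arange(1, len(index_df) + 1)
        _write_csv(index_df, outdir / "smith_hazel_index.csv")
        summary["smith_hazel_b"] = [float(x) for x in b]

        for p_sel in config.pressures:
            sets = {
                ix: selection.select_top(adjusted[TA1][ix], p_sel),
                iy: selection.select_top(adjusted[TA1][iy], p_sel),
                "smith_hazel": selection.select_top(index.scores, p_sel),
            }
            overlap = selection.selection_overlap(sets)
            overlap["selected"] = {k: [int(f) for f in v] for k, v in sets.items()}
            overlap_out[f"{p_sel:g}"] = overlap
        with open(outdir / "selection_overlap.json", "w", encoding="utf-8") as fh:
            json.dump(overlap_out, fh, indent=1, sort_keys=True, default=int)
        log.info("wrote %s", outdir / "selection_overlap.json")
    else:
        log.warning("index traits %s unavailable; Smith-Hazel stage skipped",
                    config.index_traits)

    # --- pattern analysis ---------------------------------------------------
    for treatment, matrix in adjusted.items():
        if matrix.shape[1] < 2 or len(matrix) < 3:
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            clusters = pattern.optimal_cluster(
                matrix, threshold=config.hartigan_threshold)
            biplot = pattern.pca_biplot(matrix)
        for w in caught:
            log.warning("pattern %s: %s", treatment, w.message)
        cdf = clusters.assignments.rename("group").reset_index()
        _write_csv(cdf, outdir / f"clusters_{treatment}.csv")
        sdf = biplot.scores.reset_index()
        _write_csv(sdf, outdir / f"pca_scores_{treatment}.csv")
        ldf = biplot.loadings.reset_index(names="trait")
        _write_csv(ldf, outdir / f"pca_loadings_{treatment}.csv")
        scree = pd.DataFrame({
            "component": np.arange(1, len(biplot.variance_proportions) + 1),
            "proportion": biplot.variance_proportions,
        })
        _write_csv(scree, outdir / f"pca_scree_{treatment}.csv")
        summary["treatments"].setdefault(treatment, {})["pattern"] = {
            "k": int(clusters.k),
            "group_sizes": clusters.assignments.value_counts().sort_index()
            .to_dict(),
            "pc_proportions": [float(x)
                               for x in biplot.variance_proportions[:2]],
        }
        log.info("pattern %s: k=%d, PC1+PC2=%.1f%%", treatment, clusters.k,
                 100 * biplot.variance_proportions[:2].sum())

    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    log.info("wrote %s", outdir / "run_summary.json")
    return summary
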