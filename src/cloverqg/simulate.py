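"""Synthetic half-sib family trials with known ground-truth parameters.

Emulates a controlled-environment white clover trial: ``n_families`` half-sib
families laid out in containers of four quadrants inside each of
``n_replicates`` growth rooms, with a Rhizobium-inoculated arm (``TA1``), a
mineral-N positive-control arm (``NPLUS``) and an unlabelled bulk negative
control (``NEG``).  Each quadrant (plot) value follows the additive random
model

    y = mu + family + replicate + family x replicate + row + column + plot error

with every effect drawn from a zero-mean normal at its configured variance.
Variances are specified at the plot (quadrant-mean) scale; an optional
plant-level residual adds within-quadrant noise that averages down in the
quadrant mean.  Family effects are drawn once per family and reused across
replicates and treatment arms (shared genetics), with a configurable
shoot-root genetic correlation.

The additive-normal model can emit non-positive dry weights when the residual
standard deviation is comparable to the mean (as it is at realistic variance
levels); such values are retained for fidelity to the model — downstream trait
derivation guards the ratio traits.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigError

TA1 = "TA1"
NPLUS = "NPLUS"
NEG = "NEG"
TREATMENTS = (TA1, NPLUS, NEG)

#: traits measured on every plant, in mg dry matter
MEASURED_TRAITS = ("shoot_dm", "root_dm")

PLANT_COLUMNS = (
    "family",
    "replicate",
    "container",
    "quadrant",
    "row",
    "column",
    "treatment",
    "shoot_dm_mg",
    "root_dm_mg",
)


@dataclass(frozen=True)
class VarianceSet:
    """Variance components (squared trait units) for one treatment x trait.

    ``residual`` is the plot-level (quadrant-mean) error variance; ``plant``
    is an optional within-quadrant plant-to-plant variance.
    """

    family: float
    replicate: float
    family_by_replicate: float
    row: float
    column: float
    residual: float
    plant: float = 0.0

    def validate(self, label: str = "") -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ConfigError(
                    f"variance {name!r} {label} must be non-negative, got {value}"
                )


@dataclass(frozen=True)
class NegativeControl:
    """Unlabelled bulk arm: containers of mixed-family seedlings, no structure."""

    n_containers: int = 4  # per replicate
    bulk_mean: dict = field(
        default_factory=lambda: {"shoot_dm": 2.15, "root_dm": 1.59}
    )
    bulk_sd: dict = field(
        default_factory=lambda: {"shoot_dm": 0.55, "root_dm": 0.40}
    )

    def validate(self) -> None:
        if self.n_containers < 0:
            raise ConfigError("negative_control.n_containers must be >= 0")
        for trait, sd in self.bulk_sd.items():
            if sd < 0:
                raise ConfigError(f"negative_control bulk_sd[{trait!r}] must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated trial, including the random seed."""

    n_families: int = 120
    n_replicates: int = 2
    plants_per_quadrant: int = 16
    containers_per_replicate: int = 30
    treatment_means: dict = field(
        default_factory=lambda: {
            TA1: {"shoot_dm": 11.4, "root_dm": 5.03},
            NPLUS: {"shoot_dm": 25.1, "root_dm": 9.00},
        }
    )
    components: dict = field(
        default_factory=lambda: {
            TA1: {
                "shoot_dm": VarianceSet(13.5, 1.0, 4.7, 0.5, 0.5, 49.6),
                "root_dm": VarianceSet(2.2, 0.2, 0.9, 0.1, 0.1, 10.2),
            },
            NPLUS: {
                "shoot_dm": VarianceSet(23.3, 2.0, 23.6, 1.0, 1.0, 220.6),
                "root_dm": VarianceSet(3.4, 0.3, 2.6, 0.15, 0.15, 30.7),
            },
        }
    )
    #: correlation between the family effects of shoot_dm and root_dm
    genetic_correlation: float = 0.97
    negative_control: NegativeControl | None = field(default_factory=NegativeControl)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_families", "n_replicates", "plants_per_quadrant",
                     "containers_per_replicate"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if not -1.0 <= self.genetic_correlation <= 1.0:
            raise ConfigError("genetic_correlation must be in [-1, 1]")
        bad = set(self.treatment_means) - {TA1, NPLUS}
        if bad:
            raise ConfigError(f"unknown treatments in treatment_means: {sorted(bad)}")
        for treatment, traits in self.treatment_means.items():
            if treatment not in self.components:
                raise ConfigError(f"no variance components for treatment {treatment!r}")
            for trait in traits:
                if trait not in MEASURED_TRAITS:
                    raise ConfigError(f"unknown trait {trait!r}")
                if trait not in self.components[treatment]:
                    raise ConfigError(
                        f"no variance components for {treatment!r}/{trait!r}"
                    )
                self.components[treatment][trait].validate(f"({treatment}/{trait})")
        if self.negative_control is not None:
            self.negative_control.validate()


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The trial at the study's own scale: 120 families, 2 rooms, 16 plants/quadrant."""
    return SimulationConfig(seed=seed, **overrides)


def _container_grid(n_containers: int) -> tuple[np.ndarray, np.ndarray]:
    """Bench positions: containers in a near-square grid, quadrants 2x2 within."""
    ncols = max(1, math.ceil(math.sqrt(n_containers)))
    idx = np.arange(n_containers)
    return idx // ncols, idx % ncols


def make_design(
    n_families: int,
    n_replicates: int,
    containers_per_replicate: int,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Randomised layout of one treatment arm.

    Each container holds four quadrants; every family appears exactly once per
    replicate, assigned to a (container, quadrant) slot by a seeded random
    permutation.  Row/column indices locate the quadrant on the bench grid and
    are numbered within replicate.

    Returns a frame with columns replicate, container, quadrant, row, column,
    family (one row per quadrant).
    """
    if n_families < 1 or n_replicates < 1 or containers_per_replicate < 1:
        raise ConfigError("design counts must all be >= 1")
    capacity = 4 * containers_per_replicate
    if n_families > capacity:
        raise CapacityError(
            f"{n_families} families need at least {math.ceil(n_families / 4)} "
            f"containers per replicate; only {containers_per_replicate} provided"
        )
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    crow, ccol = _container_grid(containers_per_replicate)
    frames = []
    for rep in range(1, n_replicates + 1):
        # slots in fixed container/quadrant order; families permuted over them
        slots = [(c, q) for c in range(containers_per_replicate) for q in range(4)]
        perm = rng.permutation(n_families)
        rows = []
        for fam_idx, (c, q) in zip(perm, slots[:n_families]):
            rows.append(
                (
                    rep,
                    c + 1,
                    q + 1,
                    int(2 * crow[c] + q // 2 + 1),
                    int(2 * ccol[c] + q % 2 + 1),
                    int(fam_idx) + 1,
                )
            )
        frames.append(
            pd.DataFrame(
                rows,
                columns=["replicate", "container", "quadrant", "row", "column", "family"],
            )
        )
    return pd.concat(frames, ignore_index=True)


def _draw_group_effects(rng, labels, variance) -> dict:
    sd = math.sqrt(variance)
    uniq = sorted(set(labels))
    draws = rng.standard_normal(len(uniq)) * sd
    return dict(zip(uniq, draws))


def simulate_trial(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate one trial; returns (plant table, truth record).

    The plant table has columns ``PLANT_COLUMNS``; negative-control rows carry
    no family label.  The truth record echoes the config and stores every
    realised effect, keyed for downstream parameter-recovery tests.  Output is
    a pure function of the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nf, nreps = config.n_families, config.n_replicates
    npq = config.plants_per_quadrant

    # family base deviates, shared across replicates and treatment arms
    rho = config.genetic_correlation
    u_shoot = rng.standard_normal(nf)
    u_other = rng.standard_normal(nf)
    u_root = rho * u_shoot + math.sqrt(max(0.0, 1.0 - rho * rho)) * u_other
    base = {"shoot_dm": u_shoot, "root_dm": u_root}

    truth: dict = {
        "config": _config_dict(config),
        "family_effects": {},
        "replicate_effects": {},
        "interaction_effects": {},
        "row_effects": {},
        "column_effects": {},
    }

    frames = []
    for treatment in sorted(config.treatment_means):
        design = make_design(nf, nreps, config.containers_per_replicate, rng)
        values = {}
        truth["family_effects"][treatment] = {}
        truth["replicate_effects"][treatment] = {}
        truth["interaction_effects"][treatment] = {}
        truth["row_effects"][treatment] = {}
        truth["column_effects"][treatment] = {}
        for trait in sorted(config.treatment_means[treatment]):
            vs = config.components[treatment][trait]
            mean = config.treatment_means[treatment][trait]
            fam_dev = math.sqrt(vs.family) * base[trait]
            rep_eff = _draw_group_effects(rng, design["replicate"], vs.replicate)
            inter = {
                (f, r): e
                for (f, r), e in zip(
                    [(f, r) for f in range(1, nf + 1) for r in range(1, nreps + 1)],
                    rng.standard_normal(nf * nreps)
                    * math.sqrt(vs.family_by_replicate),
                )
            }
            row_eff = _draw_group_effects(
                rng, zip(design["replicate"], design["row"]), vs.row
            )
            col_eff = _draw_group_effects(
                rng, zip(design["replicate"], design["column"]), vs.column
            )
            plot_err = rng.standard_normal(len(design)) * math.sqrt(vs.residual)

            plot_value = (
                mean
                + fam_dev[design["family"].to_numpy() - 1]
                + design["replicate"].map(rep_eff).to_numpy()
                + np.array(
                    [inter[(f, r)] for f, r in zip(design["family"], design["replicate"])]
                )
                + np.array(
                    [row_eff[(r, k)] for r, k in zip(design["replicate"], design["row"])]
                )
                + np.array(
                    [
                        col_eff[(r, c)]
                        for r, c in zip(design["replicate"], design["column"])
                    ]
                )
                + plot_err
            )
            plant_value = np.repeat(plot_value, npq)
            if vs.plant > 0:
                plant_value = plant_value + rng.standard_normal(
                    len(plant_value)
                ) * math.sqrt(vs.plant)
            values[trait] = plant_value

            truth["family_effects"][treatment][trait] = {
                str(f + 1): float(fam_dev[f]) for f in range(nf)
            }
            truth["replicate_effects"][treatment][trait] = {
                str(k): float(v) for k, v in rep_eff.items()
            }
            truth["interaction_effects"][treatment][trait] = {
                f"{f}:{r}": float(v) for (f, r), v in inter.items()
            }
            truth["row_effects"][treatment][trait] = {
                f"{r}:{k}": float(v) for (r, k), v in row_eff.items()
            }
            truth["column_effects"][treatment][trait] = {
                f"{r}:{c}": float(v) for (r, c), v in col_eff.items()
            }

        arm = design.loc[design.index.repeat(npq)].reset_index(drop=True)
        arm["treatment"] = treatment
        for trait in MEASURED_TRAITS:
            arm[f"{trait}_mg"] = values.get(trait, np.nan)
        frames.append(arm)

    neg = config.negative_control
    if neg is not None and neg.n_containers > 0:
        crow, ccol = _container_grid(neg.n_containers)
        rows = []
        for rep in range(1, nreps + 1):
            for c in range(neg.n_containers):
                for q in range(4):
                    rows.append(
                        (
                            rep,
                            c + 1,
                            q + 1,
                            int(2 * crow[c] + q // 2 + 1),
                            int(2 * ccol[c] + q % 2 + 1),
                        )
                    )
        neg_design = pd.DataFrame(
            rows, columns=["replicate", "container", "quadrant", "row", "column"]
        )
        arm = neg_design.loc[neg_design.index.repeat(npq)].reset_index(drop=True)
        arm["family"] = pd.NA
        arm["treatment"] = NEG
        for trait in MEASURED_TRAITS:
            mean = neg.bulk_mean.get(trait, np.nan)
            sd = neg.bulk_sd.get(trait, 0.0)
            arm[f"{trait}_mg"] = mean + rng.standard_normal(len(arm)) * sd
        frames.append(arm)

    plants = pd.concat(frames, ignore_index=True)
    plants["family"] = plants["family"].astype("Int64")
    plants = plants[list(PLANT_COLUMNS)]

    n_before = len(plants)
    if config.missing_rate > 0:
        keep = rng.random(n_before) >= config.missing_rate
        plants = plants[keep].reset_index(drop=True)
    truth["n_records_emitted"] = int(len(plants))
    truth["n_records_designed"] = int(n_before)
    return plants, truth


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=str))


def write_plant_csv(plants: pd.DataFrame, path) -> None:
    plants.to_csv(path, index=False, float_format="%.10g")


def read_plant_csv(path) -> pd.DataFrame:
    plants = pd.read_csv(path, dtype={"treatment": str})
    plants["family"] = plants["family"].astype("Int64")
    return plants


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
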