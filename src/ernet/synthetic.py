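"""Synthetic data generators for the pipeline's two input classes.

Two generators cover everything downstream stages consume:

* :func:`generate_expression_matrix` emulates a log2(norm_count+1) tumor
  expression matrix of the kind the bioinformatics stage analyzes (default
  dimensions 17,489 genes × 1,019 samples): a continuous marker gene (e.g.
  ESR1), programs of up-/down-regulated genes planted conditional on the
  marker's median split, a null background, and a block of genes below the
  abundance filter.  A sidecar table records the planted truth per gene.

* :func:`generate_timecourses` manufactures replicated, noisy time-course
  protein measurements (relative densitometry) from a known model
  parameterization — the estimation stage's target — and stores the
  generating parameters as hidden truth for recovery studies.

Both are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ernet.network import NetworkModel, Scenario, equilibrate, simulate

__all__ = [
    "ExprSimConfig",
    "NoiseModel",
    "ExperimentDesign",
    "TimeCourseDataset",
    "generate_expression_matrix",
    "generate_timecourses",
    "LOW_EXPRESSION_THRESHOLD",
]

#: Abundance filter the low-expression block is planted below (log2 units).
LOW_EXPRESSION_THRESHOLD = 2.0


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprSimConfig:
    """Configuration of the planted-truth expression matrix.

    Defaults mirror the tumor cohort the pipeline emulates: 17,489 genes x
    1,019 samples on the log2(norm_count+1) scale, a two-group contrast of
    effect 2 log2 units (fold change 4 between group means, comfortably past
    the FC>2 calling threshold), per-gene Gaussian noise of 0.5 log2 units,
    and ~15% of genes below the abundance filter.
    """

    n_genes: int = 17489
    n_samples: int = 1019
    marker_gene: str = "ESR1"
    n_up_planted: int = 50
    n_down_planted: int = 50
    effect_log2fc: float = 2.0
    baseline_mean: float = 8.0
    noise_sd: float = 0.5
    low_expr_fraction: float = 0.15
    seed: int = 0
    inject_marker_ties: bool = False

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 1:
            raise ValueError("n_genes must be positive and n_samples > 1")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0 (0 yields noise-free planted means)")
        if not 0 <= self.low_expr_fraction < 1:
            raise ValueError("low_expr_fraction must be in [0, 1)")
        n_low = int(round(self.low_expr_fraction * self.n_genes))
        n_planted = self.n_up_planted + self.n_down_planted
        if n_planted >= self.n_genes:
            raise ValueError("planted gene counts exceed gene count")
        if 1 + n_planted + n_low > self.n_genes:
            raise ValueError("planted + low-expressed genes leave no null background")


def generate_expression_matrix(config: ExprSimConfig):
    """Generate a matrix with planted differential structure.

    Returns ``(matrix, truth)``: a genes × samples DataFrame (log2 scale,
    values clipped at 0) and a per-gene truth table with columns ``label``
    (``marker``/``up``/``down``/``null``/``low_expressed``) and
    ``true_log2fc`` (high-group mean minus low-group mean).

    Planted effects are symmetric mean shifts of ±effect/2 conditional on the
    marker being above/below its median, so a planted up gene's group-mean
    difference is exactly ``effect_log2fc`` in the noise-free limit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_low = int(round(config.low_expr_fraction * config.n_genes))
    n_up, n_down = config.n_up_planted, config.n_down_planted
    n_null = config.n_genes - 1 - n_up - n_down - n_low

    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]

    # Marker: continuous, hence tie-free; jitter enforces strict distinctness.
    marker = config.baseline_mean + rng.normal(0.0, 1.0, config.n_samples)
    while len(np.unique(marker)) < config.n_samples:  # pragma: no cover
        marker += rng.uniform(-1e-9, 1e-9, config.n_samples)
    if config.inject_marker_ties:
        marker[: config.n_samples // 2] = np.median(marker)
    high_mask = marker > np.median(marker)

    def planted_block(n, sign):
        base = config.baseline_mean + rng.normal(0.0, 1.0, n)
        shift = sign * config.effect_log2fc / 2.0
        means = base[:, None] + np.where(high_mask, shift, -shift)[None, :]
        return means + rng.normal(0.0, config.noise_sd, (n, config.n_samples))

    up = planted_block(n_up, +1)
    down = planted_block(n_down, -1)
    null_base = config.baseline_mean + rng.normal(0.0, 1.0, n_null)
    null = null_base[:, None] + rng.normal(0.0, config.noise_sd, (n_null, config.n_samples))
    low_base = rng.uniform(0.0, 1.5, n_low)
    low = low_base[:, None] + rng.normal(0.0, config.noise_sd, (n_low, config.n_samples))

    values = np.vstack([marker[None, :], up, down, null, low])
    values = np.clip(values, 0.0, None)

    labels = np.array(
        ["marker"] + ["up"] * n_up + ["down"] * n_down + ["null"] * n_null
        + ["low_expressed"] * n_low
    )
    effects = np.concatenate([
        [np.nan], np.full(n_up, config.effect_log2fc),
        np.full(n_down, -config.effect_log2fc), np.zeros(n_null), np.zeros(n_low),
    ])
    gene_ids = np.array(
        [config.marker_gene] + [f"G{i:05d}" for i in range(config.n_genes - 1)]
    )

    order = rng.permutation(config.n_genes)
    matrix = pd.DataFrame(values[order], index=gene_ids[order], columns=sample_ids)
    matrix.index.name = "gene"
    truth = pd.DataFrame(
        {"label": labels[order], "true_log2fc": effects[order]}, index=gene_ids[order]
    )
    truth.index.name = "gene"
    return matrix, truth


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise for densitometry-style readouts.

    ``lognormal_multiplicative`` (default) has unit mean and coefficient of
    variation ``scale`` — appropriate for strictly positive ratio-scale data;
    ``gaussian_additive`` adds N(0, scale).  ``scale = 0`` yields exact
    trajectories.
    """

    kind: str = "lognormal_multiplicative"
    scale: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("lognormal_multiplicative", "gaussian_additive"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, float)
        if self.scale == 0:
            return values.copy()
        if self.kind == "lognormal_multiplicative":
            sigma = np.sqrt(np.log1p(self.scale**2))
            factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=values.shape)
            return values * factors
        return values + rng.normal(0.0, self.scale, size=values.shape)


@dataclass(frozen=True)
class ExperimentDesign:
    """Which species are observed, when, how often, and under which scenarios."""

    observed_species: tuple
    sample_times: tuple
    n_replicates: int = 3
    scenarios: tuple = ()

    def validate(self, model: NetworkModel) -> None:
        missing = [s for s in self.observed_species if s not in model.species_names]
        if missing:
            raise ValueError(f"observed species not in model: {missing}")
        times = np.asarray(self.sample_times, float)
        if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing and nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.scenarios:
            raise ValueError("at least one scenario required")


@dataclass
class TimeCourseDataset:
    """Tidy replicated measurements plus the (hidden) generating truth."""

    data: pd.DataFrame  # columns: scenario, species, time_h, replicate, value
    design: ExperimentDesign
    noise: NoiseModel
    generating_params: dict = field(repr=False, default_factory=dict)

    def scenario_map(self) -> dict:
        return {sc.label: sc for sc in self.design.scenarios}

    def to_config_json(self) -> str:
        return json.dumps(
            {
                "design": {
                    "observed_species": list(self.design.observed_species),
                    "sample_times": list(self.design.sample_times),
                    "n_replicates": self.design.n_replicates,
                    "scenarios": [asdict(sc) for sc in self.design.scenarios],
                },
                "noise": asdict(self.noise),
            },
            indent=2,
        )


def generate_timecourses(model: NetworkModel, params: Mapping[str, float],
                         design: ExperimentDesign, noise: NoiseModel,
                         rtol: float = 1e-8, atol: float = 1e-10,
                         burn_in: float | None = None,
                         polish: bool = False) -> TimeCourseDataset:
    """Simulate the design's scenarios and corrupt sampled values per the noise model.

    Every scenario starts from the shared pre-equilibrated All-Low baseline.
    The burn-in is used as-is (no Newton polish): the estimation stage relies
    on this trajectory pipeline being smooth in the parameters, and the fit's
    residual engine reproduces it exactly.  The generating parameters are
    stored on the returned dataset for parameter-recovery studies.
    """
    design.validate(model)
    rng = np.random.default_rng(noise.seed)
    t_end = float(max(design.sample_times))
    kw = {} if burn_in is None else {"t_burn": burn_in}
    x0 = equilibrate(model, params, rtol=rtol, atol=atol, polish=polish, **kw)
    records = []
    for sc in design.scenarios:
        traj = simulate(model, sc, params, t_end=max(t_end, 1e-6), x0=x0,
                        rtol=rtol, atol=atol)
        for sp in design.observed_species:
            clean = np.interp(design.sample_times, traj.times, traj.series(sp))
            noisy = noise.apply(
                np.tile(clean, (design.n_replicates, 1)), rng)
            for rep in range(design.n_replicates):
                for t, v in zip(design.sample_times, noisy[rep]):
                    records.append((sc.label, sp, float(t), rep + 1, float(v)))
    data = pd.DataFrame(records, columns=["scenario", "species", "time_h", "replicate", "value"])
    return TimeCourseDataset(data=data, design=design, noise=noise,
                             generating_params=dict(params))
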