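"""Synthetic radiomic-style feature-table generator.

Produces class-balanced cohorts with planted informative features
(standardized mean differences), correlated feature blocks, replicate
measurements with controllable ICC, optional log-normal skew, and a
covariate-shifted second cohort — the statistical structure every pipeline
stage assumes, with no external data required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import FeatureTable, ReplicatePair, write_feature_table

__all__ = ["SyntheticConfig", "generate_cohort", "generate_shifted_cohort", "write_cohort"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_sizes`` are per-informative-feature Cohen's d values (class-1
    mean minus class-0 mean in within-class-sd units).  ``block_structure``
    lists ``(block_size, rho)`` pairs realized as equicorrelated blocks among
    the *non-informative* features; informative features are independent so
    planted effects stay attributable.  The two delineations are modeled
    symmetrically: primary and replicate are each the latent feature value
    plus independent N(0, replicate_noise_sd^2) measurement noise, giving
    ICC = 1 / (1 + sd^2) for unit-latent-variance features.  ``shift`` is
    ``(scale, offset, extra_noise_sd)`` applied by
    :func:`generate_shifted_cohort`.
    """

    n_samples: int = 200
    n_features: int = 422
    n_informative: int = 5
    effect_sizes: tuple[float, ...] | None = None
    block_structure: tuple[tuple[int, float], ...] | None = None
    block_effects: tuple[float, ...] | None = None
    replicate_noise_sd: float = 0.1
    shift: tuple[float, float, float] = (1.2, 0.5, 0.3)
    lognormal_features: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples per class must be >= 2")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.effect_sizes is None:
            self.effect_sizes = tuple(
                np.linspace(2.0, 1.0, self.n_informative)
            ) if self.n_informative else ()
        if len(self.effect_sizes) != self.n_informative:
            raise ValueError("one effect size per informative feature required")
        if self.block_structure is None:
            # package convention: up to 10 blocks of 10 at rho = 0.6, capped at
            # half of the non-informative features
            budget = (self.n_features - self.n_informative) // 2
            n_blocks = min(10, budget // 10)
            self.block_structure = ((10, 0.6),) * n_blocks
        used = self.n_informative + sum(b for b, _ in self.block_structure)
        if used > self.n_features:
            raise ValueError("informative + block features exceed n_features")
        for _, rho in self.block_structure:
            if not (0 <= rho < 1):
                raise ValueError("block correlation must be in [0, 1)")
        if self.block_effects is not None and len(self.block_effects) != len(self.block_structure):
            raise ValueError("one block effect per block required")
        if self.replicate_noise_sd < 0 or self.shift[2] < 0:
            raise ValueError("noise sds must be >= 0")
        if self.lognormal_features > self.n_features - self.n_informative:
            raise ValueError("too many log-normal features requested")

    @property
    def informative_ids(self) -> list[str]:
        return [f"synthetic|informative|f{j:04d}" for j in range(self.n_informative)]

    def feature_ids(self) -> list[str]:
        ids = list(self.informative_ids)
        j = self.n_informative
        for b, (size, _) in enumerate(self.block_structure):
            ids += [f"synthetic|block{b:02d}|f{j + i:04d}" for i in range(size)]
            j += size
        ids += [f"synthetic|noise|f{i:04d}" for i in range(j, self.n_features)]
        return ids


def _draw_values(cfg: SyntheticConfig, rng: np.random.Generator, n_per_class: int):
    """Latent per-class MVN draw; returns (values, labels) in sample order."""
    n = 2 * n_per_class
    d = cfg.n_features
    labels = np.repeat([0, 1], n_per_class)
    x = rng.standard_normal((n, d))
    # equicorrelated blocks via shared factor: sqrt(rho)*g + sqrt(1-rho)*e;
    # an optional per-block effect shifts every member feature, planting
    # redundant weak signal across the whole correlated block
    j = cfg.n_informative
    for b, (size, rho) in enumerate(cfg.block_structure):
        g = rng.standard_normal(n)[:, None]
        x[:, j : j + size] = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * x[:, j : j + size]
        if cfg.block_effects is not None and cfg.block_effects[b] != 0.0:
            x[:, j : j + size] += cfg.block_effects[b] * labels[:, None]
        j += size
    # planted standardized mean differences on the informative block
    for k, delta in enumerate(cfg.effect_sizes):
        x[:, k] += delta * labels
    # log-normal skew on the last `lognormal_features` columns
    if cfg.lognormal_features:
        cols = slice(d - cfg.lognormal_features, d)
        x[:, cols] = np.exp(x[:, cols])
    return x, labels


def generate_cohort(
    config: SyntheticConfig, cohort_tag: str = "train"
) -> tuple[ReplicatePair, np.ndarray]:
    """Generate a class-balanced cohort with a replicate measurement.

    Returns a :class:`ReplicatePair` (both tables carry the labels) and the
    label vector.  All randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    x, labels = _draw_values(config, rng, config.n_samples)
    noise_a = rng.standard_normal(x.shape) * config.replicate_noise_sd
    noise_b = rng.standard_normal(x.shape) * config.replicate_noise_sd
    ids = [f"S{i:04d}" for i in range(x.shape[0])]
    feats = config.feature_ids()
    primary = FeatureTable(ids, feats, x + noise_a, labels, cohort_tag)
    replicate = FeatureTable(ids, feats, x + noise_b, labels, cohort_tag + "-replicate")
    return ReplicatePair(primary, replicate), labels


def generate_shifted_cohort(
    config: SyntheticConfig, base_seed: int = 1, cohort_tag: str = "test"
) -> FeatureTable:
    """Generate a second cohort with the same class effects under a covariate
    shift ``x -> scale * x + offset + N(0, extra_sd^2)``."""
    scale, offset, extra_sd = config.shift
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, base_seed]))
    x, labels = _draw_values(config, rng, config.n_samples)
    x = scale * x + offset + rng.standard_normal(x.shape) * extra_sd
    ids = [f"T{i:04d}" for i in range(x.shape[0])]
    return FeatureTable(ids, config.feature_ids(), x, labels, cohort_tag)


def write_cohort(config: SyntheticConfig, out_dir: str | Path) -> dict[str, str]:
    """Write primary/replicate/shifted-test CSVs plus a truth JSON; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair, _ = generate_cohort(config)
    test = generate_shifted_cohort(config)
    paths = {
        "primary": str(out / "primary.csv"),
        "replicate": str(out / "replicate.csv"),
        "test": str(out / "test.csv"),
        "truth": str(out / "truth.json"),
    }
    write_feature_table(pair.primary, paths["primary"])
    write_feature_table(pair.replicate, paths["replicate"])
    write_feature_table(test, paths["test"])
    truth = {
        "seed": config.seed,
        "informative_features": config.informative_ids,
        "effect_sizes": list(config.effect_sizes),
        "replicate_noise_sd": config.replicate_noise_sd,
        "shift": list(config.shift),
    }
    Path(paths["truth"]).write_text(json.dumps(truth, indent=1))
    return paths
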