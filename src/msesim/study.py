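"""Study configuration, seeding, and end-to-end execution.

A study is a grid over data-generating patterns, population sizes, and
expected encounter probabilities; each cell is simulated ``replicates``
times at 5 lists, truncated to cumulative sets of 2..5 lists, and fed to
the enabled estimators.  Every sample's seed is derived deterministically
from the master seed and the cell coordinates, so any cell can be
re-run in isolation and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

import msesim
from msesim.blcm import PRESETS, BlcmConfig, run_blcm
from msesim.bma import bma_posterior, enumerate_decomposable
from msesim.evaluation import EstimateResult, aggregate_tables, match_table, results_to_frame
from msesim.loglinear import aic_estimate
from msesim.synthetic import (
    PATTERNS,
    GeneratorSpec,
    collapse_frequencies,
    sample_seed,
    shapes_from_mean_cv,
    simulate_sample,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "validate_config", "run_study", "design_cardinality", "estimate_sample"]

@dataclass
class StudyConfig:
    replicates: int = 400
    patterns: list = field(default_factory=lambda: list(PATTERNS))
    N_values: list = field(default_factory=lambda: [1_000, 10_000, 20_000])
    mean_p_values: list = field(default_factory=lambda: [0.025, 0.050, 0.100, 0.150, 0.200])
    cv: float = 0.85
    behavior_multiplier: float = 0.5
    K_range: list = field(default_factory=lambda: [2, 3, 4, 5])
    methods: list = field(default_factory=lambda: ["LLM-AIC", "LLM-BMA", "BLCM"])
    llm_correction: str = "Poisson2"
    llm_ci: bool = True
    bma_prior: str = "reciprocal"
    bma_n0_factor: float = 10.0  # prior cap on the unobserved count: 10 N
    blcm: dict = field(default_factory=dict)  # overrides of BlcmConfig fields
    master_seed: int = 1
    output_dir: str = "study_output"

    @classmethod
    def preset(cls, name: str, **overrides) -> "StudyConfig":
        """``paper_full`` (400 reps, full MCMC; not desk-scale) or ``desk``
        (50 reps, reduced MCMC)."""
        if name == "paper_full":
            cfg = cls(replicates=400, blcm=dict(PRESETS["paper_full"]))
        elif name == "desk":
            cfg = cls(replicates=50, blcm=dict(PRESETS["desk"]))
        else:
            raise ValueError(f"unknown preset {name!r}")
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        preset = data.pop("preset", None)
        return cls.preset(preset, **data) if preset else cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def design_cardinality(config: StudyConfig) -> int:
    """Number of simulated samples in the design."""
    return (
        config.replicates
        * len(config.patterns)
        * len(config.N_values)
        * len(config.mean_p_values)
    )


def validate_config(config: StudyConfig) -> list[str]:
    """All feasibility constraints; returns human-readable errors (empty = ok)."""
    errors = []
    if config.replicates < 1:
        errors.append("replicates must be >= 1")
    for pat in config.patterns:
        if pat not in PATTERNS:
            errors.append(f"unknown pattern {pat!r}")
    for m in config.mean_p_values:
        try:
            shapes_from_mean_cv(m, config.cv)
        except ValueError as e:
            errors.append(f"mean_p={m}, cv={config.cv}: {e}")
    for N in config.N_values:
        if N < 1:
            errors.append(f"invalid population size {N}")
    for K in config.K_range:
        if not 2 <= K <= 5:
            errors.append(f"K_use={K} outside the supported 2-5 range")
    if "LLM-BMA" in config.methods and config.K_range and max(config.K_range) < 3:
        errors.append("LLM-BMA requires at least 3 lists; extend K_range or drop the method")
    for m in config.methods:
        if m not in ("LLM-AIC", "LLM-BMA", "BLCM"):
            errors.append(f"unknown method {m!r}")
    try:
        BlcmConfig(**config.blcm)
    except (TypeError, ValueError) as e:
        errors.append(f"blcm settings: {e}")
    return errors


def estimate_sample(
    matrix,
    K_use: int,
    config: StudyConfig,
    replicate: int,
) -> list[EstimateResult]:
    """Run every enabled estimator on one sample truncated to K_use lists."""
    spec = matrix.spec
    meta = dict(
        replicate=replicate, pattern=spec.pattern, mean_p=spec.mean_p, N=spec.N, K_use=K_use
    )
    out: list[EstimateResult] = []
    table = collapse_frequencies(matrix, K_use)

    if "LLM-AIC" in config.methods:
        try:
            fit = aic_estimate(table, ci=config.llm_ci, estimate_correction=config.llm_correction)
            lo, hi = fit.ci if fit.ci else (np.nan, np.nan)
            out.append(
                EstimateResult(
                    method="LLM-AIC", N_hat=float(fit.N_hat), ci_low=lo, ci_high=hi,
                    selected_model=fit.spec.label, **meta,
                )
            )
        except RuntimeError:
            out.append(EstimateResult(method="LLM-AIC", N_hat=np.nan, failed=True, **meta))

    if "LLM-BMA" in config.methods and K_use >= 3:
        try:
            grid = bma_posterior(
                table,
                n0_max=int(config.bma_n0_factor * spec.N),
                prior=config.bma_prior,
                models=_model_cache(K_use),
            )
            lo, hi = grid.interval(0.95)
            out.append(
                EstimateResult(
                    method="LLM-BMA", N_hat=float(grid.median_N), ci_low=float(lo),
                    ci_high=float(hi), **meta,
                )
            )
        except RuntimeError:
            out.append(EstimateResult(method="LLM-BMA", N_hat=np.nan, failed=True, **meta))

    if "BLCM" in config.methods:
        blcm_cfg = BlcmConfig(
            **{**config.blcm, "seed": sample_seed(config.master_seed + 7, replicate, spec.pattern, spec.mean_p, spec.N)}
        )
        res = run_blcm(matrix, blcm_cfg, K_use=K_use)
        lo, hi = res.interval(0.95)
        out.append(
            EstimateResult(
                method="BLCM", N_hat=res.median_N, ci_low=lo, ci_high=hi, **meta,
            )
        )
    return out


_MODEL_CACHE: dict[int, list] = {}


def _model_cache(K: int) -> list:
    if K not in _MODEL_CACHE:
        _MODEL_CACHE[K] = enumerate_decomposable(K)
    return _MODEL_CACHE[K]


def _iter_cells(config: StudyConfig) -> Iterator[tuple]:
    for pattern in config.patterns:
        for N in config.N_values:
            for mean_p in config.mean_p_values:
                for replicate in range(config.replicates):
                    yield pattern, N, mean_p, replicate


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Simulate, estimate, and evaluate the full configured design.

    Writes per-estimate rows (``estimates.csv``), pooled performance
    tables (``performance.csv``), AIC model-matching tables
    (``matching.csv``), and a manifest with the config and its hash to
    ``config.output_dir``; returns the estimates as a DataFrame.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid study configuration:\n" + "\n".join(errors))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    results: list[EstimateResult] = []
    failures = 0
    for pattern, N, mean_p, replicate in _iter_cells(config):
        seed = sample_seed(config.master_seed, replicate, pattern, mean_p, N)
        spec = GeneratorSpec(
            pattern=pattern, N=N, mean_p=mean_p, cv=config.cv,
            behavior_multiplier=config.behavior_multiplier, seed=seed,
        )
        matrix = simulate_sample(spec)
        for K_use in config.K_range:
            try:
                results.extend(estimate_sample(matrix, K_use, config, replicate))
            except Exception:  # estimator crash: recorded, not fatal
                failures += 1
                logger.exception(
                    "estimation failed: pattern=%s N=%s mean_p=%s rep=%s K=%s",
                    pattern, N, mean_p, replicate, K_use,
                )
    df = results_to_frame(results)
    df.to_csv(outdir / "estimates.csv", index=False)

    _, table = aggregate_tables(df)
    table.to_csv(outdir / "performance.csv", index=False)

    llm = df[(df["method"] == "LLM-AIC") & ~df["failed"]]
    llm = llm[llm["pattern"].isin(["Mb", "Mbh", "Mh", "Mth", "Mt"])]
    if not llm.empty:
        _, cross = match_table(list(zip(llm["pattern"], llm["selected_model"])))
        cross.to_csv(outdir / "matching.csv")

    manifest = {
        "version": msesim.__version__,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_samples": design_cardinality(config),
        "n_estimates": len(df),
        "estimator_failures": failures,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("study complete: %d estimates, %d failures", len(df), failures)
    return df
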