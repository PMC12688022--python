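"""File formats, run configuration and provenance for the pipeline.

Artifacts are plain text: assessment records, evidence tables and
prediction reports as CSV; selection reports, fit metadata and
provenance sidecars as JSON; run configuration as YAML.  Every numeric
artifact carries (or sits next to) a provenance record — configuration
hash, seeds, package version — sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, TrajectoryDataset
from .collapsed import CollapsedPosterior
from .designr import DEFAULT_CODING, SubscaleCoding
from .inference import McmcConfig, PosteriorSamples
from .model import ModelSpec, PriorConfig
from .nuts import ChainStats
from .records import exclude_single_assessment, validate_records

__all__ = ["RunConfig", "read_assessments", "write_assessments",
           "save_fit", "load_fit", "provenance_record"]


def _package_version() -> str:
    try:
        return version("pitrend")
    except PackageNotFoundError:
        return "unknown"


def provenance_record(payload: dict, seed: int | None = None) -> dict:
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return {
        "config": payload,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "package_version": _package_version(),
    }


@dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration (YAML-backed)."""

    records_path: str | None = None
    output_dir: str = "pitrend_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    spec: ModelSpec = field(default_factory=ModelSpec.base)
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    selection_threshold: float = 0.95
    selection_folds: int = 5
    selection_fraction: float = 0.8
    evidence_repetitions: int = 5
    prediction_level: float = 0.90
    prediction_mode: str = "population"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prediction_level < 1:
            raise ValueError("prediction_level must lie in (0, 1)")
        if not 0 < self.selection_fraction < 1:
            raise ValueError("selection_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("records_path", "output_dir", "selection_threshold",
                    "selection_folds", "selection_fraction",
                    "evidence_repetitions", "prediction_level",
                    "prediction_mode", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**raw["cohort"])
        if "spec" in raw:
            kwargs["spec"] = ModelSpec(
                predictors=tuple(raw["spec"].get("predictors", ())),
                include_quadratic_duration=raw["spec"].get(
                    "include_quadratic_duration", False))
        if "priors" in raw:
            kwargs["priors"] = PriorConfig(**raw["priors"])
        if "mcmc" in raw:
            mc = dict(raw["mcmc"])
            profile = mc.pop("profile", None)
            if profile == "published":
                base = McmcConfig.published_profile()
            elif profile == "smoke":
                base = McmcConfig.smoke_profile()
            else:
                base = McmcConfig()
            kwargs["mcmc"] = McmcConfig(**{
                "n_chains": base.n_chains, "n_warmup": base.n_warmup,
                "n_draws": base.n_draws, "seed": base.seed,
                "target_accept": base.target_accept,
                "max_tree_depth": base.max_tree_depth, **mc})
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "records_path": self.records_path,
            "output_dir": self.output_dir,
            "spec": {"predictors": list(self.spec.predictors),
                     "include_quadratic_duration":
                         self.spec.include_quadratic_duration},
            "mcmc": {"n_chains": self.mcmc.n_chains,
                     "n_warmup": self.mcmc.n_warmup,
                     "n_draws": self.mcmc.n_draws, "seed": self.mcmc.seed},
            "selection": {"threshold": self.selection_threshold,
                          "folds": self.selection_folds,
                          "fraction": self.selection_fraction},
            "prediction": {"level": self.prediction_level,
                           "mode": self.prediction_mode},
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# assessment records

def read_assessments(path: str | Path,
                     coding: SubscaleCoding = DEFAULT_CODING
                     ) -> TrajectoryDataset:
    """Read, validate and filter an assessment-record CSV.

    Subscale values are checked against the permissible sets, day indices
    must increase within each PI, and PIs with a single assessment are
    excluded (no change is observable for them).  Derived fields (totals,
    changes, durations, dummies) are always computed, never read.
    """
    path = Path(path)
    df = pd.read_csv(path)
    validate_records(df, coding)
    df, _excluded = exclude_single_assessment(df)
    sidecar = path.with_suffix(".provenance.json")
    provenance = (json.loads(sidecar.read_text()) if sidecar.exists()
                  else {"source": str(path)})
    return TrajectoryDataset(records=df, provenance=provenance)


def write_assessments(dataset: TrajectoryDataset, path: str | Path) -> Path:
    """Write records CSV plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.records.to_csv(path, index=False)
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(dataset.provenance, indent=2, default=str))
    return path


# ---------------------------------------------------------------------------
# fit persistence

def save_fit(samples: PosteriorSamples, outdir: str | Path) -> Path:
    """Persist a fit as unconstrained-draw CSV + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    C, D, K = samples.theta.shape
    flat = samples.theta.reshape(C * D, K)
    frame = pd.DataFrame(flat, columns=[f"theta_{k}" for k in range(K)])
    frame.insert(0, "chain", np.repeat(np.arange(C), D))
    frame.insert(1, "draw", np.tile(np.arange(D), C))
    frame.to_csv(outdir / "fit_theta.csv", index=False)
    meta = {
        "provenance": samples.provenance,
        "pi_ids": list(samples.pi_ids),
        "diagnostics": {
            "divergences": samples.divergences,
            "max_rhat": samples.max_rhat(include_effects=False)
            if samples.n_chains >= 2 else None,
        },
        "shape": [C, D, K],
    }
    (outdir / "fit.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_fit(outdir: str | Path, dataset: TrajectoryDataset,
             priors: PriorConfig | None = None) -> PosteriorSamples:
    """Rebuild a :class:`PosteriorSamples` from a saved fit and the
    training records it was computed from."""
    outdir = Path(outdir)
    fit_json = outdir / "fit.json"
    if not fit_json.exists():
        raise FileNotFoundError(
            f"no fit artifact under {outdir}; run the fit command first")
    meta = json.loads(fit_json.read_text())
    spec_info = meta["provenance"]["spec"]
    spec = ModelSpec(predictors=tuple(spec_info["predictors"]),
                     include_quadratic_duration=spec_info[
                         "include_quadratic_duration"])
    mcmc_info = meta["provenance"]["mcmc"]
    post = CollapsedPosterior(dataset.observations(), spec,
                              priors or PriorConfig())
    frame = pd.read_csv(outdir / "fit_theta.csv")
    C, D, K = meta["shape"]
    theta = frame[[f"theta_{k}" for k in range(K)]].to_numpy().reshape(C, D, K)
    p = spec.dim
    mu = theta[..., :p]
    zeta = np.exp(theta[..., p:2 * p])
    sigma = np.exp(theta[..., -1])
    omega = np.empty((C, D, p, p))
    for c in range(C):
        for d in range(D):
            omega[c, d] = post.corr.forward(theta[c, d, 2 * p:-1])[0]
    eff_seed = np.random.SeedSequence(mcmc_info["seed"]).spawn(
        mcmc_info["n_chains"] + 1)[-1]
    beta = post.sample_effects_batch(
        mu.reshape(-1, p), zeta.reshape(-1, p), omega.reshape(-1, p, p),
        sigma.reshape(-1), np.random.default_rng(eff_seed)
    ).reshape(C, D, len(post.data.pi_ids), p)
    return PosteriorSamples(
        spec=spec, pi_ids=post.data.pi_ids, mu=mu, zeta=zeta, sigma=sigma,
        omega_chol=omega, beta=beta, theta=theta,
        chain_stats=[ChainStats() for _ in range(C)], target=post,
        provenance=meta["provenance"])
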