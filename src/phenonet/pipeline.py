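"""End-to-end orchestration: aggregate, fit, measure, assess.

``run_pipeline`` reproduces the full workflow for every aggregation
window of a dataset: build the binary network, fit the requested link
models, measure nestedness of model realizations against the empirical
network and a shared ER baseline, score link-prediction accuracy, and
run the nested-backbone test for the copresence-based models.  All
randomness flows from the single configured seed; two runs with the same
configuration produce byte-identical JSON bundles.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assessment import backbone_ratios, ensemble_assess
from .exceptions import ConfigurationError, ModelInfeasibleError
from .link_models import (
    LinkProbabilityMatrix,
    degree_distribution_probabilities,
    er_probabilities,
    phenology_probabilities,
    presence_probabilities,
    sample_realizations,
)
from .nestedness import (
    delta_rho_tilde,
    er_baseline_rho,
    normalize_rho,
    rho_normalized,
    spectral_radius_raw,
)
from .synthetic import PhenologySpec, generate_dataset
from .temporal_data import (
    BipartiteNetwork,
    TemporalDataset,
    aggregate_blocks,
    build_network,
    copresence_matrix,
    copresence_summary,
    presence_average_matrix,
    read_daily_events,
)

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_MODELS = ("ER", "DD", "phenology", "presence")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``synthetic`` must be given.  The
    ensemble defaults are 1,000 model realizations and 10,000 ER baseline
    graphs.  ``window`` follows :func:`phenonet.temporal_data.aggregate_blocks`.
    """

    input_path: str | None = None
    synthetic: PhenologySpec | None = None
    window: int | str | list = "full"
    models: tuple[str, ...] = DEFAULT_MODELS
    n_realizations: int = 1_000
    n_er_graphs: int = 10_000
    backbone: bool = True
    backbone_er_graphs: int = 1_000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of input_path / synthetic must be set"
            )
        unknown = set(self.models) - set(DEFAULT_MODELS)
        if unknown:
            raise ConfigurationError(f"unknown models: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "window": self.window
            if not isinstance(self.window, list)
            else [[str(a), str(b)] for a, b in self.window],
            "models": list(self.models),
            "n_realizations": self.n_realizations,
            "n_er_graphs": self.n_er_graphs,
            "backbone": self.backbone,
            "backbone_er_graphs": self.backbone_er_graphs,
            "seed": self.seed,
        }


def _model_probabilities(
    name: str, network: BipartiteNetwork, block: TemporalDataset
) -> LinkProbabilityMatrix:
    if name == "ER":
        return er_probabilities(network)
    if name == "DD":
        return degree_distribution_probabilities(network)
    if name == "phenology":
        return phenology_probabilities(copresence_matrix(block, network), network)
    if name == "presence":
        return presence_probabilities(
            presence_average_matrix(block, network), network
        )
    raise ConfigurationError(f"unknown model {name!r}")


def _realization_rhos(reals: np.ndarray) -> np.ndarray:
    """Normalized spectral radius of each realization (own frame and L)."""
    out = np.full(len(reals), np.nan)
    for k, real in enumerate(reals):
        if real.any():
            out[k] = rho_normalized(real)
    return out


def _window_result(
    label: str,
    block: TemporalDataset,
    config: RunConfig,
    seed_seq: np.random.SeedSequence,
) -> dict:
    network = build_network(block)
    N = copresence_matrix(block, network)
    emp_rho = rho_normalized(network.incidence)
    er_seed, model_seed = seed_seq.spawn(2)
    baseline = er_baseline_rho(
        network.R,
        network.C,
        network.L,
        config.n_er_graphs,
        np.random.default_rng(er_seed),
    )
    result: dict = {
        "window": label,
        "network": {
            "R": network.R,
            "C": network.C,
            "L": network.L,
            "fill": network.fill,
            "f": N.f,
            "rho_raw": spectral_radius_raw(network.incidence),
            "rho": emp_rho,
            "rho_er_mean": baseline.mean,
            "rho_er_sd": baseline.sd,
            "delta_rho": emp_rho - baseline.mean,
            "copresence_summary": {
                "median": copresence_summary(N).median,
                "mean": copresence_summary(N).mean,
                "max": copresence_summary(N).max,
            },
        },
        "models": {},
    }
    for name, child in zip(config.models, model_seed.spawn(len(config.models))):
        entry: dict = {}
        try:
            probs = _model_probabilities(name, network, block)
        except ModelInfeasibleError as exc:
            result["models"][name] = {"error": str(exc)}
            continue
        if probs.fit is not None:
            entry["fit"] = probs.fit.to_dict()
        entry["expected_links"] = probs.expected_links

        sample_child, assess_child, backbone_child = child.spawn(3)
        reals = sample_realizations(
            probs, config.n_realizations, np.random.default_rng(sample_child)
        )
        rhos = _realization_rhos(reals)
        with np.errstate(invalid="ignore"):
            drt = (rhos - baseline.mean) / (emp_rho - baseline.mean)
        entry["nestedness"] = {
            "rho_mean": float(np.nanmean(rhos)),
            "rho_sd": float(np.nanstd(rhos, ddof=1)),
            "delta_rho_tilde_mean": float(np.nanmean(drt)),
            "delta_rho_tilde_sd": float(np.nanstd(drt, ddof=1)),
            "n_empty_realizations": int(np.isnan(rhos).sum()),
        }
        assessment = ensemble_assess(
            probs, network, config.n_realizations, np.random.default_rng(assess_child)
        )
        entry["assessment"] = assessment.summary
        if config.backbone and name in ("phenology", "presence"):
            bb = backbone_ratios(
                probs,
                network,
                n_realizations=config.n_realizations,
                er_graphs=config.backbone_er_graphs,
                seed=int(backbone_child.generate_state(1)[0] >> 1),
            )
            entry["backbone"] = bb.summary
        result["models"][name] = entry
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow and return a JSON-serializable bundle."""
    if config.synthetic is not None:
        data, _, gen_info = generate_dataset(config.synthetic)
        source = {"synthetic": config.synthetic.to_dict(),
                  "n_preference_injected": gen_info.n_preference_injected,
                  "n_preference_skipped": gen_info.n_preference_skipped}
    else:
        data = read_daily_events(config.input_path)
        source = {"input_path": str(config.input_path)}

    window = config.window
    if isinstance(window, list):
        window = [
            (datetime.date.fromisoformat(str(a)), datetime.date.fromisoformat(str(b)))
            for a, b in window
        ]
    blocks = aggregate_blocks(data, window)
    seed_root = np.random.SeedSequence(config.seed)
    windows = [
        _window_result(label, block, config, child)
        for (label, block), child in zip(blocks, seed_root.spawn(len(blocks)))
    ]
    bundle = {
        "manifest": {
            "phenonet_version": __version__,
            "config": config.to_dict(),
            "source": source,
            "n_records": data.n_records,
            "n_observation_days": len(data.observation_days),
        },
        "windows": windows,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "bundle.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True) + "\n"
        )
    return bundle
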