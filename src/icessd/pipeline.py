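"""End-to-end reproduction workflow: data → filter → SSDs → HC5 → K-S.

:func:`run_reproduction` executes the full derivation on the bundled
tables (or user-supplied tables of the same shape) and returns a
:class:`PipelineReport` that records every configuration choice alongside
the results, so the exact provenance of each number is part of the output.

The default reproduction configuration fits the SSD by least squares
against Weibull plotting positions with *estimated* curve asymptotes
(``asymptotes="free"``).  The published hazardous concentrations this
workflow reproduces are consistent with that convention — the default
behavior of the curve-fitting software used for the original analysis —
and not with the 0/1-pinned two-parameter fit, which yields far lower
HC5 values on the same data (both variants are one config switch apart,
and the report states which was used).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import core_data
from .comparison import KSResult, ks_two_sample
from .core_data import SpeciesToxicity, geometric_mean_by_species, normalize_name
from .ice_models import FilterCriteria, filter_models, load_published_models
from .ssd import HCEstimate, SSDFit, bootstrap_hcp, fit_loglogistic, hcp

__all__ = ["ReproductionConfig", "PipelineReport", "run_reproduction"]

SURROGATE_SPECIES = ("Oncorhynchus mykiss", "Hyalella azteca", "Daphnia magna")


@dataclass(frozen=True)
class ReproductionConfig:
    """Everything that influences the reproduction run."""

    measured_path: str | Path | None = None
    predicted_path: str | Path | None = None
    predicted_unit: str = "ugL"
    plotting_position: str = "weibull"
    fit_method: str = "ls"
    asymptotes: str = "free"
    p: float = 0.05
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    n_boot: int = 0
    seed: int = 0


@dataclass(frozen=True)
class PipelineReport:
    config: ReproductionConfig
    input_summary: dict
    surrogate_seeds_ugL: dict
    n_models_accepted: int
    n_models_rejected: int
    strict_filter_rejects: tuple[str, ...]
    measured_fit: SSDFit
    ice_fit: SSDFit
    measured_hc: HCEstimate
    ice_hc: HCEstimate
    ks_exact: KSResult
    ks_asymptotic: KSResult
    warnings: tuple[str, ...]

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return enc(dataclasses.asdict(self))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)


def _surrogate_seeds(species: list[SpeciesToxicity]) -> dict:
    by_name = {normalize_name(s.species_name): s for s in species}
    out = {}
    for name in SURROGATE_SPECIES:
        agg = by_name.get(normalize_name(name))
        if agg is not None:
            out[name] = agg.value_ugL
    return out


def run_reproduction(config: ReproductionConfig | None = None) -> PipelineReport:
    """Run the full measured-vs-extrapolated criteria derivation."""
    config = config or ReproductionConfig()

    measured_records = (
        core_data.load_table1()
        if config.measured_path is None
        else core_data.load_toxicity_table(config.measured_path)
    )
    measured = geometric_mean_by_species(measured_records)

    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        pairs = load_published_models(config.predicted_path, unit=config.predicted_unit)
        models = [m for m, _ in pairs]
        accepted, rejected = filter_models(models, config.criteria, allow_unknown=True)
        strict_accepted, strict_rejected = filter_models(
            models, config.criteria.strict(), allow_unknown=True
        )

        accepted_ids = {id(m) for m in accepted}
        ice_records = [rec for m, rec in pairs if id(m) in accepted_ids]
        ice_species = geometric_mean_by_species(ice_records)

        fit_kw = dict(
            plotting_position=config.plotting_position,
            method=config.fit_method,
            asymptotes=config.asymptotes,
        )
        measured_fit = fit_loglogistic(measured, **fit_kw)
        ice_fit = fit_loglogistic(ice_species, **fit_kw)
        if config.n_boot > 0:
            measured_hc = bootstrap_hcp(
                measured, p=config.p, n_boot=config.n_boot,
                seed=config.seed, **fit_kw,
            )
            ice_hc = bootstrap_hcp(
                ice_species, p=config.p, n_boot=config.n_boot,
                seed=config.seed + 1, **fit_kw,
            )
        else:
            measured_hc = hcp(measured_fit, config.p)
            ice_hc = hcp(ice_fit, config.p)

        log_measured = [s.log10_value for s in measured]
        log_ice = [s.log10_value for s in ice_species]
        ks_exact = ks_two_sample(log_measured, log_ice, method="exact")
        ks_asym = ks_two_sample(log_measured, log_ice, method="asymptotic")

    policy_passes = 0
    seen = set()
    for w in caught:
        msg = str(w.message)
        if "passed by policy" in msg:
            policy_passes += 1
        elif msg not in seen:
            seen.add(msg)
            collected.append(msg)
    if policy_passes:
        collected.insert(
            0,
            "models with unknown df/p diagnostics were passed by the "
            f"allow_unknown policy ({policy_passes} checks)",
        )
    for fit, label in ((measured_fit, "measured"), (ice_fit, "ice")):
        if not fit.converged:
            collected.append(f"{label} SSD fit did not converge")

    return PipelineReport(
        config=config,
        input_summary={
            "measured_records": len(measured_records),
            "measured_species": len(measured),
            "predicted_models": len(models),
            "ice_species": len(ice_species),
        },
        surrogate_seeds_ugL=_surrogate_seeds(measured),
        n_models_accepted=len(accepted),
        n_models_rejected=len(rejected),
        strict_filter_rejects=tuple(
            m.predicted.species for m, _ in strict_rejected
        ),
        measured_fit=measured_fit,
        ice_fit=ice_fit,
        measured_hc=measured_hc,
        ice_hc=ice_hc,
        ks_exact=ks_exact,
        ks_asymptotic=ks_asym,
        warnings=tuple(collected),
    )
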