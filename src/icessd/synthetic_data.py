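"""Synthetic generators matching the statistical structure the pipeline assumes.

Two generating processes cover every stage of the analysis without any
external data:

* cross-species toxicity pairs in which the predicted species' log10
  toxicity is linear in the surrogate's log10 toxicity plus Gaussian noise
  (the interspecies-correlation regression model), and
* species-level values drawn from a log-logistic SSD with known location
  and slope, by inverse-transform sampling of the logistic in log10 space.

Both are pure functions of their scenario, including its seed.  Defaults
mirror realistic acute aquatic toxicity work: surrogate values spanning
10–10^6 μg/L (the range printed toxicity tables cover), regression noise
of 0.2 log10 units (within the 5-fold cross-validation band that adopted
interspecies models must meet), and around 30 chemicals per regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import SpeciesToxicity, Taxonomy

__all__ = [
    "InterspeciesScenario",
    "SSDScenario",
    "generate_interspecies_pairs",
    "sample_loglogistic_species",
]


@dataclass(frozen=True)
class InterspeciesScenario:
    """Linear log–log toxicity relation between two species across chemicals."""

    n_chemicals: int = 30
    slope: float = 0.9
    intercept: float = 0.5
    noise_sd: float = 0.2
    surrogate_log_range: tuple[float, float] = (1.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.surrogate_log_range
        if not low < high:
            raise ValueError("surrogate_log_range must satisfy low < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be positive")


@dataclass(frozen=True)
class SSDScenario:
    """Log-logistic species sensitivity distribution with known parameters."""

    alpha: float = 3.0
    beta: float = 0.5
    n_species: int = 30
    seed: int = 0
    taxonomy_template: Taxonomy = field(
        default=Taxonomy(
            species="",
            genus="Synthetogenus",
            family="Synthetidae",
            order="Synthetiformes",
            class_="Synthetia",
            phylum="Synthetica",
        )
    )

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")


def generate_interspecies_pairs(
    scenario: InterspeciesScenario,
) -> list[tuple[float, float]]:
    """Draw (surrogate, predicted) log10 toxicity pairs.

    Surrogate values are uniform on ``surrogate_log_range``; predicted
    values are ``intercept + slope*surrogate`` plus Gaussian noise of sd
    ``noise_sd`` (in log10 units).
    """
    rng = np.random.default_rng(scenario.seed)
    low, high = scenario.surrogate_log_range
    x = rng.uniform(low, high, size=scenario.n_chemicals)
    y = scenario.intercept + scenario.slope * x
    if scenario.noise_sd > 0:
        y = y + rng.normal(0.0, scenario.noise_sd, size=scenario.n_chemicals)
    return [(float(a), float(b)) for a, b in zip(x, y)]


def sample_loglogistic_species(
    scenario: SSDScenario, u: np.ndarray | None = None
) -> list[SpeciesToxicity]:
    """Draw species-level toxicity values from a log-logistic SSD.

    Inverse-transform sampling: u ~ Uniform(0,1), then
    ``X = alpha + beta*ln(u/(1-u))`` and value ``10**X`` μg/L.  The ``u``
    argument overrides the uniform draws (a hook for degenerate tests,
    e.g. all-median samples); its length must be ``n_species``.
    """
    if u is None:
        rng = np.random.default_rng(scenario.seed)
        u = rng.uniform(size=scenario.n_species)
    else:
        u = np.asarray(u, dtype=float)
        if u.shape != (scenario.n_species,):
            raise ValueError("u must have length n_species")
        if not np.all((u > 0) & (u < 1)):
            raise ValueError("u values must lie strictly in (0, 1)")
    x = scenario.alpha + scenario.beta * np.log(u / (1.0 - u))
    template = scenario.taxonomy_template
    out = []
    for i, xi in enumerate(x, start=1):
        name = f"Synthetospecies sp{i:04d}"
        out.append(
            SpeciesToxicity(
                species_name=name,
                taxonomy=Taxonomy(
                    species=name,
                    genus=template.genus,
                    family=template.family,
                    order=template.order,
                    class_=template.class_,
                    phylum=template.phylum,
                ),
                value_ugL=float(10.0**xi),
            )
        )
    return out
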