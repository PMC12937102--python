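"""Ground-truth models and simulated measurements.

Everything the inference stage consumes can be generated here: a
ground-truth parameter vector drawn from the prior (rejection-sampled
until its observables are computable), noisy pseudo-measurements with
the Gaussian error model of the likelihood, and a packaged fixture whose
wild-type/mutant kinetics reproduce the qualitative asymmetry of the
two-site ATPase (mutating site I roughly halves turnover, mutating
site II strongly increases it).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from .inference import (
    ExperimentalData,
    KINETIC_IDS,
    OCCUPANCY_IDS,
    ObservableModel,
    ParameterLayout,
    PriorSpec,
)
from .model import ModelClass
from .observables import KmBracketError, SteadyStateError

#: Default relative measurement uncertainty of the pseudo-experiments.
DEFAULT_SIGMA_REL = 0.15


@dataclass
class GroundTruth:
    """A known-true model with its noise-free observables."""

    mc: ModelClass
    x: np.ndarray
    observables: dict[tuple[str, str], float]
    seed: int | None = None
    rejections: int = 0
    layout: ParameterLayout = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.layout is None:
            self.layout = ParameterLayout(self.mc)


def default_constraint(obs: dict[tuple[str, str], float]) -> bool:
    """Plausibility window for drawn truths: moderate, measurable kinetics."""
    kcats = [obs[("kcat", sp)] for sp in ("WT", "E238Q", "E485Q")]
    kms = [obs[("km", sp)] for sp in ("WT", "E238Q", "E485Q")]
    return all(1e-4 <= v <= 1e4 for v in kcats) and all(
        1e-8 <= v <= 1e1 for v in kms
    )


def draw_ground_truth(
    mc: ModelClass | None = None,
    prior: PriorSpec | None = None,
    seed: int = 0,
    constraint: Callable[[dict], bool] | None = default_constraint,
    include_occupancies: bool = False,
    max_tries: int = 100000,
) -> GroundTruth:
    """Rejection-sample the prior until all observables are computable.

    ``constraint`` can further restrict the accepted truth (pass None to
    accept any computable model).  Reproducible given ``seed``; the
    number of rejected draws is recorded.
    """
    mc = mc or ModelClass()
    layout = ParameterLayout(mc, prior)
    obs_model = ObservableModel(mc, layout)
    ids = list(KINETIC_IDS) + (list(OCCUPANCY_IDS) if include_occupancies else [])
    rng = np.random.default_rng(seed)
    for tries in range(max_tries):
        x = layout.sample_uniform(rng, 1)[0]
        try:
            obs = obs_model.compute(x, ids)
        except (KmBracketError, SteadyStateError):
            continue
        if not all(np.isfinite(list(obs.values()))):
            continue
        if constraint is not None and not constraint(obs):
            continue
        return GroundTruth(
            mc=mc, x=x, observables=obs, seed=seed, rejections=tries, layout=layout
        )
    raise RuntimeError(f"no acceptable ground truth in {max_tries} prior draws")


def simulate_measurements(
    truth: GroundTruth,
    sigma_rel: float | None = DEFAULT_SIGMA_REL,
    sigma_abs: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    ids: Sequence[tuple[str, str]] | None = None,
) -> ExperimentalData:
    """Noisy pseudo-measurements mu_i = x_i + eps, eps ~ N(0, sigma_i).

    Sigmas are relative (``sigma_rel`` times |x_i|) unless an absolute
    ``sigma_abs`` entry overrides them.  With ``sigma_rel=0`` the
    noise-free observables are returned with a nominal sigma floor.
    """
    rng = np.random.default_rng(seed)
    if ids is None:
        ids = [cid for cid in truth.observables]
    records = []
    for cid in ids:
        x_i = truth.observables[cid]
        if sigma_abs is not None and cid in sigma_abs:
            s = float(sigma_abs[cid])
        else:
            s = float(abs(x_i) * (sigma_rel or 0.0))
        noise = rng.normal(0.0, s) if s > 0 else 0.0
        records.append((cid[0], cid[1], x_i + noise, s if s > 0 else max(abs(x_i) * 1e-6, 1e-12)))
    return ExperimentalData.from_records(records)


def asymmetric_fixture() -> GroundTruth:
    """The packaged synthetic parameter set with mutant kinetic asymmetry.

    A fixed 17-parameter model (found once by constrained search within
    the prior box and committed as package data) for which, under the
    100-fold hydrolysis knockdown, mutating NBSI gives roughly half the
    wild-type turnover while mutating NBSII increases turnover at least
    five-fold.  Wild-type flux runs dominantly through hydrolysis at a
    single site, with the opposite-site hydrolysis acting as drainage.
    """
    text = (
        importlib.resources.files("twinsite.data")
        .joinpath("fixture_asymmetric.yaml")
        .read_text()
    )
    payload = yaml.safe_load(text)
    mc = ModelClass()
    layout = ParameterLayout(mc)
    x = np.array([payload["parameters"][name] for name in layout.names])
    obs_model = ObservableModel(mc, layout)
    obs = obs_model.compute(x, list(KINETIC_IDS))
    return GroundTruth(mc=mc, x=x, observables=obs, seed=payload.get("seed"), layout=layout)


__all__ = [
    "DEFAULT_SIGMA_REL",
    "GroundTruth",
    "asymmetric_fixture",
    "default_constraint",
    "draw_ground_truth",
    "simulate_measurements",
]
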