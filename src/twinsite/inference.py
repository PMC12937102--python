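"""Bayesian inference of transition rate coefficients.

The posterior P(M | {mu_i, sigma_i}) ∝ P({mu_i, sigma_i} | M) P(M) over
Markov models M combines a Gaussian likelihood of the computed
observables x_i with uniform priors on the free-energy parameters,
whose box bounds derive from physically motivated rate-coefficient
bounds (uniform in free energy = log-uniform in rate space).  Sampling
uses an affine-invariant ensemble MCMC; convergence is assessed with
split-R-hat, and the maximum-posterior models are refined by
first-choice hill climbing.  Model classes are compared with the
Bayesian information criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd

from .constants import T_REF, attempt_frequency
from .model import (
    DIFF_KEYS,
    FreeEnergyParams,
    ModelClass,
    MutationSpec,
    SPECIES_SITE,
)
from .observables import (
    KmBracketError,
    SteadyStateError,
    kinetic_observables,
    kinetic_observables_multi,
    occupancy_single_turnover,
    occupancy_steady,
)

SPECIES = ("WT", "E238Q", "E485Q")

#: Kinetic observable ids, in canonical data order.
KINETIC_IDS = tuple(
    (obs_name, sp) for sp in SPECIES for obs_name in ("kcat", "km")
)
#: Occupancy observable ids (steady-state ATP; single-turnover ATP and ADP).
OCCUPANCY_IDS = tuple(
    (obs_name, sp)
    for sp in SPECIES
    for obs_name in ("occ_ATP_steady", "occ_ATP_st", "occ_ADP_st")
)


@dataclass
class ExperimentalData:
    """Measured observables: id, species, mean mu and uncertainty sigma."""

    entries: pd.DataFrame  # columns: observable, species, mu, sigma

    def __post_init__(self) -> None:
        required = {"observable", "species", "mu", "sigma"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"data table needs columns {sorted(required)}")
        if (self.entries["sigma"] <= 0).any():
            raise ValueError("all sigma must be positive")
        ids = list(zip(self.entries["observable"], self.entries["species"]))
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate observable ids")

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[tuple[str, str]]:
        return list(zip(self.entries["observable"], self.entries["species"]))

    @property
    def mu(self) -> np.ndarray:
        return self.entries["mu"].to_numpy(dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return self.entries["sigma"].to_numpy(dtype=float)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float]]
    ) -> "ExperimentalData":
        return cls(
            pd.DataFrame(records, columns=["observable", "species", "mu", "sigma"])
        )

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExperimentalData":
        return cls(pd.read_csv(path))


#: Default rate-coefficient prior bounds per transition group (numeric
#: values as printed for the sampling priors; used at 1 M reference
#: concentrations, i.e. as 1/s bounds on the folded coefficients).
DEFAULT_RATE_BOUNDS: dict[str, tuple[float, float]] = {
    "binding": (1e-6, 1e7),
    "unbinding": (1e-6, 1e7),
    "chemical": (1e-6, 1e12),
    "conformational": (1e-6, 1e6),
}


def _label_group(label: str) -> str:
    if label.startswith("bind"):
        return "binding"
    if label.startswith("conf"):
        return "conformational"
    return "chemical"


def _backward_group(label: str) -> str:
    if label.startswith("bind"):
        return "unbinding"
    return _label_group(label)


@dataclass
class PriorSpec:
    """Uniform box priors in free-energy space.

    Barrier bounds per transition derive from the rate bounds via the
    Eyring relation ΔG‡ = ln(ω0/k) at the reference temperature; the
    bounds of a free-energy difference combine the forward and backward
    barrier bounds.  Extended classes add log10 hydrolysis reduction
    factors (log-uniform in [1e-12, 1]) and affinity shifts (uniform in
    [-10, 3] kT).
    """

    rate_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_BOUNDS)
    )
    mutation_factor_bounds: tuple[float, float] = (1e-12, 1.0)
    affinity_bounds: tuple[float, float] = (-10.0, 3.0)
    ref_temperature: float = T_REF
    state_energy_bounds: tuple[float, float] = (-100.0, 100.0)

    def __post_init__(self) -> None:
        for group, (lo, hi) in self.rate_bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"invalid rate bounds for {group}: ({lo}, {hi})")

    def barrier_bounds(self, label: str) -> tuple[float, float]:
        """kT bounds of a forward barrier (from the rate bounds)."""
        lo, hi = self.rate_bounds[_label_group(label)]
        omega0 = attempt_frequency(self.ref_temperature)
        return (math.log(omega0 / hi), math.log(omega0 / lo))

    def backward_barrier_bounds(self, label: str) -> tuple[float, float]:
        lo, hi = self.rate_bounds[_backward_group(label)]
        omega0 = attempt_frequency(self.ref_temperature)
        return (math.log(omega0 / hi), math.log(omega0 / lo))

    def diff_bounds(self, key: str) -> tuple[float, float]:
        """Bounds of a free-energy difference (forward minus backward barrier)."""
        fwd = {
            "bind_ATP_I": "bind_ATP_I",
            "bind_ADP_I": "bind_ADP_I",
            "bind_ATP_II": "bind_ATP_II",
            "bind_ADP_II": "bind_ADP_II",
            "open_to_closed": "conf_TT",
            "ATP_to_ADP_closed_I": "hyd_I",
            "ATP_to_ADP_closed_II": "hyd_II",
        }[key]
        f_lo, f_hi = self.barrier_bounds(fwd)
        b_lo, b_hi = self.backward_barrier_bounds(fwd)
        return (f_lo - b_hi, f_hi - b_lo)


class ParameterLayout:
    """Maps flat parameter vectors onto FreeEnergyParams (+ mutations).

    Order: forward barriers (label order), then free-energy differences
    (additive layout) or state energies of states 1..12 (allosteric
    layout), then per variant tag [log10 f_I, log10 f_II, shift_ATP_I,
    shift_ADP_I, shift_ATP_II, shift_ADP_II] when the class allows
    mutation-specific parameters.
    """

    def __init__(self, mc: ModelClass, prior: PriorSpec | None = None) -> None:
        self.mc = mc
        self.prior = prior or PriorSpec()
        names: list[str] = [f"barrier.{lab}" for lab in mc.labels]
        lo = [self.prior.barrier_bounds(lab)[0] for lab in mc.labels]
        hi = [self.prior.barrier_bounds(lab)[1] for lab in mc.labels]
        if mc.allostery:
            names += [f"G.{s.key}" for s in mc.states[1:]]
            lo += [self.prior.state_energy_bounds[0]] * 12
            hi += [self.prior.state_energy_bounds[1]] * 12
        else:
            names += [f"dG.{k}" for k in DIFF_KEYS]
            for k in DIFF_KEYS:
                b = self.prior.diff_bounds(k)
                lo.append(b[0])
                hi.append(b[1])
        if mc.mutation_model == "free_factor_and_affinity":
            flo, fhi = self.prior.mutation_factor_bounds
            alo, ahi = self.prior.affinity_bounds
            for tag in mc.variant_tags:
                for site in ("I", "II"):
                    names.append(f"log10_f_{site}.{tag}")
                    lo.append(math.log10(flo))
                    hi.append(math.log10(fhi))
                for nuc_site in ("ATP_I", "ADP_I", "ATP_II", "ADP_II"):
                    names.append(f"shift_{nuc_site}.{tag}")
                    lo.append(alo)
                    hi.append(ahi)
        self.names = names
        self.lower = np.array(lo)
        self.upper = np.array(hi)

    @property
    def n(self) -> int:
        return len(self.names)

    def split(self, x: np.ndarray) -> tuple[FreeEnergyParams, dict[str, dict]]:
        """Unpack a vector into free-energy params and per-tag mutation info."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"expected vector of length {self.n}, got {x.shape}")
        mc = self.mc
        nb = len(mc.labels)
        barriers = dict(zip(mc.labels, x[:nb]))
        pos = nb
        if mc.allostery:
            se = np.zeros(13)
            se[1:] = x[pos : pos + 12]
            params = FreeEnergyParams(
                barriers=barriers,
                state_energies=se,
                ref_temperature=self.prior.ref_temperature,
            )
            pos += 12
        else:
            diffs = dict(zip(DIFF_KEYS, x[pos : pos + len(DIFF_KEYS)]))
            params = FreeEnergyParams(
                barriers=barriers,
                diffs=diffs,
                ref_temperature=self.prior.ref_temperature,
            )
            pos += len(DIFF_KEYS)
        mutation_info: dict[str, dict] = {}
        if mc.mutation_model == "free_factor_and_affinity":
            for tag in mc.variant_tags:
                block = x[pos : pos + 6]
                pos += 6
                mutation_info[tag] = {
                    "factor_NBSI": 10.0 ** block[0],
                    "factor_NBSII": 10.0 ** block[1],
                    "shifts": {
                        ("ATP", "NBSI"): block[2],
                        ("ADP", "NBSI"): block[3],
                        ("ATP", "NBSII"): block[4],
                        ("ADP", "NBSII"): block[5],
                    },
                }
        return params, mutation_info

    def mutation_for(
        self, species: str, mutation_info: dict[str, dict], tag: str = "EQ"
    ) -> MutationSpec | None:
        site = SPECIES_SITE[species]
        if site is None:
            return None
        if not mutation_info:
            return self.mc.mutation_for_species(species)
        info = mutation_info[tag]
        factor = 1.0 / info[f"factor_{site}"]
        shifts = {
            key: val for key, val in info["shifts"].items() if key[1] == site
        }
        return MutationSpec(
            site=site,
            hydrolysis_reduction_factor=factor,
            affinity_shift=shifts,
            variant_tag=tag,  # type: ignore[arg-type]
        )

    def sample_uniform(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(size, self.n))


def log_prior(x: np.ndarray, layout: ParameterLayout) -> float:
    """0 inside the prior box (up to a constant), -inf outside."""
    x = np.asarray(x, dtype=float)
    if ((x < layout.lower) | (x > layout.upper)).any():
        return -np.inf
    return 0.0


class ObservableModel:
    """Computes the observables x_i of Eq-style likelihoods, with caching.

    Single-turnover observables use the EA variant tag when the class
    distinguishes EQ (steady-state) from EA (single-turnover) mutations.
    """

    def __init__(
        self,
        mc: ModelClass,
        layout: ParameterLayout | None = None,
        cache_size: int = 4096,
    ) -> None:
        self.mc = mc
        self.layout = layout or ParameterLayout(mc)
        self._cache: dict[bytes, dict] = {}
        self._cache_size = cache_size

    def compute(
        self, x: np.ndarray, ids: Sequence[tuple[str, str]]
    ) -> dict[tuple[str, str], float]:
        key = np.asarray(x, dtype=float).tobytes()
        cached = self._cache.get(key)
        if cached is None:
            cached = {}
            if len(self._cache) >= self._cache_size:
                self._cache.clear()
            self._cache[key] = cached
        out = {}
        params, mut_info = None, None
        kin_cache: dict[tuple[str, str], object] = {}
        kinetic_species = [
            sp for name, sp in ids if name in ("kcat", "km") and (name, sp) not in cached
        ]
        if kinetic_species:
            params, mut_info = self.layout.split(x)
            mutations = {
                sp: self.layout.mutation_for(sp, mut_info, "EQ")
                for sp in dict.fromkeys(kinetic_species)
            }
            for sp, kin in kinetic_observables_multi(self.mc, params, mutations).items():
                kin_cache[("kin", sp)] = kin
        for obs_name, species in ids:
            cid = (obs_name, species)
            if cid in cached:
                out[cid] = cached[cid]
                continue
            if params is None:
                params, mut_info = self.layout.split(x)
            if obs_name in ("kcat", "km"):
                kin = kin_cache[("kin", species)]
                value = kin.kcat if obs_name == "kcat" else kin.km
            elif obs_name == "occ_ATP_steady" or obs_name == "occ_ADP_steady":
                occ = kin_cache.get(("occ_ss", species))
                if occ is None:
                    mutation = self.layout.mutation_for(species, mut_info, "EQ")
                    occ = occupancy_steady(self.mc, params, mutation)
                    kin_cache[("occ_ss", species)] = occ
                value = occ[0] if obs_name == "occ_ATP_steady" else occ[1]
            elif obs_name in ("occ_ATP_st", "occ_ADP_st"):
                occ = kin_cache.get(("occ_st", species))
                if occ is None:
                    mutation = self.layout.mutation_for(species, mut_info, "EA")
                    res = occupancy_single_turnover(self.mc, params, mutation)
                    occ = (res.occ_ATP, res.occ_ADP)
                    kin_cache[("occ_st", species)] = occ
                value = occ[0] if obs_name == "occ_ATP_st" else occ[1]
            else:
                raise ValueError(f"unknown observable {obs_name!r}")
            cached[cid] = value
            out[cid] = value
        return out


def log_likelihood(
    x: np.ndarray, data: ExperimentalData, observable_model: ObservableModel
) -> float:
    """Sum of Gaussian log densities; -inf when observables fail."""
    ids = getattr(data, "_ids_cache", None)
    if ids is None:
        ids = data.ids
        data._ids_cache = ids  # type: ignore[attr-defined]
        data._mu_cache = data.mu  # type: ignore[attr-defined]
        data._sigma_cache = data.sigma  # type: ignore[attr-defined]
    try:
        computed = observable_model.compute(x, ids)
    except (KmBracketError, SteadyStateError, FloatingPointError):
        return -np.inf
    xs = np.array([computed[cid] for cid in ids])
    if not np.isfinite(xs).all():
        return -np.inf
    mu, sigma = data._mu_cache, data._sigma_cache  # type: ignore[attr-defined]
    return float(
        -0.5 * np.sum(((xs - mu) / sigma) ** 2)
        - np.sum(np.log(sigma * math.sqrt(2 * math.pi)))
    )


def make_log_posterior(
    data: ExperimentalData, layout: ParameterLayout, observable_model: ObservableModel
) -> Callable[[np.ndarray], float]:
    def log_post(x: np.ndarray) -> float:
        lp = log_prior(x, layout)
        if not np.isfinite(lp):
            return -np.inf
        return lp + log_likelihood(x, data, observable_model)

    return log_post


@dataclass
class SampleSet:
    """Posterior samples from independent MCMC ensembles.

    ``chains`` has shape (n_chains, n_steps, n_walkers, ndim) and
    ``log_post`` (n_chains, n_steps, n_walkers); each independent
    ensemble counts as one chain for convergence diagnostics.
    """

    chains: np.ndarray
    log_post: np.ndarray
    names: list[str]
    seed: int

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    def flat(self, burn_fraction: float = 0.5) -> np.ndarray:
        burn = int(self.chains.shape[1] * burn_fraction)
        post = self.chains[:, burn:, :, :]
        return post.reshape(-1, self.chains.shape[-1])

    def flat_log_post(self, burn_fraction: float = 0.5) -> np.ndarray:
        burn = int(self.chains.shape[1] * burn_fraction)
        return self.log_post[:, burn:, :].reshape(-1)

    def best(self) -> tuple[np.ndarray, float]:
        idx = np.unravel_index(np.argmax(self.log_post), self.log_post.shape)
        return self.chains[idx[0], idx[1], idx[2]].copy(), float(self.log_post[idx])

    def top(self, n: int = 20) -> list[tuple[np.ndarray, float]]:
        """The n distinct samples with highest posterior."""
        flatx = self.chains.reshape(-1, self.chains.shape[-1])
        flatlp = self.log_post.reshape(-1)
        order = np.argsort(flatlp)[::-1]
        out: list[tuple[np.ndarray, float]] = []
        seen: set[bytes] = set()
        for i in order:
            key = flatx[i].tobytes()
            if key in seen:
                continue
            seen.add(key)
            out.append((flatx[i].copy(), float(flatlp[i])))
            if len(out) == n:
                break
        return out


def _initial_walkers(
    layout: ParameterLayout,
    log_post: Callable[[np.ndarray], float],
    n_walkers: int,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Draw walkers from the prior, retrying nonfinite posteriors."""
    walkers = []
    best_fallback = None
    for _ in range(max_tries):
        x = layout.sample_uniform(rng, 1)[0]
        lp = log_post(x)
        if np.isfinite(lp):
            walkers.append(x)
            if len(walkers) == n_walkers:
                return np.array(walkers)
        elif best_fallback is None:
            best_fallback = x
    if walkers:
        # pad with jittered copies of finite walkers
        while len(walkers) < n_walkers:
            base = walkers[len(walkers) % len(walkers)]
            x = base + rng.normal(scale=1e-4, size=layout.n)
            x = np.clip(x, layout.lower, layout.upper)
            walkers.append(x)
        return np.array(walkers)
    raise RuntimeError(
        f"could not initialize any walker with finite posterior in {max_tries} draws"
    )


def _slice_update(
    x: np.ndarray,
    logf: Callable[[np.ndarray], float],
    fx: float,
    dim: int,
    width: float,
    lower: float,
    upper: float,
    rng: np.random.Generator,
    max_steps: int = 3,
) -> tuple[np.ndarray, float]:
    """Univariate slice-sampling update of one coordinate (stepping out)."""
    y = fx + math.log(rng.uniform())
    x0 = x[dim]
    left = x0 - width * rng.uniform()
    right = left + width

    def f_at(v: float) -> float:
        x[dim] = v
        return logf(x)

    steps = max_steps
    while left > lower and steps > 0 and f_at(left) > y:
        left -= width
        steps -= 1
    left = max(left, lower)
    steps = max_steps
    while right < upper and steps > 0 and f_at(right) > y:
        right += width
        steps -= 1
    right = min(right, upper)
    for _ in range(100):
        prop = rng.uniform(left, right)
        fp = f_at(prop)
        if fp > y:
            return x, fp
        if prop < x0:
            left = prop
        else:
            right = prop
    x[dim] = x0
    return x, fx


def _replica_exchange_chain(
    log_like: Callable[[np.ndarray], float],
    layout: ParameterLayout,
    n_sweeps: int,
    n_replicas: int,
    beta_min: float,
    width_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One replica-exchange slice-sampling chain; returns the cold trace."""
    betas = np.geomspace(1.0, beta_min, n_replicas)
    box = layout.upper - layout.lower
    # hot replicas take wider slice steps (flatter tempered targets)
    widths = [
        np.minimum(width_fraction * box / math.sqrt(beta), 0.5 * box)
        for beta in betas
    ]
    xs = []
    lls = []
    for _ in range(n_replicas):
        for _try in range(500):
            x = layout.sample_uniform(rng, 1)[0]
            ll = log_like(x)
            if np.isfinite(ll):
                break
        else:
            raise RuntimeError("no finite-likelihood replica start found")
        xs.append(x)
        lls.append(ll)
    xs = np.array(xs)
    lls = np.array(lls)
    trace = np.empty((n_sweeps, layout.n))
    trace_ll = np.empty(n_sweeps)
    order = np.arange(layout.n)
    for sweep in range(n_sweeps):
        for r in range(n_replicas):
            beta = betas[r]

            def logf(v: np.ndarray) -> float:
                ll = log_like(v)
                logf.last_ll = ll  # type: ignore[attr-defined]
                return beta * ll if np.isfinite(ll) else -np.inf

            x = xs[r]
            fx = beta * lls[r]
            rng.shuffle(order)
            for dim in order:
                x, fx = _slice_update(
                    x, logf, fx, dim, widths[r][dim], layout.lower[dim],
                    layout.upper[dim], rng,
                )
            xs[r] = x
            lls[r] = fx / beta if beta > 0 else log_like(x)
        # adjacent-pair swaps, alternating parity
        for r in range(sweep % 2, n_replicas - 1, 2):
            delta = (betas[r] - betas[r + 1]) * (lls[r + 1] - lls[r])
            if delta >= 0 or rng.uniform() < math.exp(delta):
                xs[[r, r + 1]] = xs[[r + 1, r]]
                lls[[r, r + 1]] = lls[[r + 1, r]]
        trace[sweep] = xs[0]
        trace_ll[sweep] = lls[0]
    return trace, trace_ll


def sample_posterior(
    data: ExperimentalData,
    mc: ModelClass,
    prior: PriorSpec | None = None,
    n_chains: int = 4,
    n_steps: int = 400,
    seed: int = 0,
    method: str = "replica_exchange",
    n_replicas: int = 6,
    beta_min: float = 1.0 / 64.0,
    width_fraction: float = 0.25,
    n_walkers: int = 36,
    thin: int = 1,
    progress: bool = False,
) -> SampleSet:
    """Posterior sampling with independent seeded chains.

    The default method runs replica-exchange Markov-chain Monte Carlo
    with a univariate slice sampler for local exploration (a geometric
    inverse-temperature ladder with adjacent swaps every sweep), which
    handles the strongly multimodal posterior over rate parameters.  The
    alternative ``method="ensemble"`` uses affine-invariant ensembles
    (emcee) with differential-evolution moves.  Each chain gets its own
    seed derived from ``seed``; chains start from prior draws with
    finite posterior.
    """
    layout = ParameterLayout(mc, prior)
    obs_model = ObservableModel(mc, layout)
    chains = []
    lps = []
    if method == "replica_exchange":
        def log_like(x: np.ndarray) -> float:
            if not np.isfinite(log_prior(x, layout)):
                return -np.inf
            return log_likelihood(x, data, obs_model)

        for c in range(n_chains):
            rng = np.random.default_rng((seed * 1000003 + c) % 2**31)
            trace, trace_ll = _replica_exchange_chain(
                log_like, layout, n_steps, n_replicas, beta_min,
                width_fraction, rng,
            )
            # cold chain: posterior = likelihood (uniform prior, const 0)
            chains.append(trace[:, None, :])  # one "walker"
            lps.append(trace_ll[:, None])
    elif method == "ensemble":
        log_post = make_log_posterior(data, layout, obs_model)
        moves = [
            (emcee.moves.DEMove(), 0.7),
            (emcee.moves.DESnookerMove(), 0.2),
            (emcee.moves.StretchMove(), 0.1),
        ]
        for c in range(n_chains):
            rng = np.random.default_rng((seed * 1000003 + c) % 2**31)
            p0 = _initial_walkers(layout, log_post, n_walkers, rng)
            sampler = emcee.EnsembleSampler(n_walkers, layout.n, log_post, moves=moves)
            sampler.random_state = np.random.RandomState(
                (seed * 9176 + 31 * c + 7) % 2**31
            ).get_state()
            sampler.run_mcmc(
                p0, n_steps, thin_by=thin, progress=progress,
                skip_initial_state_check=True,
            )
            chains.append(sampler.get_chain())  # (n_steps, n_walkers, ndim)
            lps.append(sampler.get_log_prob())
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    return SampleSet(
        chains=np.array(chains),
        log_post=np.array(lps),
        names=layout.names,
        seed=seed,
    )


def rhat(samples: SampleSet, burn_fraction: float = 0.5) -> np.ndarray:
    """Split-R-hat per parameter, ensembles as chains, walkers pooled."""
    n_chains, n_steps, n_walkers, ndim = samples.chains.shape
    burn = int(n_steps * burn_fraction)
    post = samples.chains[:, burn:, :, :]
    # (chain, draw, dim): concatenate walkers along the draw axis
    arr = post.transpose(0, 2, 1, 3).reshape(n_chains, -1, ndim)
    return np.asarray(az.rhat(az.convert_to_dataset(arr))["x"].values, dtype=float)


def hill_climb(
    x0: np.ndarray,
    log_post: Callable[[np.ndarray], float],
    layout: ParameterLayout,
    budget: int = 1000,
    step_scale: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """First-choice hill climbing: accept the first improving perturbation.

    Proposals are Gaussian in a random subset of coordinates with scale
    ``step_scale`` times the prior box width, clipped to the box; the
    log-posterior trace is monotone non-decreasing.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("hill climb must start at finite posterior")
    width = layout.upper - layout.lower
    for _ in range(budget):
        prop = x.copy()
        k = rng.integers(1, max(2, layout.n // 3))
        idx = rng.choice(layout.n, size=k, replace=False)
        prop[idx] += rng.normal(scale=step_scale, size=k) * width[idx]
        prop = np.clip(prop, layout.lower, layout.upper)
        lp_prop = log_post(prop)
        if lp_prop > lp:
            x, lp = prop, lp_prop
    return x, float(lp)


def bic(k: int, n: int, best_log_likelihood: float) -> float:
    """Bayesian information criterion k*ln(n) - 2*ln(L-hat)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return k * math.log(n) - 2.0 * best_log_likelihood


@dataclass
class PredictiveSummary:
    values: dict[tuple[str, str], np.ndarray]
    quantiles: pd.DataFrame

    def covers(self, cid: tuple[str, str], value: float, level: float = 0.95) -> bool:
        """Whether ``value`` lies in the central credible interval."""
        v = self.values[cid]
        a = (1 - level) / 2
        lo, hi = np.quantile(v, [a, 1 - a])
        return bool(lo <= value <= hi)


def posterior_predictive(
    samples: np.ndarray,
    ids: Sequence[tuple[str, str]],
    observable_model: ObservableModel,
    max_samples: int | None = None,
    seed: int = 0,
) -> PredictiveSummary:
    """Observable distributions over posterior samples.

    Recomputes each requested observable for every (optionally
    subsampled) parameter vector; vectors whose observables fail are
    skipped and counted.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if len(samples) == 0:
        raise ValueError("empty sample set")
    if max_samples is not None and len(samples) > max_samples:
        rng = np.random.default_rng(seed)
        samples = samples[rng.choice(len(samples), max_samples, replace=False)]
    collected: dict[tuple[str, str], list[float]] = {cid: [] for cid in ids}
    for x in samples:
        try:
            vals = observable_model.compute(x, ids)
        except (KmBracketError, SteadyStateError):
            continue
        for cid in ids:
            collected[cid].append(vals[cid])
    values = {cid: np.array(v) for cid, v in collected.items()}
    if any(len(v) == 0 for v in values.values()):
        raise ValueError("no sample produced computable observables")
    rows = []
    for cid, v in values.items():
        qs = np.quantile(v, [0.025, 0.25, 0.5, 0.75, 0.975])
        rows.append(
            {
                "observable": cid[0],
                "species": cid[1],
                "n": len(v),
                "q2.5": qs[0],
                "q25": qs[1],
                "median": qs[2],
                "q75": qs[3],
                "q97.5": qs[4],
            }
        )
    return PredictiveSummary(values=values, quantiles=pd.DataFrame(rows))


def fraction_within_sigma(
    samples: np.ndarray,
    data: ExperimentalData,
    observable_model: ObservableModel,
    n_sigma: float = 1.0,
    max_samples: int | None = None,
    seed: int = 0,
) -> float:
    """Fraction of samples whose observables all lie within n_sigma."""
    samples = np.atleast_2d(samples)
    if max_samples is not None and len(samples) > max_samples:
        rng = np.random.default_rng(seed)
        samples = samples[rng.choice(len(samples), max_samples, replace=False)]
    hits = 0
    for x in samples:
        try:
            vals = observable_model.compute(x, data.ids)
        except (KmBracketError, SteadyStateError):
            continue
        xs = np.array([vals[cid] for cid in data.ids])
        if (np.abs(xs - data.mu) <= n_sigma * data.sigma).all():
            hits += 1
    return hits / len(samples)


__all__ = [
    "DEFAULT_RATE_BOUNDS",
    "ExperimentalData",
    "KINETIC_IDS",
    "OCCUPANCY_IDS",
    "ObservableModel",
    "ParameterLayout",
    "PredictiveSummary",
    "PriorSpec",
    "SPECIES",
    "SampleSet",
    "bic",
    "fraction_within_sigma",
    "hill_climb",
    "log_likelihood",
    "log_prior",
    "make_log_posterior",
    "posterior_predictive",
    "rhat",
    "sample_posterior",
]
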