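"""Markov model classes of a two-site ATPase with concerted conformational gating.

The enzyme (ABCE1-like) carries two nucleotide-binding sites (NBSI, NBSII)
that open and close together.  States combine one global conformation
(open/closed) with the occupancy of each site (apo/ATP/ADP, where "ADP"
stands for the lumped ADP+Pi product state).  Structural assumptions:

1. two conformations suffice (open, closed);
2. both sites share one conformation at all times;
3. the closed conformation requires both sites occupied;
4. ligand exchange happens only in the open conformation;
5. ATP hydrolysis happens only in the closed conformation;
6. without allostery, a transition's rate coefficient is independent of the
   occupancy of the opposite site (shared labels);
7. ADP and Pi exchange is lumped into a single effective transition;
8. point mutations only rescale the hydrolysis/synthesis coefficients of
   the mutated site (plus optional affinity shifts in extended classes).

This yields 13 states (9 open, 4 closed) and 20 reversible transitions
carrying 10 distinct rate-coefficient labels when allostery is off.

Rates derive from state free energies plus forward barriers (Eyring form),
which enforces detailed balance by construction.  The hydrolysis driving
force ΔG° is injected as a chemical-work term on the ADP+Pi exchange
edges, so that the product of forward/backward rate ratios around any
single-hydrolysis cycle equals exp(-ΔG°/kT) * [ATP]/([ADP][Pi]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .constants import (
    DG0_HYDROLYSIS_KJ_MOL,
    R_GAS,
    T_REF,
    attempt_frequency,
    dg0_in_kt,
)

Conformation = Literal["open", "closed"]
Occupancy = Literal["apo", "ATP", "ADP"]
Site = Literal["NBSI", "NBSII"]

OCC_ORDER: tuple[Occupancy, ...] = ("apo", "ATP", "ADP")
SITES: tuple[Site, Site] = ("NBSI", "NBSII")

#: ATP/ADP occupation numbers per occupancy code.
N_ATP = {"apo": 0, "ATP": 1, "ADP": 0}
N_ADP = {"apo": 0, "ATP": 0, "ADP": 1}

#: Keys of the seven free-energy differences of the non-allosteric layout.
DIFF_KEYS: tuple[str, ...] = (
    "bind_ATP_I",
    "bind_ADP_I",
    "bind_ATP_II",
    "bind_ADP_II",
    "open_to_closed",
    "ATP_to_ADP_closed_I",
    "ATP_to_ADP_closed_II",
)

TransitionKind = Literal[
    "bind_ATP_I",
    "bind_ATP_II",
    "bind_ADP_Pi_I",
    "bind_ADP_Pi_II",
    "conf_change",
    "hydrolysis_I",
    "hydrolysis_II",
]


class ModelError(ValueError):
    """Invalid model-class configuration or parameters."""


@dataclass(frozen=True, order=True)
class MarkovState:
    """One enzyme state: global conformation plus per-site occupancy."""

    conformation: Conformation
    occupancy_I: Occupancy
    occupancy_II: Occupancy
    index: int = field(compare=False, default=-1)

    def __post_init__(self) -> None:
        if self.conformation == "closed" and (
            self.occupancy_I == "apo" or self.occupancy_II == "apo"
        ):
            raise ModelError("closed conformation requires both sites occupied")

    @property
    def n_atp(self) -> int:
        return N_ATP[self.occupancy_I] + N_ATP[self.occupancy_II]

    @property
    def n_adp(self) -> int:
        return N_ADP[self.occupancy_I] + N_ADP[self.occupancy_II]

    @property
    def key(self) -> str:
        """Compact structural code, e.g. ``oTD`` = open, ATP in I, ADP in II."""
        code = {"apo": "a", "ATP": "T", "ADP": "D"}
        return self.conformation[0] + code[self.occupancy_I] + code[self.occupancy_II]


def enumerate_states() -> list[MarkovState]:
    """All 13 states in canonical order.

    Conformation-major (open first), then occupancy of NBSI, then NBSII,
    each in the order apo < ATP < ADP.  Index 0 is the open/apo/apo
    reference state.
    """
    states: list[MarkovState] = []
    for occ1 in OCC_ORDER:
        for occ2 in OCC_ORDER:
            states.append(MarkovState("open", occ1, occ2, index=len(states)))
    for occ1 in ("ATP", "ADP"):
        for occ2 in ("ATP", "ADP"):
            states.append(MarkovState("closed", occ1, occ2, index=len(states)))
    return states


@dataclass(frozen=True)
class Transition:
    """A reversible transition, stored in its forward orientation.

    Forward means: ligand binding (apo -> bound), open -> closed, or
    ATP -> ADP hydrolysis.  The ``label`` identifies the rate-coefficient
    pair; labels are shared across edges when allostery is off.
    """

    source: MarkovState
    target: MarkovState
    kind: TransitionKind
    label: str

    @property
    def site(self) -> Site | None:
        if self.kind.endswith("_I"):
            return "NBSI"
        if self.kind.endswith("_II"):
            return "NBSII"
        return None

    @property
    def is_exchange(self) -> bool:
        return self.kind.startswith("bind_")

    @property
    def is_adp_exchange(self) -> bool:
        return self.kind.startswith("bind_ADP")

    @property
    def is_hydrolysis(self) -> bool:
        return self.kind.startswith("hydrolysis")


def _occ_code(occ: Occupancy) -> str:
    return {"apo": "a", "ATP": "T", "ADP": "D"}[occ]


def enumerate_transitions(
    states: Sequence[MarkovState], allostery: bool = False
) -> list[Transition]:
    """The 20 forward transitions of the 13-state topology.

    12 ligand-exchange edges (2 ligands x 2 sites x 3 opposite-site
    occupancies), 4 conformational edges (one per doubly occupied pair) and
    4 hydrolysis edges (2 sites x 2 opposite-site occupancies).  Without
    allostery the edges carry 10 distinct labels (4 binding, 4
    conformational, 2 hydrolysis); with allostery every edge has its own.
    """
    for st in states:
        if st.index < 0:
            raise ModelError("states must carry canonical indices")
    lookup = {(s.conformation, s.occupancy_I, s.occupancy_II): s for s in states}
    if len(lookup) != len(states):
        raise ModelError("duplicate states")

    transitions: list[Transition] = []

    def add(src: MarkovState, tgt: MarkovState, kind: TransitionKind, base: str, ctx: str) -> None:
        label = f"{base}.{ctx}" if allostery else base
        transitions.append(Transition(src, tgt, kind, label))

    # ligand exchange, open conformation only
    for site_idx, roman in ((0, "I"), (1, "II")):
        for ligand in ("ATP", "ADP"):
            kind = f"bind_{ligand}_{roman}" if ligand == "ATP" else f"bind_ADP_Pi_{roman}"
            for opp in OCC_ORDER:
                occ = ["", ""]
                occ[site_idx] = "apo"
                occ[1 - site_idx] = opp
                src = lookup[("open", occ[0], occ[1])]
                occ[site_idx] = ligand
                tgt = lookup[("open", occ[0], occ[1])]
                add(src, tgt, kind, f"bind_{ligand}_{roman}", _occ_code(opp))
    # conformational change, doubly occupied pairs only
    for occ1 in ("ATP", "ADP"):
        for occ2 in ("ATP", "ADP"):
            src = lookup[("open", occ1, occ2)]
            tgt = lookup[("closed", occ1, occ2)]
            ctx = _occ_code(occ1) + _occ_code(occ2)
            transitions.append(Transition(src, tgt, "conf_change", f"conf_{ctx}"))
    # hydrolysis, closed conformation only
    for site_idx, roman in ((0, "I"), (1, "II")):
        for opp in ("ATP", "ADP"):
            occ = ["", ""]
            occ[site_idx] = "ATP"
            occ[1 - site_idx] = opp
            src = lookup[("closed", occ[0], occ[1])]
            occ[site_idx] = "ADP"
            tgt = lookup[("closed", occ[0], occ[1])]
            add(src, tgt, f"hydrolysis_{roman}", f"hyd_{roman}", _occ_code(opp))

    return transitions


def forward_labels(transitions: Sequence[Transition]) -> list[str]:
    """Distinct forward labels in first-appearance order."""
    seen: dict[str, None] = {}
    for t in transitions:
        seen.setdefault(t.label, None)
    return list(seen)


@dataclass(frozen=True)
class Conditions:
    """Ligand concentrations, temperature and thermodynamic reference."""

    conc_ATP: float = 0.0
    conc_ADP: float = 0.0
    conc_Pi: float = 0.0
    temperature: float = T_REF
    dG_hydrolysis_standard: float = DG0_HYDROLYSIS_KJ_MOL  # kJ/mol

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ModelError("temperature must be positive")
        if min(self.conc_ATP, self.conc_ADP, self.conc_Pi) < 0:
            raise ModelError("concentrations must be nonnegative")


@dataclass
class FreeEnergyParams:
    """Free-energy parameterization of one Markov model.

    ``barriers`` maps every forward label to its barrier ΔG‡ (kT at the
    reference temperature).  Exactly one of ``diffs`` (additive layout:
    7 free-energy differences, 17 parameters total) or ``state_energies``
    (allosteric layout: one energy per state with state 0 fixed at 0,
    32 parameters total) must be given.
    """

    barriers: dict[str, float]
    diffs: dict[str, float] | None = None
    state_energies: np.ndarray | None = None
    ref_temperature: float = T_REF

    def __post_init__(self) -> None:
        if (self.diffs is None) == (self.state_energies is None):
            raise ModelError("exactly one of diffs / state_energies required")
        if self.diffs is not None:
            missing = set(DIFF_KEYS) - set(self.diffs)
            if missing:
                raise ModelError(f"missing free-energy differences: {sorted(missing)}")
        else:
            se = np.asarray(self.state_energies, dtype=float)
            if se.shape != (13,):
                raise ModelError("state_energies must have one entry per state")
            if abs(se[0]) > 1e-12:
                raise ModelError("reference state energy must be 0")
            self.state_energies = se
        if not all(np.isfinite(list(self.barriers.values()))):
            raise ModelError("barriers must be finite")

    @property
    def n_free(self) -> int:
        if self.diffs is not None:
            return len(self.barriers) + len(DIFF_KEYS)
        return len(self.barriers) + 12


def state_free_energy(
    params: FreeEnergyParams, state: MarkovState, conditions: Conditions | None = None
) -> float:
    """Free energy of one state in kT at the evaluation temperature.

    Additive layout: sum of binding free energies of bound ligands, plus
    the conformational offset when closed, with ADP-in-closed states
    booked as ATP-bound plus the site's hydrolysis free-energy difference.
    Chemical-potential terms of the ligand pools live on exchange edges,
    not here.
    """
    temperature = conditions.temperature if conditions is not None else params.ref_temperature
    scale = params.ref_temperature / temperature
    if params.state_energies is not None:
        return float(params.state_energies[state.index]) * scale

    d = params.diffs
    assert d is not None
    g = 0.0
    if state.conformation == "open":
        for occ, roman in ((state.occupancy_I, "I"), (state.occupancy_II, "II")):
            if occ != "apo":
                g += d[f"bind_{occ}_{roman}"]
    else:
        g += d["open_to_closed"]
        for occ, roman in ((state.occupancy_I, "I"), (state.occupancy_II, "II")):
            g += d[f"bind_ATP_{roman}"]
            if occ == "ADP":
                g += d[f"ATP_to_ADP_closed_{roman}"]
    return g * scale


def state_energy_vector(params: FreeEnergyParams, states: Sequence[MarkovState]) -> np.ndarray:
    """State free energies (kT at the reference temperature) as an array."""
    ref = Conditions(temperature=params.ref_temperature)
    return np.array([state_free_energy(params, s, ref) for s in states])


@dataclass(frozen=True)
class MutationSpec:
    """Catalytic-site mutation: hydrolysis knockdown plus affinity shifts.

    ``hydrolysis_reduction_factor`` divides both the hydrolysis (forward)
    and synthesis (backward) coefficients of the mutated site.
    ``affinity_shift[(nucleotide, site)]`` is a change of the binding
    free-energy difference in kT (negative = stronger binding); it scales
    all rate coefficients leaving a state with that nucleotide bound at
    that site toward a different occupancy by exp(shift).
    """

    site: Site
    hydrolysis_reduction_factor: float = 100.0
    affinity_shift: Mapping[tuple[str, Site], float] = field(default_factory=dict)
    variant_tag: Literal["EQ", "EA"] = "EQ"

    def __post_init__(self) -> None:
        if self.hydrolysis_reduction_factor <= 0:
            raise ModelError("reduction factor must be positive")


#: Mutated site per species; the wild type has none.
SPECIES_SITE: dict[str, Site | None] = {"WT": None, "E238Q": "NBSI", "E485Q": "NBSII"}


@dataclass
class RateMatrix:
    """Concentration-folded transition rate matrix with per-edge rates.

    Column convention: ``Q[j, i]`` is the rate coefficient i -> j (1/s),
    ``Q[i, i] = -sum_j Q[j, i]``.  ``kf``/``kb`` hold the forward/backward
    rate of every transition in enumeration order.
    """

    Q: np.ndarray
    kf: np.ndarray
    kb: np.ndarray
    conditions: Conditions


class ModelClass:
    """A state/transition topology plus parameter layout.

    Instances enumerate the 13 states and 20 transitions once and then
    build concrete rate matrices from :class:`FreeEnergyParams` at given
    :class:`Conditions`, optionally applying a mutation.
    """

    def __init__(
        self,
        allostery: bool = False,
        mutation_model: Literal["none", "fixed_factor", "free_factor_and_affinity"] = "fixed_factor",
        reduction_factor: float = 100.0,
        variant_tags: Sequence[str] = ("EQ", "EA"),
    ) -> None:
        self.allostery = bool(allostery)
        if mutation_model not in ("none", "fixed_factor", "free_factor_and_affinity"):
            raise ModelError(f"unknown mutation model {mutation_model!r}")
        self.mutation_model = mutation_model
        self.reduction_factor = float(reduction_factor)
        self.variant_tags = tuple(variant_tags)
        self.states = enumerate_states()
        self.transitions = enumerate_transitions(self.states, allostery)
        self.labels = forward_labels(self.transitions)
        self._label_index = {lab: i for i, lab in enumerate(self.labels)}
        # cached integer topology for vectorized matrix assembly
        self._src = np.array([t.source.index for t in self.transitions])
        self._tgt = np.array([t.target.index for t in self.transitions])
        self._edge_label = np.array([self._label_index[t.label] for t in self.transitions])
        self._is_atp_exchange = np.array(
            [t.kind.startswith("bind_ATP") for t in self.transitions]
        )
        self._is_adp_exchange = np.array([t.is_adp_exchange for t in self.transitions])
        self._is_hyd_I = np.array([t.kind == "hydrolysis_I" for t in self.transitions])
        self._is_hyd_II = np.array([t.kind == "hydrolysis_II" for t in self.transitions])
        # design matrix of the additive layout: G = _diff_design @ diffs
        design = np.zeros((len(self.states), len(DIFF_KEYS)))
        key_idx = {k: i for i, k in enumerate(DIFF_KEYS)}
        for s in self.states:
            if s.conformation == "open":
                for occ, roman in ((s.occupancy_I, "I"), (s.occupancy_II, "II")):
                    if occ != "apo":
                        design[s.index, key_idx[f"bind_{occ}_{roman}"]] = 1.0
            else:
                design[s.index, key_idx["open_to_closed"]] = 1.0
                for occ, roman in ((s.occupancy_I, "I"), (s.occupancy_II, "II")):
                    design[s.index, key_idx[f"bind_ATP_{roman}"]] += 1.0
                    if occ == "ADP":
                        design[s.index, key_idx[f"ATP_to_ADP_closed_{roman}"]] += 1.0
        self._diff_design = design

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def count_free_parameters(self) -> int:
        """Free parameters of the class layout (17 / 32 / 29 / 44)."""
        base = 32 if self.allostery else 17
        if self.mutation_model == "free_factor_and_affinity":
            base += 6 * len(self.variant_tags)
        return base

    def mutation_for_species(
        self, species: str, variant_tag: str = "EQ"
    ) -> MutationSpec | None:
        site = SPECIES_SITE.get(species, "missing")
        if site == "missing":
            raise ModelError(f"unknown species {species!r}")
        if site is None:
            return None
        return MutationSpec(
            site=site,
            hydrolysis_reduction_factor=self.reduction_factor,
            variant_tag=variant_tag,  # type: ignore[arg-type]
        )

    # -- rate-coefficient machinery -------------------------------------

    def _edge_energies(self, params: FreeEnergyParams) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge barrier and free-energy step (kT at reference T).

        The step includes the chemical-work term -ΔG°/kT on ADP+Pi
        exchange edges, making cycle products close to the hydrolysis
        free energy.
        """
        if params.diffs is not None:
            d = np.array([params.diffs[k] for k in DIFF_KEYS])
            g = self._diff_design @ d
        else:
            g = np.asarray(params.state_energies, dtype=float)
        barriers = np.array([params.barriers[lab] for lab in self.labels])
        b_edge = barriers[self._edge_label]
        gdiff = g[self._tgt] - g[self._src]
        w = -dg0_in_kt(params.ref_temperature)  # ΔG° < 0, so w > 0
        gdiff = gdiff + np.where(self._is_adp_exchange, w, 0.0)
        return b_edge, gdiff

    def edge_coefficients(
        self,
        params: FreeEnergyParams,
        conditions: Conditions,
        mutation: MutationSpec | None = None,
        rate_scales: Mapping[tuple[str, str], float] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Concentration-free forward/backward rate coefficients per edge.

        Returns ``(cf, cb)`` such that the forward rate is ``cf * [ATP]``
        for ATP binding, ``cf * [ADP][Pi]`` for product binding and
        ``cf`` otherwise; backward rates are always ``cb``.
        """
        temperature = conditions.temperature
        b_edge, gdiff = self._edge_energies(params)
        if abs(conditions.dG_hydrolysis_standard - DG0_HYDROLYSIS_KJ_MOL) > 1e-12:
            # honour a non-default ΔG° by re-deriving the edge work term
            w_default = -dg0_in_kt(params.ref_temperature)
            w = -conditions.dG_hydrolysis_standard * 1e3 / (
                R_GAS * params.ref_temperature
            )
            gdiff = gdiff + np.where(self._is_adp_exchange, w - w_default, 0.0)
        # rescale energies (fixed in energy units) to the evaluation T
        scale = params.ref_temperature / temperature
        b_edge = b_edge * scale
        gdiff = gdiff * scale
        omega0 = attempt_frequency(temperature)
        cf = omega0 * np.exp(-b_edge)
        cb = omega0 * np.exp(-(b_edge - gdiff))
        if mutation is not None:
            mask = self._is_hyd_I if mutation.site == "NBSI" else self._is_hyd_II
            cf = np.where(mask, cf / mutation.hydrolysis_reduction_factor, cf)
            cb = np.where(mask, cb / mutation.hydrolysis_reduction_factor, cb)
            if mutation.affinity_shift:
                cf, cb = self._apply_affinity_shifts(cf, cb, mutation.affinity_shift)
        if rate_scales:
            for (label, direction), factor in rate_scales.items():
                mask = self._edge_label == self._label_index[label]
                if direction == "f":
                    cf = np.where(mask, cf * factor, cf)
                elif direction == "b":
                    cb = np.where(mask, cb * factor, cb)
                else:
                    raise ModelError("rate-scale direction must be 'f' or 'b'")
        return cf, cb

    def _apply_affinity_shifts(
        self,
        cf: np.ndarray,
        cb: np.ndarray,
        shifts: Mapping[tuple[str, Site], float],
    ) -> tuple[np.ndarray, np.ndarray]:
        """Scale every rate leaving a shifted bound state by exp(shift).

        A shift changes the binding free energy of (nucleotide, site);
        negative values strengthen binding and slow all transitions that
        carry that site away from the bound nucleotide (unbinding, and
        hydrolysis/synthesis at that site).
        """
        cf = cf.copy()
        cb = cb.copy()
        for (nucleotide, site), shift in shifts.items():
            if nucleotide not in ("ATP", "ADP") or site not in SITES:
                raise ModelError(f"unknown affinity-shift key {(nucleotide, site)}")
            factor = math.exp(shift)
            attr = "occupancy_I" if site == "NBSI" else "occupancy_II"
            for e, t in enumerate(self.transitions):
                changes_site = t.site == site and not t.kind == "conf_change"
                if not changes_site:
                    continue
                # forward direction leaves `source`, backward leaves `target`
                if getattr(t.source, attr) == nucleotide:
                    cf[e] *= factor
                if getattr(t.target, attr) == nucleotide:
                    cb[e] *= factor
        return cf, cb

    def assemble(
        self, cf: np.ndarray, cb: np.ndarray, conditions: Conditions
    ) -> RateMatrix:
        """Fold concentrations into the coefficients and build Q."""
        kf = cf * self.concentration_factors(conditions)
        kb = cb
        n = self.n_states
        Q = np.zeros((n, n))
        np.add.at(Q, (self._tgt, self._src), kf)
        np.add.at(Q, (self._src, self._tgt), kb)
        Q[np.diag_indices(n)] -= Q.sum(axis=0)
        return RateMatrix(Q=Q, kf=kf, kb=kb, conditions=conditions)

    def concentration_factors(self, conditions: Conditions) -> np.ndarray:
        """Per-edge forward concentration factor ([ATP], [ADP][Pi], or 1)."""
        return np.where(
            self._is_atp_exchange,
            conditions.conc_ATP,
            np.where(self._is_adp_exchange, conditions.conc_ADP * conditions.conc_Pi, 1.0),
        )

    def build_rate_matrix(
        self,
        params: FreeEnergyParams,
        conditions: Conditions,
        mutation: MutationSpec | None = None,
        rate_scales: Mapping[tuple[str, str], float] | None = None,
    ) -> RateMatrix:
        """Full rate matrix at the given conditions (mutation optional)."""
        cf, cb = self.edge_coefficients(params, conditions, mutation, rate_scales)
        return self.assemble(cf, cb, conditions)

    def build_for_species(
        self,
        params: FreeEnergyParams,
        conditions: Conditions,
        species: str = "WT",
        mutation: MutationSpec | None = None,
    ) -> RateMatrix:
        """Rate matrix for a species, deriving the mutation from the class."""
        if mutation is None:
            mutation = self.mutation_for_species(species)
        return self.build_rate_matrix(params, conditions, mutation)


def count_free_parameters(
    allostery: bool,
    mutation_model: str = "fixed_factor",
    variant_tags: Sequence[str] = ("EQ", "EA"),
) -> int:
    """Parameter count of a class layout: 17, 32, 29 or 44."""
    return ModelClass(
        allostery=allostery, mutation_model=mutation_model, variant_tags=variant_tags
    ).count_free_parameters()


def cycle_ratio_product(
    mc: ModelClass, rm: RateMatrix, cycle_states: Sequence[int]
) -> float:
    """Product of forward/backward rate ratios along a closed state walk.

    ``cycle_states`` lists state indices; the walk closes from the last
    back to the first.  Each step uses the rates in the traversal
    direction.
    """
    edge_of = {}
    for e, t in enumerate(mc.transitions):
        edge_of[(t.source.index, t.target.index)] = (e, +1)
        edge_of[(t.target.index, t.source.index)] = (e, -1)
    prod = 1.0
    seq = list(cycle_states)
    for a, b in zip(seq, seq[1:] + seq[:1]):
        if (a, b) not in edge_of:
            raise ModelError(f"no transition between states {a} and {b}")
        e, sign = edge_of[(a, b)]
        ratio = rm.kf[e] / rm.kb[e] if sign > 0 else rm.kb[e] / rm.kf[e]
        prod *= ratio
    return prod


def equilibrium_conditions(
    conc_ATP: float = 1.0, temperature: float = T_REF
) -> Conditions:
    """Ligand pools at chemical equilibrium: [ADP][Pi]/[ATP] = exp(-ΔG°/RT)."""
    k_eq = math.exp(-dg0_in_kt(temperature))
    c = math.sqrt(k_eq * conc_ATP)
    return Conditions(conc_ATP=conc_ATP, conc_ADP=c, conc_Pi=c, temperature=temperature)


__all__ = [
    "Conditions",
    "DIFF_KEYS",
    "FreeEnergyParams",
    "MarkovState",
    "ModelClass",
    "ModelError",
    "MutationSpec",
    "RateMatrix",
    "SPECIES_SITE",
    "Transition",
    "count_free_parameters",
    "cycle_ratio_product",
    "enumerate_states",
    "enumerate_transitions",
    "equilibrium_conditions",
    "forward_labels",
    "state_free_energy",
    "state_energy_vector",
]
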