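"""Reaction network of the mitochondrial H2O2 clearance system.

The model tracks 28 chemical species coupled by 30 reactions inside a single
well-mixed mitochondrion of a HeLa cell.  Hydrogen peroxide is produced at a
constant rate by oxidative phosphorylation (and optionally by a matrix-targeted
D-amino acid oxidase, DAAO) and is cleared by two peroxiredoxins (Prx3, Prx5),
two glutathione peroxidases (Gpx1, Gpx4) and generic protein thiols.  The
peroxiredoxin disulfides are recycled by thioredoxin-2, the glutathione system
by glutathione/glutaredoxin-2, and both ultimately draw on NADPH, which is
regenerated by a Michaelis-Menten source term.  Prx3 alone can hyperoxidize to
a sulfinic acid (Prx3-SOOH), which is slowly repaired by imported sulfiredoxin
(Srx).

All concentrations are in uM (monomer-equivalents for protein forms), all
times in seconds, all fluxes in uM/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "N_REACTIONS",
    "species_index",
    "RateParameters",
    "Reaction",
    "ReactionSet",
    "default_parameters",
    "default_initial_state",
    "reaction_rates",
    "rhs",
    "jacobian",
    "conserved_pools",
    "PRX3_RANGE_UM",
    "network_document",
]

#: Ordered species names.  The order defines the state-vector layout.
SPECIES: tuple[str, ...] = (
    "H2O2",
    "Prx3-SH", "Prx3-SOH", "Prx3-SS", "Prx3-SOOH",
    "Prx5-SH", "Prx5-SOH", "Prx5-SS",
    "Gpx1red", "Gpx1ox", "Gpx1-SSG",
    "Gpx4red", "Gpx4ox", "Gpx4-SSG",
    "Trx2-SH", "Trx2-SS",
    "GSH", "GSSG",
    "NADPH", "NADP+",
    "Pr-SH", "Pr-SOH", "Pr-SSG",
    "Pr-(SH)2", "Pr-SS",
    "Grx2-SH", "Grx2-SSG",
    "Srx",
)

N_SPECIES = len(SPECIES)
N_REACTIONS = 30

_IX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: Feasible range of the total Prx3 pool per mitochondrion (uM), from the
#: proteomic copy-number conversion (see :mod:`mitoh2o2.units`).
PRX3_RANGE_UM: tuple[float, float] = (48.0, 110.0)


def species_index(name: str) -> int:
    """Return the state-vector index of a species name."""
    try:
        return _IX[name]
    except KeyError:
        raise KeyError(f"unknown species {name!r}; valid names: {SPECIES}") from None


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

_DEFAULT_K = {
    "k1": 4.0,        # uM/s    H2O2 generation by OxPhos
    "k2": 60.0,       # 1/uM/s  Gpx1red + H2O2
    "k3": 0.04,       # 1/uM/s  Gpx1ox + GSH
    "k4": 10.0,       # 1/uM/s  Gpx-SSG + GSH
    "k5": 57.0,       # uM      Michaelis constant of NADPH regeneration
    "k6": 20.0,       # 1/uM/s  Prx3-SH + H2O2
    "k7": 0.014,      # 1/uM/s  Prx3-SOH + H2O2 (hyperoxidation)
    "k8": 3.0e-3,     # 1/uM/s  Prx3-SOOH + Srx (sulfinic-acid repair)
    "k9": 20.0,       # 1/s     Prx3-SOH resolution to disulfide
    "k10": 0.22,      # 1/uM/s  Prx3-SS + Trx2-SH
    "k11": 7.4e-5,    # 1/s     GSH autoxidation
    "k12": 1.0e-4,    # 1/uM/s  Pr-SH + H2O2
    "k13": 0.12,      # 1/uM/s  Pr-SOH + GSH
    "k14": 0.01,      # 1/uM/s  Grx2-SH + Pr-SSG
    "k15": 0.04,      # 1/uM/s  Grx2-SSG + GSH
    "k16": 1.0e-4,    # 1/uM/s  Pr-(SH)2 + H2O2
    "k17": 1.0e-4,    # 1/uM/s  Pr-SS + Trx2-SH
    "k18": 3.2,       # 1/uM/s  GSSG + NADPH
    "k19": 20.0,      # 1/uM/s  Trx2-SS + NADPH
    "k20": 375.0,     # uM/s    maximal NADPH regeneration rate
    "k21": 0.48,      # uM/s    GSH import
    "k22": 9.6e-5,    # 1/s     GSH efflux
    "k23": 0.3,       # 1/uM/s  Prx5-SH + H2O2
    "k24": 14.7,      # 1/s     Prx5-SOH resolution
    "k25": 2.0,       # 1/uM/s  Prx5-SS + Trx2-SH
    "k26": 0.05,      # 1/uM/s  Gpx4red + H2O2
    "k27": 0.02,      # 1/uM/s  Gpx4ox + GSH
    "k28": 0.0,       # uM/s    H2O2 generation by DAAO (kDAAO; perturbation)
    "k29": 1.23e-5,   # uM/s    Srx import
    "k30": 0.0,       # kefflux: H2O2 efflux (uM/s zeroth-order, 1/s first-order)
}

EFFLUX_MODES = ("first_order", "zeroth_order")


@dataclass(frozen=True)
class RateParameters:
    """Rate constants k1..k30 plus the efflux rate-law switch.

    ``k5`` is the Michaelis constant (uM) and ``k20`` the maximal rate (uM/s)
    of the NADPH regeneration term; ``k28`` is the DAAO perturbation source
    (kDAAO, uM/s) and ``k30`` the H2O2 efflux coefficient (kefflux).  In
    ``first_order`` efflux mode (default) the efflux flux is k30*[H2O2] with
    k30 in 1/s; in ``zeroth_order`` mode it is k30*min(1, [H2O2]/efflux_eps)
    with k30 in uM/s, a near-constant sink with a linear cutoff below
    ``efflux_eps`` that preserves nonnegativity.
    """

    k: tuple[float, ...] = tuple(_DEFAULT_K[f"k{i}"] for i in range(1, 31))
    efflux_mode: str = "first_order"
    efflux_eps: float = 1.0e-3  # uM; cutoff scale of the zeroth-order sink

    def __post_init__(self) -> None:
        if len(self.k) != 30:
            raise ValueError("expected exactly 30 rate constants k1..k30")
        if any(ki < 0 for ki in self.k):
            raise ValueError("rate constants must be non-negative")
        if self.efflux_mode not in EFFLUX_MODES:
            raise ValueError(f"efflux_mode must be one of {EFFLUX_MODES}")
        if self.efflux_eps <= 0:
            raise ValueError("efflux_eps must be positive")

    def __getattr__(self, name: str) -> float:
        # attribute access k1..k30
        if name.startswith("k") and name[1:].isdigit():
            i = int(name[1:])
            if 1 <= i <= 30:
                return self.k[i - 1]
        raise AttributeError(name)

    @property
    def kdaao(self) -> float:
        return self.k[27]

    @property
    def kefflux(self) -> float:
        return self.k[29]

    def with_values(self, **overrides: float) -> "RateParameters":
        """Return a copy with named constants (``k1``..``k30``, ``kdaao``,
        ``kefflux``) or the efflux mode replaced."""
        alias = {"kdaao": "k28", "kefflux": "k30"}
        k = list(self.k)
        other: dict[str, object] = {}
        for name, value in overrides.items():
            name = alias.get(name, name)
            if name in ("efflux_mode", "efflux_eps"):
                other[name] = value
            elif name.startswith("k") and name[1:].isdigit() and 1 <= int(name[1:]) <= 30:
                k[int(name[1:]) - 1] = float(value)
            else:
                raise KeyError(f"unknown rate parameter {name!r}")
        return replace(self, k=tuple(k), **other)

    def as_dict(self) -> dict[str, float | str]:
        d: dict[str, float | str] = {f"k{i+1}": self.k[i] for i in range(30)}
        d["efflux_mode"] = self.efflux_mode
        d["efflux_eps"] = self.efflux_eps
        return d


def default_parameters(**overrides: float) -> RateParameters:
    """Literature rate constants; kDAAO and kefflux default to zero."""
    p = RateParameters()
    return p.with_values(**overrides) if overrides else p


# --------------------------------------------------------------------------
# reactions
# --------------------------------------------------------------------------

# rate-law kinds
_ZERO, _UNI, _BI, _MM, _EFFLUX = range(5)


@dataclass(frozen=True)
class Reaction:
    """One reaction: identifier, rate law, signed stoichiometry."""

    rid: str
    name: str
    kind: int               # rate-law kind tag
    k_index: int            # 0-based index into RateParameters.k
    substrates: tuple[int, ...]   # species indices entering the rate law
    stoich: Mapping[str, float]   # species name -> signed coefficient

    def rate(self, state: np.ndarray, params: RateParameters) -> float:
        k = params.k[self.k_index]
        if self.kind == _ZERO:
            return k
        if self.kind == _UNI:
            return k * state[self.substrates[0]]
        if self.kind == _BI:
            return k * state[self.substrates[0]] * state[self.substrates[1]]
        if self.kind == _MM:
            c = state[self.substrates[0]]
            return k * c / (params.k[4] + c)   # k5 is the Michaelis constant
        # efflux
        c = state[self.substrates[0]]
        if params.efflux_mode == "first_order":
            return k * c
        return k * min(1.0, c / params.efflux_eps)


def _r(rid, name, kind, kidx, subs, stoich) -> Reaction:
    return Reaction(rid, name, kind, kidx, tuple(_IX[s] for s in subs),
                    dict(stoich))


def _build_reactions() -> tuple[Reaction, ...]:
    R = [
        _r("R1", "H2O2 generation by OxPhos", _ZERO, 0, (), {"H2O2": +1}),
        _r("R2", "Gpx1 oxidation by H2O2", _BI, 1, ("Gpx1red", "H2O2"),
           {"Gpx1red": -1, "H2O2": -1, "Gpx1ox": +1}),
        _r("R3", "Gpx1ox glutathionylation", _BI, 2, ("Gpx1ox", "GSH"),
           {"Gpx1ox": -1, "GSH": -1, "Gpx1-SSG": +1}),
        _r("R4", "Gpx1-SSG reduction by GSH", _BI, 3, ("Gpx1-SSG", "GSH"),
           {"Gpx1-SSG": -1, "GSH": -1, "Gpx1red": +1, "GSSG": +1}),
        _r("R5", "NADPH regeneration (Michaelis-Menten)", _MM, 19, ("NADP+",),
           {"NADP+": -1, "NADPH": +1}),
        _r("R6", "Prx3 oxidation by H2O2", _BI, 5, ("Prx3-SH", "H2O2"),
           {"Prx3-SH": -1, "H2O2": -1, "Prx3-SOH": +1}),
        _r("R7", "Prx3 hyperoxidation", _BI, 6, ("Prx3-SOH", "H2O2"),
           {"Prx3-SOH": -1, "H2O2": -1, "Prx3-SOOH": +1}),
        _r("R8", "Prx3-SOOH repair by Srx", _BI, 7, ("Prx3-SOOH", "Srx"),
           {"Prx3-SOOH": -1, "Srx": -1, "Prx3-SOH": +1}),
        _r("R9", "Prx3-SOH resolution to disulfide", _UNI, 8, ("Prx3-SOH",),
           {"Prx3-SOH": -1, "Prx3-SS": +1}),
        _r("R10", "Prx3-SS reduction by Trx2", _BI, 9, ("Prx3-SS", "Trx2-SH"),
           {"Prx3-SS": -1, "Trx2-SH": -1, "Prx3-SH": +1, "Trx2-SS": +1}),
        _r("R11", "GSH autoxidation", _UNI, 10, ("GSH",),
           {"GSH": -1, "GSSG": +0.5}),
        _r("R12", "protein thiol oxidation", _BI, 11, ("Pr-SH", "H2O2"),
           {"Pr-SH": -1, "H2O2": -1, "Pr-SOH": +1}),
        _r("R13", "protein sulfenic glutathionylation", _BI, 12, ("Pr-SOH", "GSH"),
           {"Pr-SOH": -1, "GSH": -1, "Pr-SSG": +1}),
        _r("R14", "Pr-SSG reduction by Grx2", _BI, 13, ("Grx2-SH", "Pr-SSG"),
           {"Grx2-SH": -1, "Pr-SSG": -1, "Pr-SH": +1, "Grx2-SSG": +1}),
        _r("R15", "Grx2-SSG reduction by GSH", _BI, 14, ("Grx2-SSG", "GSH"),
           {"Grx2-SSG": -1, "GSH": -1, "Grx2-SH": +1, "GSSG": +1}),
        _r("R16", "protein dithiol oxidation", _BI, 15, ("Pr-(SH)2", "H2O2"),
           {"Pr-(SH)2": -1, "H2O2": -1, "Pr-SS": +1}),
        _r("R17", "Pr-SS reduction by Trx2", _BI, 16, ("Pr-SS", "Trx2-SH"),
           {"Pr-SS": -1, "Trx2-SH": -1, "Pr-(SH)2": +1, "Trx2-SS": +1}),
        _r("R18", "GSSG reduction by NADPH", _BI, 17, ("GSSG", "NADPH"),
           {"GSSG": -1, "NADPH": -1, "GSH": +2, "NADP+": +1}),
        _r("R19", "Trx2-SS reduction by NADPH", _BI, 18, ("Trx2-SS", "NADPH"),
           {"Trx2-SS": -1, "NADPH": -1, "Trx2-SH": +1, "NADP+": +1}),
        # Gpx4-SSG reduction shares the Gpx1-SSG rate constant k4 (no
        # mitochondria-specific value is available; cytosolic equivalent).
        _r("R20", "Gpx4-SSG reduction by GSH", _BI, 3, ("Gpx4-SSG", "GSH"),
           {"Gpx4-SSG": -1, "GSH": -1, "Gpx4red": +1, "GSSG": +1}),
        _r("R21", "GSH import", _ZERO, 20, (), {"GSH": +1}),
        _r("R22", "GSH efflux", _UNI, 21, ("GSH",), {"GSH": -1}),
        _r("R23", "Prx5 oxidation by H2O2", _BI, 22, ("Prx5-SH", "H2O2"),
           {"Prx5-SH": -1, "H2O2": -1, "Prx5-SOH": +1}),
        _r("R24", "Prx5-SOH resolution", _UNI, 23, ("Prx5-SOH",),
           {"Prx5-SOH": -1, "Prx5-SS": +1}),
        _r("R25", "Prx5-SS reduction by Trx2", _BI, 24, ("Prx5-SS", "Trx2-SH"),
           {"Prx5-SS": -1, "Trx2-SH": -1, "Prx5-SH": +1, "Trx2-SS": +1}),
        _r("R26", "Gpx4 oxidation by H2O2", _BI, 25, ("Gpx4red", "H2O2"),
           {"Gpx4red": -1, "H2O2": -1, "Gpx4ox": +1}),
        _r("R27", "Gpx4ox glutathionylation", _BI, 26, ("Gpx4ox", "GSH"),
           {"Gpx4ox": -1, "GSH": -1, "Gpx4-SSG": +1}),
        _r("R28", "H2O2 generation by DAAO", _ZERO, 27, (), {"H2O2": +1}),
        _r("R29", "Srx import", _ZERO, 28, (), {"Srx": +1}),
        _r("R30", "H2O2 efflux to cytosol", _EFFLUX, 29, ("H2O2",),
           {"H2O2": -1}),
    ]
    assert len(R) == N_REACTIONS
    return tuple(R)


class ReactionSet:
    """The 30 reactions with a compiled fast path for fluxes and Jacobian."""

    def __init__(self, reactions: Sequence[Reaction] | None = None):
        self.reactions: tuple[Reaction, ...] = (
            tuple(reactions) if reactions is not None else _build_reactions()
        )
        if len(self.reactions) != N_REACTIONS:
            raise ValueError(f"expected {N_REACTIONS} reactions")
        # stoichiometry matrix S (species x reactions)
        S = np.zeros((N_SPECIES, len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sp, coef in rxn.stoich.items():
                S[_IX[sp], j] = coef
        self.S = S

    def fluxes(self, state: np.ndarray, params: RateParameters) -> np.ndarray:
        """Reaction rates (uM/s), in reaction order."""
        v = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            v[j] = rxn.rate(state, params)
        return v

    def flux_jacobian(self, state: np.ndarray, params: RateParameters) -> np.ndarray:
        """d(flux_j)/d(C_i) as a (reactions x species) matrix."""
        J = np.zeros((len(self.reactions), N_SPECIES))
        for j, rxn in enumerate(self.reactions):
            k = params.k[rxn.k_index]
            if rxn.kind == _UNI:
                J[j, rxn.substrates[0]] = k
            elif rxn.kind == _BI:
                a, b = rxn.substrates
                J[j, a] = k * state[b]
                J[j, b] += k * state[a]
            elif rxn.kind == _MM:
                a = rxn.substrates[0]
                km = params.k[4]
                J[j, a] = k * km / (km + state[a]) ** 2
            elif rxn.kind == _EFFLUX:
                a = rxn.substrates[0]
                if params.efflux_mode == "first_order":
                    J[j, a] = k
                elif state[a] < params.efflux_eps:
                    J[j, a] = k / params.efflux_eps
        return J


_DEFAULT_NETWORK = ReactionSet()


# --------------------------------------------------------------------------
# initial state
# --------------------------------------------------------------------------

# Measured / literature abundances (uM).
_TABLE2 = {
    "Prx5-SH": 14.0,
    "Gpx1red": 1.5e-2,
    "Gpx4red": 0.23,
    "Grx2-SH": 1.0,
    "Trx2-SH": 7.7,
    "Trx2-SS": 0.075,
    "GSH": 5.0e3,
    "GSSG": 1.78,
    "NADPH": 30.0,
    "NADP+": 0.03,
    "Pr-SH": 1.0e-3,
    "Pr-(SH)2": 1.09e3,
    "Srx": 8.8e-3,
}

# Midpoints of the derived-abundance ranges (basal oxidized forms).
_TABLE3_MID = {
    "H2O2": 3.0e-3,
    "Prx3-SOH": 0.19,
    "Prx3-SS": 2.25,
    "Prx3-SOOH": 0.305,
    "Prx5-SOH": 7.5e-4,
    "Prx5-SS": 7.5e-4,
    "Gpx1ox": 1.4e-5,
    "Gpx1-SSG": 5.0e-8,
    "Gpx4ox": 0.0,
    "Gpx4-SSG": 0.0,
    "Grx2-SSG": 1.0e-16,
    "Pr-SOH": 4.5e-13,
    "Pr-SSG": 2.0e-8,
    "Pr-SS": 0.425,
}


def default_initial_state(
    prx3_total: float = 62.0,
    policy: str = "zeros",
    allow_out_of_range: bool = False,
) -> np.ndarray:
    """Initial species vector for a given total Prx3 pool (uM).

    ``policy='zeros'`` (default) puts the whole Prx3 pool in the reduced form
    and all derived oxidized species at zero; the network relaxes to its basal
    steady state in well under a second.  ``policy='table'`` instead seeds the
    oxidized forms at the midpoints of their derived basal ranges, carving them
    out of the same total pool so both policies relax to the same steady state.
    """
    lo, hi = PRX3_RANGE_UM
    if not allow_out_of_range and not (lo <= prx3_total <= hi):
        raise ValueError(
            f"prx3_total={prx3_total} uM outside the feasible range "
            f"[{lo}, {hi}] uM; pass allow_out_of_range=True to override"
        )
    y = np.zeros(N_SPECIES)
    for sp, c in _TABLE2.items():
        y[_IX[sp]] = c
    if policy == "zeros":
        y[_IX["Prx3-SH"]] = prx3_total
    elif policy == "table":
        for sp, c in _TABLE3_MID.items():
            y[_IX[sp]] = c
        oxidized = sum(_TABLE3_MID[s] for s in ("Prx3-SOH", "Prx3-SS", "Prx3-SOOH"))
        if prx3_total <= oxidized:
            raise ValueError("prx3_total smaller than the seeded oxidized forms")
        y[_IX["Prx3-SH"]] = prx3_total - oxidized
        # keep the Prx5 pool at its printed total as well
        y[_IX["Prx5-SH"]] = _TABLE2["Prx5-SH"] - (
            _TABLE3_MID["Prx5-SOH"] + _TABLE3_MID["Prx5-SS"]
        )
        y[_IX["Gpx1red"]] = _TABLE2["Gpx1red"] - (
            _TABLE3_MID["Gpx1ox"] + _TABLE3_MID["Gpx1-SSG"]
        )
        y[_IX["Pr-(SH)2"]] = _TABLE2["Pr-(SH)2"] - _TABLE3_MID["Pr-SS"]
    else:
        raise ValueError("policy must be 'zeros' or 'table'")
    return y


# --------------------------------------------------------------------------
# ODE right-hand side
# --------------------------------------------------------------------------

def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},)")
    if np.any(state < 0):
        bad = [SPECIES[i] for i in np.where(state < 0)[0]]
        raise ValueError(f"negative concentrations for {bad}")
    return state


def reaction_rates(
    state: np.ndarray,
    params: RateParameters,
    network: ReactionSet = _DEFAULT_NETWORK,
) -> np.ndarray:
    """The 30 reaction fluxes (uM/s) at a (non-negative) state."""
    return network.fluxes(_check_state(state), params)


def rhs(
    state: np.ndarray,
    params: RateParameters,
    network: ReactionSet = _DEFAULT_NETWORK,
) -> np.ndarray:
    """dC/dt (uM/s): stoichiometry-weighted sum of the reaction fluxes."""
    return network.S @ reaction_rates(state, params, network)


def rhs_unchecked(
    state: np.ndarray,
    params: RateParameters,
    network: ReactionSet = _DEFAULT_NETWORK,
) -> np.ndarray:
    """As :func:`rhs` but tolerating the tiny negative excursions a stiff
    integrator may probe; for solver callbacks only."""
    return network.S @ network.fluxes(state, params)


def jacobian(
    state: np.ndarray,
    params: RateParameters,
    network: ReactionSet = _DEFAULT_NETWORK,
) -> np.ndarray:
    """Analytic Jacobian d(rhs)/d(state), (species x species)."""
    return network.S @ network.flux_jacobian(state, params)


# --------------------------------------------------------------------------
# conserved pools
# --------------------------------------------------------------------------

#: Closed protein / cofactor pools (name -> member species).  Each is exactly
#: conserved by the stoichiometry; trajectories may only drift by integrator
#: error.
CONSERVED_POOLS: dict[str, tuple[str, ...]] = {
    "Prx3": ("Prx3-SH", "Prx3-SOH", "Prx3-SS", "Prx3-SOOH"),
    "Prx5": ("Prx5-SH", "Prx5-SOH", "Prx5-SS"),
    "Gpx1": ("Gpx1red", "Gpx1ox", "Gpx1-SSG"),
    "Gpx4": ("Gpx4red", "Gpx4ox", "Gpx4-SSG"),
    "Trx2": ("Trx2-SH", "Trx2-SS"),
    "Grx2": ("Grx2-SH", "Grx2-SSG"),
    "NADP(H)": ("NADPH", "NADP+"),
}


def conserved_pools(state: np.ndarray) -> dict[str, float]:
    """Totals of the closed pools at one state."""
    state = np.asarray(state, dtype=float)
    return {
        name: float(sum(state[_IX[s]] for s in members))
        for name, members in CONSERVED_POOLS.items()
    }


def glutathione_total(state: np.ndarray) -> float:
    """Total glutathione equivalents: GSH + 2*GSSG + glutathionylated forms."""
    state = np.asarray(state, dtype=float)
    ssg = ("Gpx1-SSG", "Gpx4-SSG", "Pr-SSG", "Grx2-SSG")
    return float(
        state[_IX["GSH"]]
        + 2.0 * state[_IX["GSSG"]]
        + sum(state[_IX[s]] for s in ssg)
    )


# --------------------------------------------------------------------------
# structured export
# --------------------------------------------------------------------------

def network_document(
    params: RateParameters | None = None,
    network: ReactionSet = _DEFAULT_NETWORK,
) -> dict:
    """Model definition (species, parameters, reactions) as plain data,
    suitable for YAML/JSON serialization."""
    params = params or default_parameters()
    return {
        "species": list(SPECIES),
        "parameters": params.as_dict(),
        "reactions": [
            {
                "id": rxn.rid,
                "name": rxn.name,
                "rate_constant": f"k{rxn.k_index + 1}",
                "substrates": [SPECIES[i] for i in rxn.substrates],
                "stoichiometry": dict(rxn.stoich),
            }
            for rxn in network.reactions
        ],
    }
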