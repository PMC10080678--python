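"""Schematic formose-like reaction network in a CSTR under a dynamic input.

This is the package's synthetic-data generator.  It does not attempt to
reproduce measured formose kinetics (no rate constants for the real
network are published); instead it reproduces the *structure* the
downstream analyses assume: an autocatalytic Breslow-cycle engine
(formaldehyde + glycolaldehyde -> trioses -> tetroses -> 2x
glycolaldehyde, with DHA entering by isomerisation) feeding five
measured compound families, each reached through gating steps whose
catalyst response stamps a distinctive temporal signature (sign,
bandwidth, lag) on the whole family, so that environmental Ca(OH)2
fluctuations transfer non-uniformly into the 28 measured traces.

Catalysis is modelled as a power law: a reaction with sensitivity ``s``
runs at ``k * (ca / ca_ref)**s`` where ``ca`` is the *reactor*
catalyst-proxy concentration.  The proxy is carried as a non-consumed
species with its own CSTR mass balance, so the reactor itself low-pass
filters the applied input with time constant tau before any chemistry
sees it.  Enolate intermediates are folded into effective gating rate
laws; unmeasured pool species stand in for slow off-cycle reservoirs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .flow_program import FlowProgram

__all__ = [
    "ModelError",
    "IntegrationError",
    "Species",
    "Reaction",
    "NetworkModel",
    "TraceSet",
    "build_formose_model",
    "effective_rate",
    "simulate_cstr",
    "sample_outlet",
]

MODULES = ("core", "II", "III", "IV", "V", "none")

#: species id used for the catalyst proxy
CATALYST = "CA"


class ModelError(ValueError):
    """Malformed network model."""


class IntegrationError(RuntimeError):
    """ODE solver failed to converge."""


@dataclass(frozen=True)
class Species:
    id: str
    carbon_count: int
    module_label: str = "none"
    intermediate: bool = False  # unmeasured pool / proxy species

    def __post_init__(self):
        if self.module_label not in MODULES:
            raise ModelError(f"unknown module label {self.module_label!r}")


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction with a power-law catalyst modulation."""

    id: str
    reactants: tuple[tuple[str, int], ...]  # (species id, stoichiometry)
    products: tuple[tuple[str, int], ...]
    k: float
    catalyst_sensitivity: float = 0.0

    def __post_init__(self):
        if self.k < 0:
            raise ModelError(f"{self.id}: negative rate constant")
        if self.catalyst_sensitivity < 0:
            raise ModelError(f"{self.id}: negative catalyst sensitivity")


@dataclass
class NetworkModel:
    species: list[Species]
    reactions: list[Reaction]
    catalyst_reference: float = 15.0  # mM

    def __post_init__(self):
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate species ids")
        if self.catalyst_reference <= 0:
            raise ModelError("catalyst_reference must be positive")
        self._index = {s.id: i for i, s in enumerate(self.species)}
        carbons = {s.id: s.carbon_count for s in self.species}
        for r in self.reactions:
            for sid, _ in r.reactants + r.products:
                if sid not in self._index:
                    raise ModelError(f"{r.id}: unknown species {sid!r}")
            lhs = sum(carbons[sid] * nu for sid, nu in r.reactants)
            rhs = sum(carbons[sid] * nu for sid, nu in r.products)
            if lhs != rhs:
                raise ModelError(
                    f"{r.id}: carbon not conserved ({lhs} -> {rhs})"
                )
        labels = {s.module_label for s in self.species if not s.intermediate
                  and s.module_label != "none"}
        if labels and len(labels) < 2:
            raise ModelError("module labels must partition measured species into >= 2 groups")

    def index(self, species_id: str) -> int:
        return self._index[species_id]

    @property
    def measured_ids(self) -> list[str]:
        return [s.id for s in self.species
                if not s.intermediate and s.module_label != "none"]

    @property
    def module_of(self) -> dict[str, str]:
        return {s.id: s.module_label for s in self.species}

    def to_dict(self) -> dict:
        return {
            "catalyst_reference": self.catalyst_reference,
            "species": [
                {"id": s.id, "carbon_count": s.carbon_count,
                 "module_label": s.module_label, "intermediate": s.intermediate}
                for s in self.species
            ],
            "reactions": [
                {"id": r.id,
                 "reactants": [[sid, nu] for sid, nu in r.reactants],
                 "products": [[sid, nu] for sid, nu in r.products],
                 "k": r.k, "catalyst_sensitivity": r.catalyst_sensitivity}
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        species = [Species(**s) for s in d["species"]]
        reactions = [
            Reaction(
                id=r["id"],
                reactants=tuple((sid, int(nu)) for sid, nu in r["reactants"]),
                products=tuple((sid, int(nu)) for sid, nu in r["products"]),
                k=float(r["k"]),
                catalyst_sensitivity=float(r.get("catalyst_sensitivity", 0.0)),
            )
            for r in d["reactions"]
        ]
        return cls(species=species, reactions=reactions,
                   catalyst_reference=float(d.get("catalyst_reference", 15.0)))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class TraceSet:
    """Time axis plus a compound-by-time concentration matrix (mM)."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_compounds, n_times)
    compound_ids: list[str]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.concentrations.shape != (len(self.compound_ids), self.times.size):
            raise ValueError("concentration matrix shape mismatch")
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentrations in TraceSet")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def trace(self, compound_id: str) -> np.ndarray:
        return self.concentrations[self.compound_ids.index(compound_id)]

    def select(self, ids: list[str]) -> "TraceSet":
        rows = [self.compound_ids.index(i) for i in ids]
        return TraceSet(self.times.copy(), self.concentrations[rows].copy(), list(ids))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.concentrations.T, columns=self.compound_ids)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df) -> "TraceSet":
        if df.columns[0] != "time_s":
            raise ValueError("first column must be time_s")
        ids = list(df.columns[1:])
        return cls(df["time_s"].to_numpy(), df[ids].to_numpy().T, ids)

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        import pandas as pd

        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# default network topology


DEFAULT_SENSITIVITIES = {
    "core": 1.0,  # Breslow-cycle enolate steps (aldols, retro-aldol)
    "II": 0.5,    # formaldehyde + triose-enolate gate into the C4 pool
    "III": 0.0,   # formaldehyde oligomerisation ladder (uncatalysed; its
                  # response is inherited from the catalyst-depleted C1 pool)
    "IV": 2.0,    # catalysed retro-aldol: drains the off-cycle hexose pool
                  # behind cluster II and degrades the cluster-IV ketoses
    "V": 2.0,     # catalysed DHA self-aldol filling the slow oligomer relay
                  # behind clusters IV and V
}

DEFAULT_RATES = {
    # Breslow-cycle engine
    "ald_C1_G2": 4.0e-3, "ald_C1_G3": 3.0e-3, "retro_T4": 4.0e-2,
    "iso_DHA_G3": 2.0e-3, "iso_G3_DHA": 1.0e-3,
    # cluster II: tetrose/tetrulose isomer pool (enolate exchange)
    "iso_T4_K4": 5.0e-2, "iso_K4_T4": 4.0e-2, "iso_E4": 5.0e-2,
    "ald_Pb2_G2": 3.0e-3, "deg_M": 1.0e-2, "iso_M": 2.0e-1,
    # cluster I adducts of the glycolaldehyde pool
    "dim_G2": 1.0e-2, "ald_G2_Q4": 5.0e-3, "ald_G2_G3": 5.0e-3,
    "sink_Q": 1.0e-2, "iso_Q": 2.0e-1,
    # cluster III: formaldehyde ladder
    "dim_C1": 4.0e-5, "ext_F": 1.5e-3, "sink_F4": 3.0e-2, "iso_F": 2.0e-1,
    # slow catalyst-drained hexose pool feeding clusters II and IV
    "dim_DHA_b": 4.0e-5, "deg_Pb1": 4.0e-3, "conv_Pb": 3.0e-3,
    # cluster IV: catalyst-labile C9 ketoses off the slow oligomer pool
    "ald_Pw1_DHA": 2.0e-4, "deg_X": 1.0e-2, "iso_X": 2.0e-1,
    # cluster V: catalysed DHA self-aldol through two slow oligomer pools
    "dim_DHA_w": 8.0e-5, "conv_Pw0": 3.0e-3, "conv_Pw1": 4.0e-3,
    "ald_Pw2_DHA": 5.0e-4,
    "deg_W": 3.0e-3, "iso_W": 2.0e-1,
}


def build_formose_model(config: dict | None = None) -> NetworkModel:
    """Construct the default gated formose-like network.

    ``config`` may override ``sensitivities`` (per module), individual
    ``rates`` (by rate key), and ``catalyst_reference``.

    The default topology couples a Breslow-cycle engine (formaldehyde +
    glycolaldehyde -> glyceraldehyde -> tetrose pool -> 2x
    glycolaldehyde, with the DHA feed entering by triose isomerisation)
    to five measured compound families, each reached through one or two
    "gating" steps whose catalyst response stamps a distinctive temporal
    signature on the whole family:

    * core (I): aldol adducts Q4-Q6 of the glycolaldehyde pool — track
      the catalyst positively with fast relaxation.
    * II: C8 ketoses (M8a-e) from aldol addition of glycolaldehyde to a
      slow off-cycle hexose pool drained by catalysed retro-aldol — a
      negative, deeply lagged response partially offset by the positive
      glycolaldehyde term.
    * III: the formaldehyde oligomerisation ladder F2-F4 (uncatalysed)
      — inherits the catalyst-depleted formaldehyde pool (negative,
      fast).
    * IV: C9 ketoses (X9a-f) formed by DHA addition onto the first slow
      oligomer pool but degraded by catalysed retro-aldol — a lagged
      positive source opposed by an instantaneous negative drain.
    * V: C9 ketoses (W9a-f) fed through a three-stage slow oligomer
      relay filled by catalysed DHA self-aldol — a positive, deeply
      lagged response.

    28 measured compounds in total, 5-6 per family, plus the feeds
    (C1, DHA) and the catalyst proxy, which are not measured.
    """
    config = config or {}
    sens = dict(DEFAULT_SENSITIVITIES, **config.get("sensitivities", {}))
    rates = dict(DEFAULT_RATES, **config.get("rates", {}))
    for key in sens:
        if key not in DEFAULT_SENSITIVITIES:
            raise ModelError(f"unknown sensitivity key {key!r}")
        if sens[key] < 0:
            raise ModelError(f"sensitivity for {key!r} must be >= 0")
    for key in rates:
        if key not in DEFAULT_RATES:
            raise ModelError(f"unknown rate key {key!r}")

    species = [
        Species("C1", 1, "none"),            # formaldehyde feed
        Species("DHA", 3, "none"),           # dihydroxyacetone feed
        Species(CATALYST, 0, "none", intermediate=True),  # Ca(OH)2 proxy
        Species("G2", 2, "none"),            # glycolaldehyde (engine)
        Species("G3", 3, "none"),            # glyceraldehyde (engine)
        Species("Q4", 4, "core"),            # glycolaldehyde dimer
        Species("Q4b", 4, "core"),           # its isomer
        Species("Q5", 5, "core"),            # G2 + G3 aldol adduct
        Species("Q6", 6, "core"),            # G2 + Q4 aldol adduct
        Species("Q6b", 6, "core"),           # its isomer
        Species("T4", 4, "none"),            # tetrose (engine)
        Species("K4", 4, "none"),            # tetrulose (engine)
        Species("E4a", 4, "none"),           # C4 isomers via enolate exchange
        Species("E4b", 4, "none"),
        Species("E4c", 4, "none"),
        Species("Pb1", 6, "none", intermediate=True),  # branch-IV slow pools
        Species("Pb2", 6, "none", intermediate=True),
        Species("Pw0", 6, "none", intermediate=True),  # branch-V slow pools
        Species("Pw1", 6, "none", intermediate=True),
        Species("Pw2", 6, "none", intermediate=True),
    ]
    species += [Species(f"M8{t}", 8, "II") for t in ("", "b", "c", "d", "e")]
    species += [Species(f"F{c}{t}", c, "III")
                for c in (2, 3, 4) for t in ("", "b")]
    species += [Species(f"X9{t}", 9, "IV") for t in ("", "b", "c", "d", "e", "f")]
    species += [Species(f"W9{t}", 9, "V") for t in ("", "b", "c", "d", "e", "f")]

    s_core, s2, s3, s4, s5 = (sens[m] for m in ("core", "II", "III", "IV", "V"))
    R = Reaction

    def iso_pair(rid, a, b, k, s):
        return [R(f"{rid}", ((a, 1),), ((b, 1),), k, s),
                R(f"{rid}_r", ((b, 1),), ((a, 1),), k, s)]

    reactions = [
        # Breslow-cycle engine; ald_C1_G3 is the gate into the C4 pool (II)
        R("ald_C1_G2", (("C1", 1), ("G2", 1)), (("G3", 1),), rates["ald_C1_G2"], s_core),
        R("ald_C1_G3", (("C1", 1), ("G3", 1)), (("T4", 1),), rates["ald_C1_G3"], s2),
        R("retro_T4", (("T4", 1),), (("G2", 2),), rates["retro_T4"], s_core),
        R("iso_DHA_G3", (("DHA", 1),), (("G3", 1),), rates["iso_DHA_G3"], 0.0),
        R("iso_G3_DHA", (("G3", 1),), (("DHA", 1),), rates["iso_G3_DHA"], 0.0),
        # cluster II: enolate-mediated C4 pool exchange
        R("iso_T4_K4", (("T4", 1),), (("K4", 1),), rates["iso_T4_K4"], 0.0),
        R("iso_K4_T4", (("K4", 1),), (("T4", 1),), rates["iso_K4_T4"], 0.0),
        *iso_pair("iso_T4_E4a", "T4", "E4a", rates["iso_E4"], 0.0),
        *iso_pair("iso_K4_E4b", "K4", "E4b", rates["iso_E4"], 0.0),
        *iso_pair("iso_E4a_E4c", "E4a", "E4c", rates["iso_E4"], 0.0),
        # cluster II: C8 ketoses from aldol of glycolaldehyde with the slow
        # hexose pool — the positive G2 term offsets the lagged negative
        # pool term, rotating the family off both axes
        R("ald_Pb2_G2", (("Pb2", 1), ("G2", 1)), (("M8", 1),), rates["ald_Pb2_G2"], 0.0),
        R("deg_M8", (("M8", 1),), (("G3", 2), ("G2", 1)), rates["deg_M"], 0.0),
        *iso_pair("iso_M8_b", "M8", "M8b", rates["iso_M"], 0.0),
        *iso_pair("iso_M8_c", "M8", "M8c", rates["iso_M"], 0.0),
        *iso_pair("iso_M8_d", "M8", "M8d", rates["iso_M"], 0.0),
        *iso_pair("iso_M8_e", "M8", "M8e", rates["iso_M"], 0.0),
        # cluster I: aldol adducts of glycolaldehyde (uncatalysed, reversible)
        R("dim_G2", (("G2", 2),), (("Q4", 1),), rates["dim_G2"], 0.0),
        R("sink_Q4", (("Q4", 1),), (("G2", 2),), rates["sink_Q"], 0.0),
        *iso_pair("iso_Q4", "Q4", "Q4b", rates["iso_Q"], 0.0),
        R("ald_G2_G3", (("G2", 1), ("G3", 1)), (("Q5", 1),), rates["ald_G2_G3"], 0.0),
        R("sink_Q5", (("Q5", 1),), (("G2", 1), ("G3", 1)), rates["sink_Q"], 0.0),
        R("ald_G2_Q4", (("G2", 1), ("Q4", 1)), (("Q6", 1),), rates["ald_G2_Q4"], 0.0),
        R("sink_Q6", (("Q6", 1),), (("G2", 1), ("Q4", 1)), rates["sink_Q"], 0.0),
        *iso_pair("iso_Q6", "Q6", "Q6b", rates["iso_Q"], 0.0),
        # cluster III: formaldehyde oligomerisation ladder
        R("dim_C1", (("C1", 2),), (("F2", 1),), rates["dim_C1"], s3),
        *iso_pair("iso_F2", "F2", "F2b", rates["iso_F"], 0.0),
        R("ext_F2", (("C1", 1), ("F2", 1)), (("F3", 1),), rates["ext_F"], s3),
        *iso_pair("iso_F3", "F3", "F3b", rates["iso_F"], 0.0),
        R("ext_F3", (("C1", 1), ("F3", 1)), (("F4", 1),), rates["ext_F"], s3),
        *iso_pair("iso_F4", "F4", "F4b", rates["iso_F"], 0.0),
        R("sink_F4", (("F4", 1),), (("T4", 1),), rates["sink_F4"], 0.0),
        # slow hexose pool drained by catalysed retro-aldol (feeds II and IV)
        R("dim_DHA_b", (("DHA", 2),), (("Pb1", 1),), rates["dim_DHA_b"], 0.0),
        R("deg_Pb1", (("Pb1", 1),), (("DHA", 2),), rates["deg_Pb1"], s4),
        R("conv_Pb", (("Pb1", 1),), (("Pb2", 1),), rates["conv_Pb"], 0.0),
        # cluster IV: C9 ketoses formed by DHA addition onto the first slow
        # oligomer pool but degraded by catalysed retro-aldol — a lagged
        # positive source opposed by an instantaneous negative drain
        R("ald_Pw1_DHA", (("Pw1", 1), ("DHA", 1)), (("X9", 1),),
          rates["ald_Pw1_DHA"], 0.0),
        *[R(f"deg_X9{t or '_a'}", ((f"X9{t}", 1),), (("DHA", 3),),
            rates["deg_X"], s4) for t in ("", "b", "c", "d", "e", "f")],
        *iso_pair("iso_X9_b", "X9", "X9b", rates["iso_X"], 0.0),
        *iso_pair("iso_X9_c", "X9", "X9c", rates["iso_X"], 0.0),
        *iso_pair("iso_X9_d", "X9", "X9d", rates["iso_X"], 0.0),
        *iso_pair("iso_X9_e", "X9", "X9e", rates["iso_X"], 0.0),
        *iso_pair("iso_X9_f", "X9", "X9f", rates["iso_X"], 0.0),
        # cluster V: catalysed DHA self-aldol relayed through two slow pools,
        # then extended by DHA into the C9 isomer family
        R("dim_DHA_w", (("DHA", 2),), (("Pw0", 1),), rates["dim_DHA_w"], s5),
        R("conv_Pw0", (("Pw0", 1),), (("Pw1", 1),), rates["conv_Pw0"], 0.0),
        R("conv_Pw1", (("Pw1", 1),), (("Pw2", 1),), rates["conv_Pw1"], 0.0),
        R("ald_Pw2_DHA", (("Pw2", 1), ("DHA", 1)), (("W9", 1),), rates["ald_Pw2_DHA"], 0.0),
        R("deg_W9", (("W9", 1),), (("DHA", 3),), rates["deg_W"], 0.0),
        *iso_pair("iso_W9_b", "W9", "W9b", rates["iso_W"], 0.0),
        *iso_pair("iso_W9_c", "W9", "W9c", rates["iso_W"], 0.0),
        *iso_pair("iso_W9_d", "W9", "W9d", rates["iso_W"], 0.0),
        *iso_pair("iso_W9_e", "W9", "W9e", rates["iso_W"], 0.0),
        *iso_pair("iso_W9_f", "W9", "W9f", rates["iso_W"], 0.0),
    ]
    return NetworkModel(
        species=species,
        reactions=reactions,
        catalyst_reference=float(config.get("catalyst_reference", 15.0)),
    )


def effective_rate(k: float, ca: float, sensitivity: float,
                   catalyst_reference: float) -> float:
    """Power-law catalyst modulation ``k * (ca / ref) ** s``."""
    if ca < 0:
        raise ModelError("catalyst concentration must be non-negative")
    if catalyst_reference <= 0:
        raise ModelError("catalyst_reference must be positive")
    if sensitivity == 0:
        return k
    return k * (ca / catalyst_reference) ** sensitivity


# ---------------------------------------------------------------------------
# CSTR integration


class _CompiledModel:
    """Index arrays for a fast vectorised mass-action right-hand side."""

    def __init__(self, model: NetworkModel):
        n = len(model.species)
        m = len(model.reactions)
        self.n, self.m = n, m
        self.k = np.array([r.k for r in model.reactions])
        self.s = np.array([r.catalyst_sensitivity for r in model.reactions])
        self.stoich = np.zeros((n, m))
        # up to two reactant slots with integer orders; slot 2 may be empty
        self.r1 = np.zeros(m, dtype=int)
        self.o1 = np.zeros(m)
        self.r2 = np.zeros(m, dtype=int)
        self.o2 = np.zeros(m)
        for j, r in enumerate(model.reactions):
            if not 1 <= len(r.reactants) <= 2:
                raise ModelError(f"{r.id}: only 1-2 distinct reactants supported")
            (sid1, nu1), *rest = r.reactants
            self.r1[j], self.o1[j] = model.index(sid1), nu1
            self.stoich[model.index(sid1), j] -= nu1
            if rest:
                sid2, nu2 = rest[0]
                self.r2[j], self.o2[j] = model.index(sid2), nu2
                self.stoich[model.index(sid2), j] -= nu2
            else:
                self.r2[j], self.o2[j] = model.index(sid1), 0.0
            for sid, nu in r.products:
                self.stoich[model.index(sid), j] += nu
        self.ca_idx = model.index(CATALYST)
        self.ca_ref = model.catalyst_reference

    def rhs(self, inv_tau: float, c_in: np.ndarray):
        stoich, k, s = self.stoich, self.k, self.s
        r1, o1, r2, o2, ca_idx, ca_ref = (
            self.r1, self.o1, self.r2, self.o2, self.ca_idx, self.ca_ref)

        def f(t, c):
            cp = np.maximum(c, 0.0)
            ratio = cp[ca_idx] / ca_ref
            rates = k * ratio ** s * cp[r1] ** o1 * cp[r2] ** o2
            return inv_tau * (c_in - c) + stoich @ rates

        return f


def simulate_cstr(
    model: NetworkModel,
    flows: FlowProgram,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    initial: dict[str, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> TraceSet:
    """Integrate the CSTR mass balance driven by a flow program.

    dC_i/dt = (C_in,i(t) - C_i)/tau + sum_r nu_ir * rate_r(C, ca)

    The flow program's step boundaries partition time; each segment has
    constant inlet concentrations and is integrated separately so the
    solver never smooths across a step discontinuity.  Output is
    evaluated on ``t_eval`` (default: a 2-s grid over ``t_span``).
    Concentrations are clamped at zero within solver tolerance.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    ca_sig = flows.ca_inlet
    if t0 < ca_sig.step_times[0] - 1e-9 or t1 > ca_sig.end_time + 1e-9:
        raise IntegrationError("flow program does not cover the requested t_span")
    if t_eval is None:
        t_eval = np.arange(t0, t1, 2.0)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size == 0 or t_eval[0] < t0 - 1e-9 or t_eval[-1] > t1 + 1e-9:
        raise IntegrationError("t_eval must lie within t_span")

    compiled = _CompiledModel(model)
    tau = flows.reactor.residence_time_s
    ids = [s.id for s in model.species]
    c = np.zeros(len(ids))
    if initial:
        for sid, v in initial.items():
            c[model.index(sid)] = v

    # inlet concentration vector per step (constant within a segment);
    # feed species that the model does not carry are simply not fed
    c_in_base = np.zeros(len(ids))
    for sid, c_in in (("C1", flows.inlet.formaldehyde_in),
                      ("DHA", flows.inlet.dha_in)):
        if sid in model._index:
            c_in_base[model.index(sid)] = c_in
    ca_steps = ca_sig.values

    edges = ca_sig.boundaries()
    cut = np.unique(np.clip(edges, t0, t1))
    if cut[0] > t0:
        cut = np.insert(cut, 0, t0)
    if cut[-1] < t1:
        cut = np.append(cut, t1)

    out = np.empty((len(ids), t_eval.size))
    filled = 0
    for a, b in zip(cut[:-1], cut[1:]):
        if b - a <= 1e-12:
            continue
        step_idx = min(
            int(np.searchsorted(ca_sig.step_times, a + 1e-9, side="right")) - 1,
            len(ca_steps) - 1,
        )
        c_in = c_in_base.copy()
        c_in[compiled.ca_idx] = ca_steps[max(step_idx, 0)]
        mask = (t_eval >= a - 1e-9) & (t_eval < b - 1e-9)
        if b >= t1 - 1e-9:  # include right endpoint in the last segment
            mask |= np.abs(t_eval - b) <= 1e-9
        seg_eval = t_eval[mask]
        sol = solve_ivp(
            compiled.rhs(1.0 / tau, c_in), (a, b), c,
            t_eval=seg_eval if seg_eval.size else None,
            method=method, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{a:.1f}, {b:.1f}] s: {sol.message}"
            )
        if seg_eval.size:
            out[:, filled:filled + seg_eval.size] = sol.y
            filled += seg_eval.size
        c = sol.y[:, -1]

    if filled != t_eval.size:
        raise IntegrationError("internal error: evaluation grid not fully covered")
    # clamp tiny negative excursions (within solver tolerance)
    neg = out < 0
    if np.any(out < -1e-6):
        raise IntegrationError(
            f"negative concentration beyond tolerance (min {out.min():.3e})"
        )
    out[neg] = 0.0
    return TraceSet(times=t_eval, concentrations=out, compound_ids=ids)


def sample_outlet(
    traces: TraceSet,
    start: float,
    interval: float,
    n_samples: int,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> TraceSet:
    """Sample the simulated outlet at fixed intervals with multiplicative noise.

    Emulates periodic collection of outlet aliquots: ``n_samples`` rows at
    ``start + i * interval``, linearly interpolated from the simulation,
    each multiplied by a lognormal factor with unit mean and coefficient
    of variation ``noise_cv``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    t_s = start + np.arange(n_samples) * interval
    if t_s[0] < traces.times[0] - 1e-9 or t_s[-1] > traces.times[-1] + 1e-9:
        raise ValueError("sampling window extends beyond the simulated span")
    sampled = np.vstack([
        np.interp(t_s, traces.times, row) for row in traces.concentrations
    ])
    if noise_cv > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sig = np.sqrt(np.log1p(noise_cv ** 2))
        factors = rng.lognormal(mean=-0.5 * sig ** 2, sigma=sig, size=sampled.shape)
        sampled = sampled * factors
    return TraceSet(times=t_s, concentrations=sampled,
                    compound_ids=list(traces.compound_ids))
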