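"""Stoichiometric yield model of bifidobacterial lactose and fucose fermentation.

Bifidobacteria ferment hexoses through the fructose-6-phosphate phosphoketolase
("bifid shunt") pathway, which converts 2 hexose to 3 acetate + 2 lactate, and
some infant-type species additionally catabolise L-fucose — the sub-component of
fucosylated human-milk oligosaccharides such as 2'-fucosyllactose (2'-FL) — to
formate, acetate and 1,2-propanediol (1,2-PD).  The two routes differ in their
redox budget: the fucose route regenerates the NAD+ spent on fucose oxidation by
reducing lactaldehyde to 1,2-PD, so pyruvate is routed to formate + acetyl-CoA
(pyruvate formate-lyase) rather than to lactate, whereas on hexose the NADH from
lower glycolysis must be discharged through lactate dehydrogenase.  Both
terminal reactions are present in every network here; which one carries flux is
decided by the NAD+/NADH balance, not by hand.

The model is a steady-state yield (flux-balance) model: every non-exchange
metabolite, including the NAD+/NADH and CoA pools, must net to zero, the fed
substrate is converted completely, and the minimum-total-flux solution is
reported.  ATP/ADP turnover is tracked in the reactions but left unconstrained
because biomass and maintenance are not modelled.  Inorganic phosphate is not
tracked.  Carbon bookkeeping counts the acetyl moiety of acetyl-CoA as C2 and
all cofactors as carbon-free, so each reaction conserves the carbon skeleton
being transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: cofactor metabolites; never allowed in an exchange set
COFACTORS = frozenset({"NAD+", "NADH", "ATP", "ADP", "CoA"})

#: metabolites whose mass balance is deliberately not enforced (no biomass sink)
UNCONSTRAINED = frozenset({"ATP", "ADP"})


class InfeasibleBalanceError(ValueError):
    """Raised when no flux distribution balances the network.

    ``metabolite`` names the species with the largest residual imbalance in
    the least-squares relaxation of the balance system.
    """

    def __init__(self, metabolite: str, residual: float):
        self.metabolite = metabolite
        self.residual = residual
        super().__init__(
            f"no feasible flux balance: metabolite {metabolite!r} cannot be "
            f"balanced (least-squares residual {residual:.3g})"
        )


@dataclass(frozen=True)
class Reaction:
    """A mass- and redox-balanced reaction.

    ``stoichiometry`` maps metabolite name to a signed coefficient; negative
    coefficients are consumed, positive produced.  Cofactors (NAD+/NADH,
    ATP/ADP, CoA) appear explicitly.
    """

    id: str
    stoichiometry: Mapping[str, float]

    def validate(self, carbons: Mapping[str, int]) -> None:
        coeffs = list(self.stoichiometry.values())
        if not any(c < 0 for c in coeffs) or not any(c > 0 for c in coeffs):
            raise ValueError(
                f"reaction {self.id!r} must consume and produce at least one "
                "metabolite"
            )
        balance = 0.0
        for met, coef in self.stoichiometry.items():
            if met not in carbons:
                raise ValueError(
                    f"reaction {self.id!r} uses unregistered metabolite {met!r}"
                )
            balance += coef * carbons[met]
        if abs(balance) > 1e-9:
            raise ValueError(
                f"reaction {self.id!r} does not conserve carbon "
                f"(net {balance:+g} C)"
            )


@dataclass
class PathwayNetwork:
    """A set of reactions with a metabolite registry and exchange boundary.

    ``substrates`` are metabolites that may be fed; ``products`` are terminal
    metabolites allowed to accumulate.  Everything else — intermediates and
    cofactors — must net to zero at steady state (ATP/ADP excepted, see module
    docstring).
    """

    name: str
    metabolites: dict[str, int]  # name -> carbon count
    reactions: list[Reaction]
    substrates: frozenset[str]
    products: frozenset[str]

    def __post_init__(self):
        self.substrates = frozenset(self.substrates)
        self.products = frozenset(self.products)
        self.validate()

    @property
    def exchanges(self) -> frozenset[str]:
        return self.substrates | self.products

    def validate(self) -> None:
        if self.exchanges & COFACTORS:
            raise ValueError("cofactors may not be exchange metabolites")
        for met in self.exchanges:
            if met not in self.metabolites:
                raise ValueError(f"exchange metabolite {met!r} not registered")
        for rxn in self.reactions:
            rxn.validate(self.metabolites)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Return (S, metabolite order, reaction order) with S[i, j] the
        coefficient of metabolite i in reaction j."""
        mets = sorted(self.metabolites)
        rxns = [r.id for r in self.reactions]
        S = np.zeros((len(mets), len(rxns)))
        idx = {m: i for i, m in enumerate(mets)}
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[idx[met], j] = coef
        return S, mets, rxns

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "metabolites": dict(self.metabolites),
            "substrates": sorted(self.substrates),
            "products": sorted(self.products),
            "reactions": [
                {"id": r.id, "stoichiometry": dict(r.stoichiometry)}
                for r in self.reactions
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PathwayNetwork":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            name=doc["name"],
            metabolites=dict(doc["metabolites"]),
            reactions=[
                Reaction(r["id"], dict(r["stoichiometry"]))
                for r in doc["reactions"]
            ],
            substrates=frozenset(doc["substrates"]),
            products=frozenset(doc["products"]),
        )


@dataclass
class FermentationResult:
    """Net products of completely fermenting ``amount`` mol of ``substrate``.

    ``production`` holds net mol per exchange metabolite (the substrate appears
    with a negative entry equal to −amount); ``yields`` the same divided by the
    substrate amount; ``fluxes`` the reaction flux vector; ``residuals`` the
    per-metabolite balance residuals of the constrained solve.
    """

    substrate: str
    amount: float
    production: dict[str, float]
    yields: dict[str, float]
    fluxes: dict[str, float]
    residuals: dict[str, float]

    def product(self, metabolite: str) -> float:
        return self.production.get(metabolite, 0.0)


# ---------------------------------------------------------------------------
# Metabolite registry (carbon counts; cofactors carbon-free by convention,
# acetyl-CoA counted as its C2 acetyl moiety)
# ---------------------------------------------------------------------------

CARBONS: dict[str, int] = {
    "glucose": 6,
    "galactose": 6,
    "lactose": 12,
    "fucose": 6,
    "2FL": 18,
    "F6P": 6,
    "GAP": 3,
    "acetyl-P": 2,
    "acetyl-CoA": 2,
    "pyruvate": 3,
    "lactate": 3,
    "acetate": 2,
    "formate": 1,
    "fuconate": 6,
    "lactaldehyde": 3,
    "1,2-PD": 3,
    "NAD+": 0,
    "NADH": 0,
    "ATP": 0,
    "ADP": 0,
    "CoA": 0,
}

# -- reaction pool ----------------------------------------------------------

_R = {
    # hexokinase / glucose-6-P isomerase, lumped
    "glk": Reaction("glk", {"glucose": -1, "ATP": -1, "F6P": 1, "ADP": 1}),
    # fructose-6-P phosphoketolase + transaldolase/transketolase + xylulose-5-P
    # phosphoketolase, lumped: the defining step of the bifid shunt
    "f6ppk": Reaction("f6ppk", {"F6P": -2, "acetyl-P": 3, "GAP": 2}),
    # lower glycolysis GAP -> pyruvate, lumped (1 NADH, 2 ATP per triose)
    "gapdh_pk": Reaction(
        "gapdh_pk",
        {"GAP": -1, "NAD+": -1, "ADP": -2, "pyruvate": 1, "NADH": 1, "ATP": 2},
    ),
    # L-lactate dehydrogenase
    "ldh": Reaction("ldh", {"pyruvate": -1, "NADH": -1, "lactate": 1, "NAD+": 1}),
    # acetate kinase on acetyl-P
    "ack": Reaction("ack", {"acetyl-P": -1, "ADP": -1, "acetate": 1, "ATP": 1}),
    # pyruvate formate-lyase (formate C-acetyltransferase)
    "pfl": Reaction(
        "pfl", {"pyruvate": -1, "CoA": -1, "formate": 1, "acetyl-CoA": 1}
    ),
    # phosphotransacetylase + acetate kinase on acetyl-CoA, lumped
    "pta_ack": Reaction(
        "pta_ack", {"acetyl-CoA": -1, "ADP": -1, "acetate": 1, "ATP": 1, "CoA": 1}
    ),
    # fucose dehydrogenase + lactonase, lumped (the NAD+-consuming entry step)
    "fdh": Reaction("fdh", {"fucose": -1, "NAD+": -1, "fuconate": 1, "NADH": 1}),
    # fuconate dehydratase + 2-keto-3-deoxy-fuconate aldolase, lumped
    "fclv": Reaction("fclv", {"fuconate": -1, "pyruvate": 1, "lactaldehyde": 1}),
    # lactaldehyde reductase: regenerates NAD+, yields 1,2-propanediol
    "lar": Reaction(
        "lar", {"lactaldehyde": -1, "NADH": -1, "1,2-PD": 1, "NAD+": 1}
    ),
    # intracellular 2'-FL hydrolysis after ABC-transporter import
    "fl_hydro": Reaction("fl_hydro", {"2FL": -1, "fucose": 1, "lactose": 1}),
    # beta-galactosidase
    "lacZ": Reaction("lacZ", {"lactose": -1, "glucose": 1, "galactose": 1}),
    # Leloir pathway, lumped: galactose enters glycolysis at fructose-6-P
    "leloir": Reaction(
        "leloir", {"galactose": -1, "ATP": -1, "F6P": 1, "ADP": 1}
    ),
}

_SHUNT_RXNS = ["glk", "f6ppk", "gapdh_pk", "ldh", "ack", "pfl", "pta_ack"]
_FUCOSE_RXNS = ["fdh", "fclv", "lar", "pfl", "pta_ack", "ldh"]
_PRODUCTS = frozenset({"acetate", "lactate", "formate", "1,2-PD"})


def _subset(mets_needed: set[str]) -> dict[str, int]:
    return {m: CARBONS[m] for m in sorted(mets_needed)}


def _network(name: str, rxn_ids: Sequence[str], substrates, products) -> PathwayNetwork:
    rxns = [_R[i] for i in rxn_ids]
    mets: set[str] = set()
    for r in rxns:
        mets |= set(r.stoichiometry)
    mets |= set(substrates) | set(products)
    return PathwayNetwork(
        name=name,
        metabolites=_subset(mets),
        reactions=rxns,
        substrates=frozenset(substrates),
        products=frozenset(products),
    )


def build_default_networks() -> tuple[PathwayNetwork, PathwayNetwork, PathwayNetwork]:
    """Return the (bifid shunt, fucose, combined) default networks.

    The shunt network ferments hexose (net 2 glucose -> 3 acetate + 2 lactate);
    the fucose network ferments L-fucose (1 fucose -> 1 formate + 1 acetate +
    1 1,2-PD); the combined network adds 2'-FL import/hydrolysis and the
    lactose/Leloir route so whole 2'-FL can be fermented by one organism.
    """
    shunt = _network("bifid_shunt", _SHUNT_RXNS, {"glucose"}, _PRODUCTS)
    fucose = _network("fucose", _FUCOSE_RXNS, {"fucose"}, _PRODUCTS)
    combined = _network(
        "combined_fl",
        _SHUNT_RXNS + ["fdh", "fclv", "lar", "fl_hydro", "lacZ", "leloir"],
        {"2FL", "fucose", "lactose", "glucose"},
        _PRODUCTS,
    )
    return shunt, fucose, combined


def ferment(
    network: PathwayNetwork, substrate: str, amount: float
) -> FermentationResult:
    """Completely ferment ``amount`` mol of ``substrate`` on ``network``.

    Solves the steady-state balance (all non-exchange metabolites, including
    NAD+/NADH and CoA, net to zero; other substrates net to zero; products
    net >= 0; substrate consumed exactly) with non-negative fluxes, taking the
    minimum-total-flux solution.

    Raises
    ------
    ValueError
        If the substrate is not in the exchange set or amount < 0.
    InfeasibleBalanceError
        If no flux distribution balances the network, naming the metabolite
        with the largest irreducible imbalance.
    """
    if substrate not in network.substrates:
        raise ValueError(
            f"{substrate!r} is not a substrate of network {network.name!r}"
        )
    if amount < 0:
        raise ValueError("amount must be >= 0")

    S, mets, rxns = network.stoichiometric_matrix()
    met_idx = {m: i for i, m in enumerate(mets)}

    internal = [
        m
        for m in mets
        if m not in network.exchanges and m not in UNCONSTRAINED
    ]
    other_substrates = [m for m in network.substrates if m != substrate]

    eq_rows = [S[met_idx[m]] for m in internal]
    eq_rhs = [0.0] * len(internal)
    for m in other_substrates:
        eq_rows.append(S[met_idx[m]])
        eq_rhs.append(0.0)
    eq_rows.append(S[met_idx[substrate]])
    eq_rhs.append(-float(amount))
    A_eq = np.asarray(eq_rows)
    b_eq = np.asarray(eq_rhs)

    prod_rows = [m for m in network.products]
    A_ub = -np.asarray([S[met_idx[m]] for m in prod_rows])
    b_ub = np.zeros(len(prod_rows))

    res = linprog(
        c=np.ones(len(rxns)),
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(0, None)] * len(rxns),
        method="highs",
    )
    if not res.success:
        # identify the least-balanceable metabolite via least squares
        v, *_ = np.linalg.lstsq(A_eq, b_eq, rcond=None)
        v = np.clip(v, 0.0, None)
        resid = A_eq @ v - b_eq
        worst = int(np.argmax(np.abs(resid[: len(internal)]))) if internal else 0
        met = internal[worst] if internal else substrate
        raise InfeasibleBalanceError(met, float(np.max(np.abs(resid))))

    v = res.x
    net = S @ v
    production = {m: float(net[met_idx[m]]) for m in sorted(network.exchanges)}
    scale = amount if amount > 0 else 1.0
    yields = {m: p / scale for m, p in production.items()}
    residuals = {m: float(net[met_idx[m]]) for m in internal}
    return FermentationResult(
        substrate=substrate,
        amount=float(amount),
        production=production,
        yields=yields,
        fluxes={r: float(x) for r, x in zip(rxns, v)},
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# Co-culture cross-feeding on 2'-FL
# ---------------------------------------------------------------------------

GENOTYPE_KEYS = frozenset(
    {"fl_sbp", "fucp", "fucosidase", "fucose_pathway", "shunt"}
)


def _check_flags(flags: Mapping[str, bool], who: str) -> dict[str, bool]:
    unknown = set(flags) - GENOTYPE_KEYS
    if unknown:
        raise ValueError(f"unknown genotype flag(s) for {who}: {sorted(unknown)}")
    return {k: bool(flags.get(k, False)) for k in GENOTYPE_KEYS}


def organism_network(flags: Mapping[str, bool], substrate: str) -> PathwayNetwork:
    """Assemble the network an organism with ``flags`` uses on ``substrate``.

    The exchange boundary is tailored to the feed so intermediates released
    intracellularly (fucose and lactose from imported 2'-FL) are fully
    fermented rather than excreted.
    """
    f = _check_flags(flags, "organism")
    rxn_ids: list[str] = []
    if f["shunt"]:
        rxn_ids += _SHUNT_RXNS + ["lacZ", "leloir"]
    if f["fucose_pathway"]:
        rxn_ids += [r for r in _FUCOSE_RXNS if r not in rxn_ids]
    if substrate == "2FL":
        rxn_ids.append("fl_hydro")
    # preserve pool order, dedupe
    seen: list[str] = []
    for r in rxn_ids:
        if r not in seen:
            seen.append(r)
    return _network(f"organism_{substrate}", seen, {substrate}, _PRODUCTS)


def _zero_result(substrate: str, amount: float) -> FermentationResult:
    return FermentationResult(
        substrate=substrate,
        amount=float(amount),
        production={substrate: 0.0},
        yields={substrate: 0.0},
        fluxes={},
        residuals={},
    )


def coculture_ferment(
    organisms: Mapping[str, Mapping[str, bool]],
    amount: float,
    substrate: str = "2FL",
    uptake_weights: Mapping[str, float] | None = None,
) -> FermentationResult:
    """Ferment 2'-FL with one or more organisms, modelling fucose cross-feeding.

    2'-FL is accessible if some organism imports it intact (FL-SBP transporter
    plus an intracellular fucose pathway) or some organism carries an
    extracellular fucosidase, which releases free fucose + lactose into a
    shared pool.  Released fucose is consumed by organisms with FucP + fucose
    pathway; released lactose by organisms with the shunt.  When both the
    direct-import and the extracellular route exist, or several organisms
    compete for a pool, the substrate is split by ``uptake_weights``
    (default equal shares).  Unconsumed pool metabolites are reported as
    positive net production (they accumulate in the medium).
    """
    if substrate != "2FL":
        raise ValueError("coculture_ferment models 2'-FL feeding only")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    flags = {name: _check_flags(f, name) for name, f in organisms.items()}
    if not flags:
        raise ValueError("at least one organism required")
    weights = {
        name: (uptake_weights or {}).get(name, 1.0) for name in flags
    }

    direct = [n for n, f in flags.items() if f["fl_sbp"] and f["fucose_pathway"]]
    hydrolysers = [n for n, f in flags.items() if f["fucosidase"]]

    production: dict[str, float] = {
        m: 0.0 for m in ("2FL", "fucose", "lactose", *sorted(_PRODUCTS))
    }
    fluxes: dict[str, float] = {}
    residuals: dict[str, float] = {}

    def _accumulate(name: str, result: FermentationResult) -> None:
        for m, p in result.production.items():
            if m in production and p > 0:
                production[m] += p
        for r, x in result.fluxes.items():
            fluxes[f"{name}:{r}"] = x
        for m, x in result.residuals.items():
            residuals[f"{name}:{m}"] = x

    def _split(pool: float, consumers: list[str]) -> dict[str, float]:
        if not consumers or pool <= 0:
            return {}
        w = np.array([weights[n] for n in consumers], dtype=float)
        if w.sum() <= 0:
            w = np.ones_like(w)
        return {n: pool * wi / w.sum() for n, wi in zip(consumers, w)}

    # route allocation for the intact trisaccharide
    routes = int(bool(direct)) + int(bool(hydrolysers))
    if routes == 0:
        production["2FL"] = 0.0  # inaccessible: nothing consumed
        return FermentationResult(
            substrate="2FL",
            amount=float(amount),
            production={m: v for m, v in production.items()},
            yields={
                m: (v / amount if amount > 0 else 0.0)
                for m, v in production.items()
            },
            fluxes={},
            residuals={},
        )
    direct_share = amount / routes if direct else 0.0
    extracellular_share = amount - direct_share if hydrolysers else 0.0

    for name, share in _split(direct_share, direct).items():
        net = organism_network(flags[name], "2FL")
        _accumulate(name, ferment(net, "2FL", share))

    fucose_pool = extracellular_share
    lactose_pool = extracellular_share  # 1 mol each per mol 2'-FL hydrolysed

    fucose_eaters = [
        n for n, f in flags.items() if f["fucp"] and f["fucose_pathway"]
    ]
    lactose_eaters = [n for n, f in flags.items() if f["shunt"]]

    alloc = _split(fucose_pool, fucose_eaters)
    for name, share in alloc.items():
        net = organism_network(flags[name], "fucose")
        _accumulate(name, ferment(net, "fucose", share))
    production["fucose"] += fucose_pool - sum(alloc.values())

    alloc = _split(lactose_pool, lactose_eaters)
    for name, share in alloc.items():
        net = organism_network(flags[name], "lactose")
        _accumulate(name, ferment(net, "lactose", share))
    production["lactose"] += lactose_pool - sum(alloc.values())

    production["2FL"] = -float(direct_share + extracellular_share)
    scale = amount if amount > 0 else 1.0
    return FermentationResult(
        substrate="2FL",
        amount=float(amount),
        production=production,
        yields={m: v / scale for m, v in production.items()},
        fluxes=fluxes,
        residuals=residuals,
    )
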