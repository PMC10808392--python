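"""Metabolic network representation and I/O.

A :class:`MetabolicNetwork` holds metabolites, reactions (signed stoichiometry),
allosteric regulatory annotations, and the three distinguished reactions every
strain-design run needs: the biomass lump, the product exchange/transport to be
maximised, and the substrate uptake step.

Two on-disk formats are supported: SBML Level 3 (via python-libsbml) and a
human-writable three-file TSV dialect (``metabolites.tsv``, ``reactions.tsv``,
``regulations.tsv``).  Round trips preserve stoichiometry exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "RegulatoryInteraction",
    "MetabolicNetwork",
    "NetworkValidationError",
    "FormatError",
    "load_network",
    "save_network",
    "stoichiometric_matrix",
    "conservation_relations",
]

REGULATION_MODES = (
    "competitive_inhibition",
    "uncompetitive_inhibition",
    "mixed_inhibition",
    "activation",
)

# SBO terms used to tag regulator modifier species in SBML output.
_MODE_TO_SBO = {
    "competitive_inhibition": 206,
    "uncompetitive_inhibition": 207,
    "mixed_inhibition": 20,
    "activation": 21,
}
_SBO_TO_MODE = {v: k for k, v in _MODE_TO_SBO.items()}


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


class FormatError(ValueError):
    """Raised when a network file cannot be parsed."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_boundary: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = True
    is_transport: bool = False
    is_exchange: bool = False
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")
        zero = [m for m, c in self.stoichiometry.items() if c == 0]
        if zero:
            raise NetworkValidationError(
                f"reaction {self.id!r}: zero coefficient for {zero}"
            )

    @property
    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass(frozen=True)
class RegulatoryInteraction:
    regulator: str
    target: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in REGULATION_MODES:
            raise NetworkValidationError(
                f"unknown regulation mode {self.mode!r}; expected one of {REGULATION_MODES}"
            )


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    regulations: list[RegulatoryInteraction] = field(default_factory=list)
    compartments: set[str] = field(default_factory=set)
    biomass_reaction: str = ""
    objective_product: str = ""
    substrate_uptake: str = ""
    extracellular_compartment: str = "e"

    def __post_init__(self) -> None:
        if not self.compartments:
            self.compartments = {m.compartment for m in self.metabolites}
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_boundary]

    @property
    def boundary_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.is_boundary]

    def metabolite(self, mid: str) -> Metabolite:
        return self._met_map[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_map[rid]

    def regulations_of(self, rid: str) -> list[RegulatoryInteraction]:
        return [r for r in self.regulations if r.target == rid]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            dup = sorted({m for m in mids if mids.count(m) > 1})
            raise NetworkValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dup}")
        self._met_map = {m.id: m for m in self.metabolites}
        self._rxn_map = {r.id: r for r in self.reactions}
        for m in self.metabolites:
            if m.compartment not in self.compartments:
                raise NetworkValidationError(
                    f"metabolite {m.id!r}: undeclared compartment {m.compartment!r}"
                )
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_map:
                    raise NetworkValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )
        for rid, role in (
            (self.biomass_reaction, "biomass_reaction"),
            (self.objective_product, "objective_product"),
            (self.substrate_uptake, "substrate_uptake"),
        ):
            if rid and rid not in self._rxn_map:
                raise NetworkValidationError(f"{role} {rid!r} is not a declared reaction")
        for reg in self.regulations:
            if reg.regulator not in self._met_map:
                raise NetworkValidationError(
                    f"regulation references undeclared metabolite {reg.regulator!r}"
                )
            if reg.target not in self._rxn_map:
                raise NetworkValidationError(
                    f"regulation references undeclared reaction {reg.target!r}"
                )


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def stoichiometric_matrix(net: MetabolicNetwork, scope: str = "all") -> np.ndarray:
    """Stoichiometric matrix N (metabolites x reactions).

    ``scope='internal'`` drops rows of boundary (fixed-concentration) species,
    which is the matrix entering the steady-state constraint N v = 0.
    """
    if scope not in ("all", "internal"):
        raise ValueError(f"scope must be 'all' or 'internal', got {scope!r}")
    mids = net.metabolite_ids if scope == "all" else net.internal_metabolite_ids
    idx = {m: i for i, m in enumerate(mids)}
    N = np.zeros((len(mids), len(net.reactions)))
    for j, r in enumerate(net.reactions):
        for m, c in r.stoichiometry.items():
            if m in idx:
                N[idx[m], j] = c
    return N


def conservation_relations(net: MetabolicNetwork) -> list[np.ndarray]:
    """Basis of the left null space of the internal stoichiometric matrix.

    Each returned vector ``l`` (indexed like ``internal_metabolite_ids``)
    satisfies l.T @ N = 0 exactly: the corresponding weighted metabolite sum
    is a conserved moiety of the mass-balance dynamics.  Computed by rational
    elimination so the basis is reproducible.
    """
    import sympy

    N = stoichiometric_matrix(net, scope="internal")
    if N.size == 0:
        return []
    Nrat = sympy.Matrix(
        [[Fraction(float(x)).limit_denominator(10**9) for x in row] for row in N]
    )
    basis = Nrat.T.nullspace()
    out = []
    for vec in basis:
        arr = np.array([float(v) for v in vec], dtype=float)
        # scale to integer-ish representative: largest |entry| -> 1
        arr = arr / np.max(np.abs(arr))
        out.append(arr)
    return out


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_ROLE_COLS = {
    "biomass": "biomass_reaction",
    "product": "objective_product",
    "uptake": "substrate_uptake",
}


def _fmt_coeff(c: float) -> str:
    return repr(c) if c != int(c) else str(int(c))


def _write_tsv(net: MetabolicNetwork, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "metabolites.tsv"), "w") as fh:
        fh.write("id\tname\tcompartment\tis_boundary\n")
        for m in net.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{m.compartment}\t{int(m.is_boundary)}\n")
    role_of = {}
    if net.biomass_reaction:
        role_of[net.biomass_reaction] = "biomass"
    if net.objective_product:
        role_of[net.objective_product] = "product"
    if net.substrate_uptake:
        role_of[net.substrate_uptake] = "uptake"
    with open(os.path.join(directory, "reactions.tsv"), "w") as fh:
        fh.write(
            "id\tstoichiometry\treversible\tis_transport\tis_exchange\tgene_label\trole\n"
        )
        for r in net.reactions:
            stoich = ";".join(
                f"{m}:{_fmt_coeff(c)}" for m, c in r.stoichiometry.items()
            )
            fh.write(
                f"{r.id}\t{stoich}\t{int(r.reversible)}\t{int(r.is_transport)}"
                f"\t{int(r.is_exchange)}\t{r.gene_label or ''}\t{role_of.get(r.id, '')}\n"
            )
    with open(os.path.join(directory, "regulations.tsv"), "w") as fh:
        fh.write("regulator\ttarget\tmode\n")
        for reg in net.regulations:
            fh.write(f"{reg.regulator}\t{reg.target}\t{reg.mode}\n")


def _read_tsv(directory: str) -> MetabolicNetwork:
    def rows(fname):
        path = os.path.join(directory, fname)
        if not os.path.exists(path):
            raise FormatError(f"missing TSV file {path}")
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(header):
                    raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
                yield lineno, dict(zip(header, parts))

    mets = [
        Metabolite(
            id=d["id"],
            name=d["name"],
            compartment=d["compartment"],
            is_boundary=bool(int(d["is_boundary"])),
        )
        for _, d in rows("metabolites.tsv")
    ]
    rxns, roles = [], {}
    for lineno, d in rows("reactions.tsv"):
        stoich = {}
        for term in d["stoichiometry"].split(";"):
            if not term:
                continue
            try:
                m, c = term.rsplit(":", 1)
                stoich[m] = float(c)
            except ValueError as exc:
                raise FormatError(
                    f"reactions.tsv:{lineno}: bad stoichiometry term {term!r}"
                ) from exc
        rxns.append(
            Reaction(
                id=d["id"],
                stoichiometry=stoich,
                reversible=bool(int(d["reversible"])),
                is_transport=bool(int(d["is_transport"])),
                is_exchange=bool(int(d["is_exchange"])),
                gene_label=d["gene_label"] or None,
            )
        )
        if d.get("role"):
            roles[_ROLE_COLS[d["role"]]] = d["id"]
    regs = [
        RegulatoryInteraction(d["regulator"], d["target"], d["mode"])
        for _, d in rows("regulations.tsv")
    ]
    return MetabolicNetwork(metabolites=mets, reactions=rxns, regulations=regs, **roles)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_ANNOT_NS = "https://strainkit.invalid/roles"


def _write_sbml(net: MetabolicNetwork, path: str) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel("network")
    for comp in sorted(net.compartments):
        c = model.createCompartment()
        c.setId(comp)
        c.setConstant(True)
    for m in net.metabolites:
        s = model.createSpecies()
        s.setId(m.id)
        if m.name:
            s.setName(m.name)
        s.setCompartment(m.compartment)
        s.setBoundaryCondition(m.is_boundary)
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
    for r in net.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setReversible(r.reversible)
        if r.gene_label:
            rx.setName(r.gene_label)
        for m, c in r.stoichiometry.items():
            ref = rx.createReactant() if c < 0 else rx.createProduct()
            ref.setSpecies(m)
            ref.setStoichiometry(abs(c))
            ref.setConstant(True)
        for reg in net.regulations_of(r.id):
            mod = rx.createModifier()
            mod.setSpecies(reg.regulator)
            mod.setSBOTerm(_MODE_TO_SBO[reg.mode])
        # transport/exchange flags ride on an annotation
        rx.appendAnnotation(
            f'<sk:flags xmlns:sk="{_ANNOT_NS}" transport="{int(r.is_transport)}" '
            f'exchange="{int(r.is_exchange)}"/>'
        )
    model.appendAnnotation(
        f'<sk:roles xmlns:sk="{_ANNOT_NS}" biomass="{net.biomass_reaction}" '
        f'product="{net.objective_product}" uptake="{net.substrate_uptake}" '
        f'extracellular="{net.extracellular_compartment}"/>'
    )
    libsbml.writeSBMLToFile(doc, path)


def _annot_attrs(node, name: str) -> dict[str, str]:
    """Extract attributes of the first <name> element inside an annotation."""
    if node is None:
        return {}
    for i in range(node.getNumChildren()):
        child = node.getChild(i)
        if child.getName() == name:
            attrs = child.getAttributes()
            return {
                attrs.getName(k): attrs.getValue(k) for k in range(attrs.getLength())
            }
        found = _annot_attrs(child, name)
        if found:
            return found
    return {}


def _read_sbml(path: str) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"SBML parse error at line {err.getLine()}: {err.getMessage()}")
    model = doc.getModel()
    if model is None:
        raise FormatError(f"{path}: no model element")
    mets = [
        Metabolite(
            id=s.getId(),
            name=s.getName() or "",
            compartment=s.getCompartment(),
            is_boundary=s.getBoundaryCondition(),
        )
        for s in model.getListOfSpecies()
    ]
    known = {m.id for m in mets}
    rxns, regs = [], []
    for rx in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            if ref.getSpecies() not in known:
                raise NetworkValidationError(
                    f"reaction {rx.getId()!r} references undeclared species "
                    f"{ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            if ref.getSpecies() not in known:
                raise NetworkValidationError(
                    f"reaction {rx.getId()!r} references undeclared species "
                    f"{ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        flags = _annot_attrs(rx.getAnnotation(), "flags")
        rxns.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                reversible=rx.getReversible(),
                is_transport=bool(int(flags.get("transport", "0"))),
                is_exchange=bool(int(flags.get("exchange", "0"))),
                gene_label=rx.getName() or None,
            )
        )
        for mod in rx.getListOfModifiers():
            mode = _SBO_TO_MODE.get(mod.getSBOTerm())
            if mode is not None:
                regs.append(RegulatoryInteraction(mod.getSpecies(), rx.getId(), mode))
    roles = _annot_attrs(model.getAnnotation(), "roles")
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        regulations=regs,
        biomass_reaction=roles.get("biomass", ""),
        objective_product=roles.get("product", ""),
        substrate_uptake=roles.get("uptake", ""),
        extracellular_compartment=roles.get("extracellular", "e"),
    )


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def load_network(path: str, format: str = "tsv") -> MetabolicNetwork:
    """Read a network from ``path`` (a directory for TSV, a file for SBML)."""
    if format == "tsv":
        return _read_tsv(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown format {format!r}")


def save_network(net: MetabolicNetwork, path: str, format: str = "tsv") -> None:
    if format == "tsv":
        _write_tsv(net, path)
    elif format == "sbml":
        _write_sbml(net, path)
    else:
        raise ValueError(f"unknown format {format!r}")
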