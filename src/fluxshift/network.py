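"""Metabolic network container and model I/O.

The network holds metabolites, reactions (stoichiometry, flux bounds, GPR,
subsystem) and the stoichiometric matrix S (metabolites x reactions) used by
all constraint-based computations.  The flux convention follows standard
genome-scale models: bounds default to [-1000, 1000] for reversible
reactions and [0, 1000] for irreversible ones, with negative flux meaning
the reverse direction.

Two on-disk dialects are supported:

* a plain TSV dialect (header ``reaction_id  equation  lower_bound
  upper_bound  gpr  subsystem``; equation syntax ``a A + b B <=> c C``,
  ``=>`` for irreversible, one side may be empty for boundary reactions);
* SBML Level 3 with the FBC package, read through cobrapy.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .gpr import EMPTY_GPR, GprExpression, parse_gpr

__all__ = [
    "NetworkError",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "read_network",
    "read_tabular",
    "read_sbml",
    "write_tabular",
    "parse_equation",
]

DEFAULT_BOUND = 1000.0


class NetworkError(ValueError):
    """Raised for malformed or inconsistent model files."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """One reaction: stoichiometry (negative = consumed), bounds, GPR, subsystem."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GprExpression = field(default_factory=lambda: EMPTY_GPR)
    subsystem: str = ""
    is_exchange: bool | None = None  # None -> auto-detect on network build

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise NetworkError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes()


class MetabolicNetwork:
    """Validated collection of metabolites and reactions with matrix S."""

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        exchange_prefix: str = "EX_",
    ) -> None:
        met_ids = [m.id for m in metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = _first_duplicate(met_ids)
            raise NetworkError(f"duplicate metabolite id {dup!r}")
        rxn_ids = [r.id for r in reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = _first_duplicate(rxn_ids)
            raise NetworkError(f"duplicate reaction id {dup!r}")
        known = set(met_ids)
        for rxn in reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise NetworkError(
                    f"reaction {rxn.id} references unknown metabolite(s) "
                    f"{sorted(missing)}"
                )
            if rxn.is_exchange is None:
                rxn.is_exchange = (
                    len(rxn.stoichiometry) == 1 or rxn.id.startswith(exchange_prefix)
                )
            if not rxn.stoichiometry and not rxn.is_exchange:
                raise NetworkError(f"non-exchange reaction {rxn.id} has empty stoichiometry")
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.metabolite_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self.reaction_index = {r.id: j for j, r in enumerate(self.reactions)}
        self._matrix: sparse.csr_matrix | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for rxn in self.reactions:
            out |= rxn.genes
        return out

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.reaction_index[rxn_id]]

    @property
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S (metabolites x reactions), column j = reaction j's stoichiometry."""
        if self._matrix is None:
            rows, cols, data = [], [], []
            for j, rxn in enumerate(self.reactions):
                for met, coef in rxn.stoichiometry.items():
                    rows.append(self.metabolite_index[met])
                    cols.append(j)
                    data.append(float(coef))
            self._matrix = sparse.csr_matrix(
                (data, (rows, cols)),
                shape=(len(self.metabolites), len(self.reactions)),
            )
        return self._matrix

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def __len__(self) -> int:
        return len(self.reactions)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicNetwork {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return ""


# -- equation dialect ------------------------------------------------------

_ARROWS = ("<=>", "=>")
_COMPARTMENT_RE = re.compile(r"\[(\w+)\]$")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``a A + b B <=> c C`` into (stoichiometry, reversible).

    Coefficients default to 1; either side may be empty (boundary reaction);
    metabolite ids may carry a compartment suffix like ``glc[c]``.
    """
    arrow = None
    for candidate in _ARROWS:
        if candidate in text:
            arrow = candidate
            break
    if arrow is None:
        raise NetworkError(f"equation {text!r} has no '=>' or '<=>' arrow")
    lhs_text, rhs_text = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"empty term in equation {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise NetworkError(
                        f"bad coefficient {parts[0]!r} in equation {text!r}"
                    ) from exc
                met = parts[1]
            else:
                raise NetworkError(f"cannot parse term {term!r} in equation {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs_text, -1.0)
    add_side(rhs_text, +1.0)
    # drop metabolites that cancel exactly (appear on both sides equally)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, arrow == "<=>"


def format_equation(rxn: Reaction) -> str:
    lhs, rhs = [], []
    for met in sorted(rxn.stoichiometry):
        coef = rxn.stoichiometry[met]
        target = lhs if coef < 0 else rhs
        mag = abs(coef)
        target.append(met if mag == 1 else f"{mag:g} {met}")
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# -- readers/writers -------------------------------------------------------

_TABULAR_COLUMNS = [
    "reaction_id",
    "equation",
    "lower_bound",
    "upper_bound",
    "gpr",
    "subsystem",
]


def read_tabular(path: str, exchange_prefix: str = "EX_") -> MetabolicNetwork:
    """Read the TSV model dialect; blank bounds get defaults from the arrow."""
    reactions: list[Reaction] = []
    met_ids: list[str] = []
    seen_mets: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        header: list[str] | None = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if header[: len(_TABULAR_COLUMNS)] != _TABULAR_COLUMNS:
                    raise NetworkError(
                        f"{path}:{lineno}: expected header "
                        f"{' '.join(_TABULAR_COLUMNS)!r}, got {line!r}"
                    )
                continue
            if len(fields) < 2:
                raise NetworkError(f"{path}:{lineno}: too few columns")
            fields += [""] * (len(_TABULAR_COLUMNS) - len(fields))
            rxn_id, equation, lb_text, ub_text, gpr_text, subsystem = (
                f.strip() for f in fields[: len(_TABULAR_COLUMNS)]
            )
            try:
                stoich, reversible = parse_equation(equation)
                gpr = parse_gpr(gpr_text)
            except (NetworkError, ValueError) as exc:
                raise NetworkError(f"{path}:{lineno}: {exc}") from exc
            lb = float(lb_text) if lb_text else (-DEFAULT_BOUND if reversible else 0.0)
            ub = float(ub_text) if ub_text else DEFAULT_BOUND
            if not (math.isfinite(lb) and math.isfinite(ub)):
                raise NetworkError(f"{path}:{lineno}: non-finite bounds")
            reactions.append(
                Reaction(
                    id=rxn_id,
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr=gpr,
                    subsystem=subsystem,
                )
            )
            for met in stoich:
                if met not in seen_mets:
                    seen_mets.add(met)
                    met_ids.append(met)
    if header is None:
        raise NetworkError(f"{path}: empty model file")
    metabolites = [
        Metabolite(id=m, compartment=_compartment_of(m)) for m in met_ids
    ]
    return MetabolicNetwork(metabolites, reactions, exchange_prefix=exchange_prefix)


def _compartment_of(met_id: str) -> str:
    match = _COMPARTMENT_RE.search(met_id)
    return match.group(1) if match else ""


def read_sbml(path: str, exchange_prefix: str = "EX_") -> MetabolicNetwork:
    """Read an SBML L3 + FBC model via cobrapy and convert it."""
    import cobra.io

    model = cobra.io.read_sbml_model(path)
    # subsystems may travel as SBML groups rather than reaction attributes
    group_of: dict[str, str] = {}
    for group in getattr(model, "groups", []):
        for member in group.members:
            group_of.setdefault(member.id, group.name or group.id)
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in model.metabolites
    ]
    reactions = []
    for rxn in model.reactions:
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gpr=parse_gpr(rxn.gene_reaction_rule),
                subsystem=rxn.subsystem or group_of.get(rxn.id, ""),
                is_exchange=bool(rxn.boundary),
            )
        )
    return MetabolicNetwork(metabolites, reactions, exchange_prefix=exchange_prefix)


def read_network(
    path: str, dialect: str = "tabular", exchange_prefix: str = "EX_"
) -> MetabolicNetwork:
    """Read a model file in the named dialect (``tabular`` or ``sbml``)."""
    if dialect == "tabular":
        return read_tabular(path, exchange_prefix=exchange_prefix)
    if dialect == "sbml":
        return read_sbml(path, exchange_prefix=exchange_prefix)
    raise ValueError(f"unknown model dialect {dialect!r}")


def write_tabular(network: MetabolicNetwork, path: str) -> None:
    """Serialize a network to the TSV dialect (deterministic ordering)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(_TABULAR_COLUMNS) + "\n")
        for rxn in network.reactions:
            handle.write(
                "\t".join(
                    [
                        rxn.id,
                        format_equation(rxn),
                        f"{rxn.lower_bound:g}",
                        f"{rxn.upper_bound:g}",
                        rxn.gpr.to_text(),
                        rxn.subsystem,
                    ]
                )
                + "\n"
            )
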