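"""Stoichiometric network data model and I/O.

A :class:`MetabolicNetwork` is an ordered collection of metabolites and
reactions.  Stoichiometric coefficients are stored as exact
:class:`~fractions.Fraction` values so that multiplier searches over integer
reaction combinations never suffer float drift.  The network is the lossless
source of the stoichiometric matrix S (rows = metabolites, columns =
reactions, entry = product coefficient minus substrate coefficient).

Supported on-disk formats:

* **JSON** -- the package's native schema (see :func:`network_to_dict`).
* **TSV** -- one reaction per line: ``id <TAB> substrates <TAB> products
  [<TAB> reversible]`` with coefficient syntax ``2*mal``; optional directive
  lines ``#!external: m1 m2`` and ``#!cofactor: m1 m2`` declare metabolite
  attributes.
* **SBML** -- level-3 core stoichiometry only (kinetics ignored), read
  through :mod:`cobra` when available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import NetworkParseError, ValidationError

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ReactionVector",
    "load_network",
    "write_network",
    "strip_cofactors",
    "net_reaction_vector",
    "DEFAULT_COFACTORS",
]

#: Conventional small co-factors removed before cycle detection on
#: core-model-like networks.  User-overridable everywhere it is consumed.
DEFAULT_COFACTORS = frozenset(
    {"atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "coa", "pi", "h2o", "h", "co2"}
)


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, bool):
        raise ValidationError(f"boolean is not a stoichiometric coefficient: {value!r}")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**9)
    if isinstance(value, str):
        return Fraction(value)
    raise ValidationError(f"cannot interpret stoichiometric coefficient {value!r}")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species; ``is_external`` marks species outside the modeled
    system boundary (assimilated nutrients, sinks) that never count as cycle
    intermediates."""

    id: str
    name: str = ""
    is_cofactor: bool = False
    is_external: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValidationError("metabolite id must be nonempty")


@dataclass(frozen=True)
class Reaction:
    """An irreversible or reversible stoichiometric conversion.

    ``substrates`` and ``products`` map metabolite ids to strictly positive
    coefficients; a metabolite may not appear on both sides.
    """

    id: str
    substrates: Mapping[str, Fraction]
    products: Mapping[str, Fraction]
    reversible: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValidationError("reaction id must be nonempty")
        subs = {m: _as_fraction(c) for m, c in dict(self.substrates).items()}
        prods = {m: _as_fraction(c) for m, c in dict(self.products).items()}
        for side, coeffs in (("substrate", subs), ("product", prods)):
            for m, c in coeffs.items():
                if c <= 0:
                    raise ValidationError(
                        f"reaction {self.id!r}: {side} coefficient for {m!r} must be > 0, got {c}"
                    )
        overlap = set(subs) & set(prods)
        if overlap:
            raise ValidationError(
                f"reaction {self.id!r}: metabolites on both sides: {sorted(overlap)}"
            )
        object.__setattr__(self, "substrates", subs)
        object.__setattr__(self, "products", prods)

    @property
    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.substrates) | frozenset(self.products)

    def stoichiometry(self) -> dict[str, Fraction]:
        """Net coefficient per metabolite (products positive)."""
        net = {m: -c for m, c in self.substrates.items()}
        for m, c in self.products.items():
            net[m] = net.get(m, Fraction(0)) + c
        return net

    def has_unit_stoichiometry(self) -> bool:
        return all(c == 1 for c in self.substrates.values()) and all(
            c == 1 for c in self.products.values()
        )

    def reversed(self, suffix: str = "__rev") -> "Reaction":
        return Reaction(
            id=self.id + suffix,
            substrates=self.products,
            products=self.substrates,
            reversible=False,
        )


@dataclass(frozen=True)
class ReactionVector:
    """Net production per metabolite of a (weighted) reaction combination.

    Entries cover exactly the owning network's metabolites; missing ids are
    implicit zeros.
    """

    entries: Mapping[str, Fraction]

    def __post_init__(self):
        object.__setattr__(
            self, "entries", {m: _as_fraction(c) for m, c in dict(self.entries).items()}
        )

    def __getitem__(self, metabolite_id: str) -> Fraction:
        return self.entries.get(metabolite_id, Fraction(0))

    def restricted(self, metabolite_ids: Iterable[str]) -> dict[str, Fraction]:
        return {m: self[m] for m in metabolite_ids}


class MetabolicNetwork:
    """Ordered metabolites + reactions with validated cross-references."""

    def __init__(self, metabolites: Iterable[Metabolite], reactions: Iterable[Reaction]):
        self.metabolites: tuple[Metabolite, ...] = tuple(metabolites)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self._met_index = {}
        for m in self.metabolites:
            if m.id in self._met_index:
                raise ValidationError(f"duplicate metabolite id {m.id!r}")
            self._met_index[m.id] = m
        self._rxn_index = {}
        for r in self.reactions:
            if r.id in self._rxn_index:
                raise ValidationError(f"duplicate reaction id {r.id!r}")
            self._rxn_index[r.id] = r
            unknown = r.metabolite_ids - self._met_index.keys()
            if unknown:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: {sorted(unknown)}"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def internal_metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites if not m.is_external)

    def metabolite(self, metabolite_id: str) -> Metabolite:
        try:
            return self._met_index[metabolite_id]
        except KeyError:
            raise ValidationError(f"unknown metabolite {metabolite_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise ValidationError(f"unknown reaction {reaction_id!r}") from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._met_index or item_id in self._rxn_index

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return self.metabolites == other.metabolites and self.reactions == other.reactions

    def __repr__(self) -> str:
        return f"MetabolicNetwork(|M|={len(self.metabolites)}, |R|={len(self.reactions)})"

    # -- stoichiometry ---------------------------------------------------
    def stoich_column(self, reaction_id: str) -> dict[str, Fraction]:
        return self.reaction(reaction_id).stoichiometry()

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense float view of S; exact values live in :meth:`stoich_column`."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        row = {m: i for i, m in enumerate(self.metabolite_ids)}
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry().items():
                S[row[m], j] = float(c)
        return S

    def split_reversible(self, suffix: str = "__rev") -> "MetabolicNetwork":
        """Replace each reversible reaction with a forward/backward pair of
        irreversible reactions (the backward id gets ``suffix``)."""
        out = []
        for r in self.reactions:
            if r.reversible:
                fwd = Reaction(r.id, r.substrates, r.products, reversible=False)
                out.extend([fwd, r.reversed(suffix)])
            else:
                out.append(r)
        return MetabolicNetwork(self.metabolites, out)


# ---------------------------------------------------------------------------
# operations


def strip_cofactors(net: MetabolicNetwork, cofactor_ids: Iterable[str]) -> MetabolicNetwork:
    """Delete the given metabolites from every reaction.

    Reactions left with *both* sides empty are dropped.  Unknown ids raise
    :class:`ValidationError`.
    """
    cofactor_ids = set(cofactor_ids)
    unknown = cofactor_ids - set(net.metabolite_ids)
    if unknown:
        raise ValidationError(f"unknown cofactor ids: {sorted(unknown)}")
    metabolites = [m for m in net.metabolites if m.id not in cofactor_ids]
    reactions = []
    for r in net.reactions:
        subs = {m: c for m, c in r.substrates.items() if m not in cofactor_ids}
        prods = {m: c for m, c in r.products.items() if m not in cofactor_ids}
        if not subs and not prods:
            continue
        reactions.append(Reaction(r.id, subs, prods, r.reversible))
    return MetabolicNetwork(metabolites, reactions)


def net_reaction_vector(
    net: MetabolicNetwork, multiplicities: Mapping[str, int]
) -> ReactionVector:
    """Multiplicity-weighted sum of reaction stoichiometry columns.

    This is the total reaction vector of the formal autocatalysis definition:
    applying reaction ``l`` exactly ``i_l`` times changes each metabolite by
    the returned amount.
    """
    total: dict[str, Fraction] = {m: Fraction(0) for m in net.metabolite_ids}
    for rid, mult in multiplicities.items():
        if rid not in set(net.reaction_ids):
            raise ValidationError(f"unknown reaction {rid!r}")
        if not isinstance(mult, (int, Fraction)) or mult <= 0:
            raise ValidationError(f"multiplicity for {rid!r} must be a positive integer")
        for m, c in net.stoich_column(rid).items():
            total[m] += mult * c
    return ReactionVector(total)


# ---------------------------------------------------------------------------
# JSON format


def _coeff_to_json(c: Fraction):
    return int(c) if c.denominator == 1 else str(c)


def network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "is_cofactor": m.is_cofactor,
                "is_external": m.is_external,
            }
            for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": {m: _coeff_to_json(c) for m, c in r.substrates.items()},
                "products": {m: _coeff_to_json(c) for m, c in r.products.items()},
                "reversible": r.reversible,
            }
            for r in net.reactions
        ],
    }


def network_from_dict(data: Mapping) -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                is_cofactor=bool(m.get("is_cofactor", False)),
                is_external=bool(m.get("is_external", False)),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                substrates=r.get("substrates", {}),
                products=r.get("products", {}),
                reversible=bool(r.get("reversible", False)),
            )
            for r in data["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise NetworkParseError(f"malformed network record: {exc!r}") from exc
    return MetabolicNetwork(mets, rxns)


# ---------------------------------------------------------------------------
# TSV format


def _parse_side(text: str, rid: str) -> dict[str, Fraction]:
    side: dict[str, Fraction] = {}
    text = text.strip()
    if not text or text == "-":
        return side
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise NetworkParseError(f"reaction {rid!r}: empty term in {text!r}")
        if "*" in term:
            coeff_s, _, met = term.partition("*")
            try:
                coeff = Fraction(coeff_s.strip())
            except ValueError:
                raise NetworkParseError(
                    f"reaction {rid!r}: bad coefficient {coeff_s!r}"
                ) from None
        else:
            coeff, met = Fraction(1), term
        met = met.strip()
        if not met:
            raise NetworkParseError(f"reaction {rid!r}: missing metabolite in {term!r}")
        side[met] = side.get(met, Fraction(0)) + coeff
    return side


def _format_side(coeffs: Mapping[str, Fraction]) -> str:
    if not coeffs:
        return "-"
    return " + ".join(
        (f"{c}*{m}" if c != 1 else m) for m, c in coeffs.items()
    )


def network_from_tsv(text: str) -> MetabolicNetwork:
    external: set[str] = set()
    cofactor: set[str] = set()
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#!"):
            directive, _, payload = line[2:].partition(":")
            ids = payload.split()
            if directive.strip() == "external":
                external.update(ids)
            elif directive.strip() == "cofactor":
                cofactor.update(ids)
            else:
                raise NetworkParseError(f"line {lineno}: unknown directive {directive!r}")
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise NetworkParseError(f"line {lineno}: expected >=3 tab-separated fields")
        rid = parts[0].strip()
        subs = _parse_side(parts[1], rid)
        prods = _parse_side(parts[2], rid)
        reversible = len(parts) > 3 and parts[3].strip().lower() in {"reversible", "true", "1"}
        rows.append(Reaction(rid, subs, prods, reversible))
    met_ids: list[str] = []
    for r in rows:
        for m in list(r.substrates) + list(r.products):
            if m not in met_ids:
                met_ids.append(m)
    mets = [
        Metabolite(m, is_cofactor=m in cofactor, is_external=m in external) for m in met_ids
    ]
    return MetabolicNetwork(mets, rows)


def network_to_tsv(net: MetabolicNetwork) -> str:
    lines = []
    external = [m.id for m in net.metabolites if m.is_external]
    cofactor = [m.id for m in net.metabolites if m.is_cofactor]
    if external:
        lines.append("#!external: " + " ".join(external))
    if cofactor:
        lines.append("#!cofactor: " + " ".join(cofactor))
    for r in net.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    _format_side(r.substrates),
                    _format_side(r.products),
                    "reversible" if r.reversible else "irreversible",
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML (optional, via cobra)


def _network_from_sbml(path: Path) -> MetabolicNetwork:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - extra not installed
        raise NetworkParseError("SBML import requires the 'cobra' package") from exc
    model = cobra.io.read_sbml_model(str(path))
    mets = [
        Metabolite(id=m.id, name=m.name or "", is_external="_e" in m.id or m.compartment == "e")
        for m in model.metabolites
    ]
    rxns = []
    for r in model.reactions:
        subs = {m.id: Fraction(-r.metabolites[m]).limit_denominator() for m in r.metabolites if r.metabolites[m] < 0}
        prods = {m.id: Fraction(r.metabolites[m]).limit_denominator() for m in r.metabolites if r.metabolites[m] > 0}
        rxns.append(Reaction(r.id, subs, prods, reversible=r.reversibility))
    return MetabolicNetwork(mets, rxns)


# ---------------------------------------------------------------------------
# top-level I/O


def load_network(path, format: str | None = None) -> MetabolicNetwork:
    """Read a network file; ``format`` in ``{"json", "tsv", "sbml"}``.

    When ``format`` is omitted it is inferred from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = {".json": "json", ".tsv": "tsv", ".xml": "sbml", ".sbml": "sbml"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise NetworkParseError(f"cannot infer format of {path.name!r}")
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise NetworkParseError(f"{path.name}: invalid JSON ({exc})") from exc
        return network_from_dict(data)
    if format == "tsv":
        return network_from_tsv(path.read_text())
    if format == "sbml":
        return _network_from_sbml(path)
    raise NetworkParseError(f"unknown network format {format!r}")


def write_network(net: MetabolicNetwork, path, format: str = "json") -> None:
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(network_to_dict(net), indent=1) + "\n")
    elif format == "tsv":
        path.write_text(network_to_tsv(net))
    else:
        raise NetworkParseError(f"unsupported output format {format!r}")
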