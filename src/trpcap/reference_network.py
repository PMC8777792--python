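"""Curated tryptophan-metabolism reference network.

The reference network is the curation product at the heart of the tool: a
bipartite graph of metabolites and reactions describing how L-tryptophan is
degraded along its three canonical branches (indole, serotonin, kynurenine),
with each reaction and metabolite labelled by its origin (host, microbe, both,
or unknown).  Producibility queries against this network — "given the reactions
an organism carries, which tryptophan end-products can it reach?" — drive the
capability calls for every genome-scale model downstream.

Reachability semantics
----------------------
A metabolite is *producible* from a reaction subset when it can be reached from
the root (L-tryptophan) by iterating reactions to a fixed point.  A reaction
fires once every **non-currency** substrate is already reachable; currency
species (water, ammonia, cofactors, ...) are assumed freely available and are
never reported as products.  Reversible reactions may fire in either
direction.  This is deliberately conservative for multi-substrate reactions:
an end product whose obligatory intermediate is absent is not called
producible.  A simpler "reaction presence" mode (a metabolite counts as
producible whenever some present reaction emits it) is available via
``mode="presence"``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "TrpcapError",
    "SchemaError",
    "IntegrityError",
    "MetaboliteRecord",
    "ReactionRecord",
    "ReferenceNetwork",
    "DEFAULT_CURRENCY_NAMES",
    "FORMAT_HEADER",
    "load_reference_network",
    "save_reference_network",
    "producible_set",
    "subset_by_taxa",
    "export_graphml",
    "export_sif",
]


class TrpcapError(Exception):
    """Base class for errors raised by trpcap."""


class SchemaError(TrpcapError):
    """A file or record violates the documented schema."""


class IntegrityError(TrpcapError):
    """A cross-reference does not resolve (referential integrity)."""


#: Default currency species used by the synthetic generator and suggested to
#: curators.  The authoritative currency call for a loaded network is its
#: ``is_currency`` column; this set only seeds new networks.
DEFAULT_CURRENCY_NAMES = frozenset(
    {
        "h2o", "h", "o2", "co2", "nh3", "nh4",
        "atp", "adp", "pi", "ppi",
        "nad", "nadh", "nadp", "nadph", "coa",
    }
)

FORMAT_HEADER = "# trpcap-reference-network v1"

_ORIGINS = frozenset({"host", "microbe", "both", "unknown"})
_PATHWAYS = frozenset({"indole", "serotonin", "kynurenine"})


@dataclass(frozen=True)
class MetaboliteRecord:
    met_id: str
    name: str
    abbrev: str
    xrefs: tuple[tuple[str, str], ...] = ()
    is_currency: bool = False
    origin: str = "unknown"
    is_bioactive: bool = False

    def __post_init__(self) -> None:
        if not self.met_id:
            raise SchemaError("metabolite with empty met_id")
        if self.origin not in _ORIGINS:
            raise SchemaError(
                f"metabolite {self.met_id!r}: origin {self.origin!r} not in {sorted(_ORIGINS)}"
            )
        if self.is_currency and self.is_bioactive:
            raise SchemaError(
                f"metabolite {self.met_id!r} flagged both currency and bioactive"
            )


@dataclass(frozen=True)
class ReactionRecord:
    rxn_id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    reversible: bool = False
    enzymes: tuple[str, ...] = ()
    origin: str = "unknown"
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.rxn_id:
            raise SchemaError("reaction with empty rxn_id")
        if not self.substrates or not self.products:
            raise SchemaError(f"reaction {self.rxn_id!r}: empty substrate or product side")
        for side in (self.substrates, self.products):
            for met, coef in side:
                if coef < 0:
                    raise SchemaError(
                        f"reaction {self.rxn_id!r}: negative coefficient for {met!r}"
                    )
        subs = dict(self.substrates)
        prods = dict(self.products)
        both = {m for m in subs if m in prods and subs[m] == prods[m]}
        if both:
            raise SchemaError(
                f"reaction {self.rxn_id!r}: metabolites {sorted(both)} appear on both "
                "sides with identical coefficients"
            )
        if self.origin not in _ORIGINS:
            raise SchemaError(
                f"reaction {self.rxn_id!r}: origin {self.origin!r} not in {sorted(_ORIGINS)}"
            )

    @property
    def substrate_ids(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.substrates)

    @property
    def product_ids(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.products)


@dataclass
class ReferenceNetwork:
    """A validated reference network.

    ``metabolites`` and ``reactions`` are keyed by id; ``pathway_tags`` maps
    each reaction to one of the three branches.  Equality is content-based
    (dict order is ignored), so loading a row-shuffled file yields an equal
    network.
    """

    metabolites: dict[str, MetaboliteRecord]
    reactions: dict[str, ReactionRecord]
    root_met: str = "trp"
    pathway_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.root_met not in self.metabolites:
            raise IntegrityError(f"root metabolite {self.root_met!r} not in network")
        if self.metabolites[self.root_met].is_currency:
            raise SchemaError(f"root metabolite {self.root_met!r} is flagged as currency")
        for rxn in self.reactions.values():
            missing = (rxn.substrate_ids | rxn.product_ids) - self.metabolites.keys()
            if missing:
                raise IntegrityError(
                    f"reaction {rxn.rxn_id!r} references unknown metabolites {sorted(missing)}"
                )
        bad_tags = {
            r: t for r, t in self.pathway_tags.items() if t and t not in _PATHWAYS
        }
        if bad_tags:
            raise SchemaError(f"unknown pathway tags: {bad_tags}")
        unknown = self.pathway_tags.keys() - self.reactions.keys()
        if unknown:
            raise IntegrityError(f"pathway tags for unknown reactions {sorted(unknown)}")
        seen_abbrev: dict[str, str] = {}
        for met in self.metabolites.values():
            if not met.is_bioactive:
                continue
            if met.abbrev in seen_abbrev:
                raise SchemaError(
                    f"bioactive abbrev {met.abbrev!r} duplicated by "
                    f"{seen_abbrev[met.abbrev]!r} and {met.met_id!r}"
                )
            seen_abbrev[met.abbrev] = met.met_id

    # -- convenience -----------------------------------------------------
    @property
    def currency_ids(self) -> frozenset[str]:
        return frozenset(m for m, rec in self.metabolites.items() if rec.is_currency)

    @property
    def bioactive_ids(self) -> frozenset[str]:
        return frozenset(m for m, rec in self.metabolites.items() if rec.is_bioactive)

    def abbrev_of(self, met_id: str) -> str:
        return self.metabolites[met_id].abbrev


# ---------------------------------------------------------------------------
# File I/O
#
# Single TSV file with a versioned header line, then two sections introduced
# by "## metabolites" and "## reactions".  Lists are ";"-separated;
# stoichiometric sides use "met:coef;met:coef".
# ---------------------------------------------------------------------------

_MET_COLS = ["met_id", "name", "abbrev", "kegg", "modelseed", "bigg",
             "is_currency", "origin", "is_bioactive"]
_RXN_COLS = ["rxn_id", "substrates", "products", "reversible", "ec_list",
             "origin", "pathway_tag", "evidence_pmids"]


def _parse_bool(value: str, where: str) -> bool:
    if value in {"0", "1"}:
        return value == "1"
    raise SchemaError(f"{where}: boolean cell must be 0 or 1, got {value!r}")


def _parse_side(text: str, where: str) -> tuple[tuple[str, float], ...]:
    out = []
    for item in filter(None, (s.strip() for s in text.split(";"))):
        met, _, coef = item.partition(":")
        try:
            c = float(coef) if coef else 1.0
        except ValueError as exc:
            raise SchemaError(f"{where}: bad stoichiometry {item!r}") from exc
        out.append((met, c))
    return tuple(out)


def load_reference_network(path, root_met: str = "trp") -> ReferenceNetwork:
    """Load a reference network from its TSV serialization.

    Raises :class:`SchemaError` for malformed files or duplicate ids and
    :class:`IntegrityError` when a reaction references an unknown metabolite
    or the root is missing.  Loading is order-independent.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(FORMAT_HEADER):
        raise SchemaError(f"{path}: missing format header {FORMAT_HEADER!r}")
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in lines:
        if line.startswith("## "):
            current = sections.setdefault(line[3:].strip(), [])
        elif line.startswith("#") or current is None:
            continue
        elif line.strip():
            current.append(line)
    for needed in ("metabolites", "reactions"):
        if needed not in sections:
            raise SchemaError(f"{path}: missing section '## {needed}'")

    def read_table(name: str, cols: list[str]) -> pd.DataFrame:
        df = pd.read_csv(io.StringIO("\n".join(sections[name])), sep="\t",
                         dtype=str, keep_default_na=False)
        missing = set(cols) - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: {name} table missing columns {sorted(missing)}")
        return df

    mets_df = read_table("metabolites", _MET_COLS)
    rxns_df = read_table("reactions", _RXN_COLS)

    metabolites: dict[str, MetaboliteRecord] = {}
    for row in mets_df.itertuples(index=False):
        if row.met_id in metabolites:
            raise SchemaError(f"duplicate metabolite id {row.met_id!r}")
        xrefs = tuple(
            (ns, getattr(row, ns)) for ns in ("kegg", "modelseed", "bigg") if getattr(row, ns)
        )
        metabolites[row.met_id] = MetaboliteRecord(
            met_id=row.met_id, name=row.name, abbrev=row.abbrev, xrefs=xrefs,
            is_currency=_parse_bool(row.is_currency, f"metabolite {row.met_id}"),
            origin=row.origin,
            is_bioactive=_parse_bool(row.is_bioactive, f"metabolite {row.met_id}"),
        )

    reactions: dict[str, ReactionRecord] = {}
    pathway_tags: dict[str, str] = {}
    for row in rxns_df.itertuples(index=False):
        if row.rxn_id in reactions:
            raise SchemaError(f"duplicate reaction id {row.rxn_id!r}")
        reactions[row.rxn_id] = ReactionRecord(
            rxn_id=row.rxn_id,
            substrates=_parse_side(row.substrates, f"reaction {row.rxn_id}"),
            products=_parse_side(row.products, f"reaction {row.rxn_id}"),
            reversible=_parse_bool(row.reversible, f"reaction {row.rxn_id}"),
            enzymes=tuple(filter(None, row.ec_list.split(";"))),
            origin=row.origin,
            evidence=tuple(filter(None, row.evidence_pmids.split(";"))),
        )
        if row.pathway_tag:
            pathway_tags[row.rxn_id] = row.pathway_tag
    return ReferenceNetwork(metabolites, reactions, root_met=root_met,
                            pathway_tags=pathway_tags)


def save_reference_network(net: ReferenceNetwork, path) -> None:
    """Serialize a network to the documented TSV format."""
    lines = [FORMAT_HEADER, "## metabolites", "\t".join(_MET_COLS)]
    for met in net.metabolites.values():
        xrefs = dict(met.xrefs)
        lines.append("\t".join([
            met.met_id, met.name, met.abbrev,
            xrefs.get("kegg", ""), xrefs.get("modelseed", ""), xrefs.get("bigg", ""),
            str(int(met.is_currency)), met.origin, str(int(met.is_bioactive)),
        ]))
    lines += ["## reactions", "\t".join(_RXN_COLS)]
    for rxn in net.reactions.values():
        fmt = lambda side: ";".join(f"{m}:{c:g}" for m, c in side)
        lines.append("\t".join([
            rxn.rxn_id, fmt(rxn.substrates), fmt(rxn.products),
            str(int(rxn.reversible)), ";".join(rxn.enzymes), rxn.origin,
            net.pathway_tags.get(rxn.rxn_id, ""), ";".join(rxn.evidence),
        ]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Producibility queries
# ---------------------------------------------------------------------------

def producible_set(
    net: ReferenceNetwork,
    present_rxns,
    mode: str = "reachability",
) -> frozenset[str]:
    """Non-currency metabolites producible from the root given a reaction subset.

    ``mode="reachability"`` (default) iterates reactions to a fixed point; a
    reaction fires when all its non-currency substrates are reachable, with
    currency species assumed available and reversible reactions usable in
    both directions.  ``mode="presence"`` calls a metabolite producible
    whenever any present reaction emits it.  The root itself and currency
    species are never returned.
    """
    present = set(present_rxns)
    unknown = present - net.reactions.keys()
    if unknown:
        raise IntegrityError(f"unknown reaction ids in present_rxns: {sorted(unknown)}")
    currency = net.currency_ids

    if mode == "presence":
        out: set[str] = set()
        for rid in present:
            rxn = net.reactions[rid]
            out |= rxn.product_ids
            if rxn.reversible:
                out |= rxn.substrate_ids
        return frozenset(out - currency - {net.root_met})
    if mode != "reachability":
        raise ValueError(f"unknown mode {mode!r}")

    available = set(currency) | {net.root_met}
    pending = [
        (net.reactions[rid].substrate_ids, net.reactions[rid].product_ids)
        for rid in present
    ]
    pending += [
        (net.reactions[rid].product_ids, net.reactions[rid].substrate_ids)
        for rid in present
        if net.reactions[rid].reversible
    ]
    changed = True
    while changed and pending:
        changed = False
        still = []
        for subs, prods in pending:
            if subs - currency <= available:
                if not prods <= available:
                    available |= prods
                    changed = True
            else:
                still.append((subs, prods))
        pending = still
    return frozenset(available - currency - {net.root_met})


def subset_by_taxa(net: ReferenceNetwork, models) -> ReferenceNetwork:
    """Sub-network induced by the union of the models' matched reactions.

    Origin labels and pathway tags are preserved; the root metabolite is
    always retained so the result remains a valid network.  An empty model
    list yields an empty (root-only) network with a warning.
    """
    rxn_ids: set[str] = set()
    for model in models:
        rxn_ids |= set(model.matched_rxns)
    if not models:
        warnings.warn("subset_by_taxa: empty model list; returning root-only network")
    unknown = rxn_ids - net.reactions.keys()
    if unknown:
        raise IntegrityError(f"models carry unknown reaction ids {sorted(unknown)}")
    reactions = {r: net.reactions[r] for r in sorted(rxn_ids)}
    met_ids = {net.root_met}
    for rxn in reactions.values():
        met_ids |= rxn.substrate_ids | rxn.product_ids
    metabolites = {m: net.metabolites[m] for m in net.metabolites if m in met_ids}
    tags = {r: t for r, t in net.pathway_tags.items() if r in reactions}
    return ReferenceNetwork(metabolites, reactions, root_met=net.root_met,
                            pathway_tags=tags)


# ---------------------------------------------------------------------------
# Exports: bipartite metabolite/reaction graph, edge direction = flow
# ---------------------------------------------------------------------------

def _bipartite_graph(net: ReferenceNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for met in net.metabolites.values():
        g.add_node(met.met_id, kind="metabolite", name=met.name, abbrev=met.abbrev,
                   is_currency=int(met.is_currency), origin=met.origin,
                   is_bioactive=int(met.is_bioactive))
    for rxn in net.reactions.values():
        g.add_node(rxn.rxn_id, kind="reaction", origin=rxn.origin,
                   reversible=int(rxn.reversible),
                   pathway=net.pathway_tags.get(rxn.rxn_id, ""))
        for m, coef in rxn.substrates:
            g.add_edge(m, rxn.rxn_id, coef=coef)
            if rxn.reversible:
                g.add_edge(rxn.rxn_id, m, coef=coef)
        for m, coef in rxn.products:
            g.add_edge(rxn.rxn_id, m, coef=coef)
            if rxn.reversible:
                g.add_edge(m, rxn.rxn_id, coef=coef)
    return g


def export_graphml(net: ReferenceNetwork, path) -> None:
    nx.write_graphml(_bipartite_graph(net), path)


def export_sif(net: ReferenceNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in _bipartite_graph(net).edges:
            fh.write(f"{u}\tflow\t{v}\n")
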