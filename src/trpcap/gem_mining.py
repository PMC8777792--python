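"""Parse genome-scale metabolic models (GEMs) and map them onto the reference network.

A GEM (e.g. from the AGORA or EMBL collections) is an organism-level
reconstruction of reactions and metabolites distributed as SBML.  This module
extracts each model's reaction content, translates metabolite identifiers into
the reference namespace through a cross-reference table, and decides which
curated tryptophan reactions the organism carries.

Because GEM collections use different identifier dialects, reactions are
matched by *metabolite-set equality*: a GEM reaction matches a reference
reaction when, after id mapping and removal of currency species, its substrate
set and product set equal the reference reaction's (in either orientation when
one of the two is reversible).  Stoichiometric coefficients are ignored —
capability calls downstream are presence/absence.  A GEM species that touches
the tryptophan pathway but cannot be mapped blocks a match (conservative), and
such near-miss reactions are counted in ``unmatched_count``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .reference_network import IntegrityError, ReferenceNetwork, SchemaError

__all__ = [
    "LINEAGE_RANKS",
    "RawReaction",
    "RawGem",
    "IdMap",
    "GemModel",
    "parse_sbml",
    "match_to_reference",
    "merge_duplicates",
    "annotate_host",
    "models_table",
    "load_host_annotations",
]

LINEAGE_RANKS = ("phylum", "class", "order", "family", "genus", "species", "strain")

_COMPARTMENT_RE = re.compile(r"_(?:[a-z][a-z0-9]?)$")


@dataclass(frozen=True)
class RawReaction:
    rxn_id: str
    substrates: frozenset[str]  # compartment-stripped base ids
    products: frozenset[str]
    reversible: bool


@dataclass
class RawGem:
    model_id: str
    species: dict[str, set[str]]  # base id -> compartments observed
    reactions: list[RawReaction]


def _strip_compartment(met_id: str, compartment: str | None) -> tuple[str, str]:
    """Return (base id, compartment) with the trailing compartment suffix removed."""
    if compartment and met_id.endswith(f"_{compartment}"):
        return met_id[: -len(compartment) - 1], compartment
    m = _COMPARTMENT_RE.search(met_id)
    if m:
        return met_id[: m.start()], m.group(0)[1:]
    return met_id, compartment or ""


def parse_sbml(path) -> RawGem:
    """Parse an SBML document into a raw model (species, reactions, reversibility).

    Compartment suffixes such as ``_c``/``_e`` are recorded but stripped from
    ids for matching.  Malformed XML raises :class:`SchemaError`; a model with
    zero reactions parses with a warning.
    """
    import logging

    import cobra.io  # deferred: cobra import is heavy

    logging.getLogger("cobra.io.sbml").setLevel(logging.CRITICAL)  # toy models have no FBA objective
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # cobra raises CobraSBMLError on bad XML
            raise SchemaError(f"{path}: SBML parse failed: {exc}") from exc
    species: dict[str, set[str]] = {}
    for met in model.metabolites:
        base, comp = _strip_compartment(met.id, met.compartment)
        species.setdefault(base, set()).add(comp)
    reactions = []
    for rxn in model.reactions:
        subs, prods = set(), set()
        for met, coef in rxn.metabolites.items():
            base, _ = _strip_compartment(met.id, met.compartment)
            (subs if coef < 0 else prods).add(base)
        if not subs and not prods:
            continue
        reactions.append(
            RawReaction(rxn.id, frozenset(subs), frozenset(prods), rxn.reversibility)
        )
    if not reactions:
        warnings.warn(f"{path}: SBML model has no reactions")
    return RawGem(model_id=model.id or path.stem, species=species, reactions=reactions)


# ---------------------------------------------------------------------------
# Identifier cross-reference
# ---------------------------------------------------------------------------

@dataclass
class IdMap:
    """Bridge between GEM metabolite ids and reference ``met_id``s.

    Rows are (namespace, external_id, met_id); (namespace, external_id) pairs
    must be unique and an external id may not point at two different
    reference metabolites across namespaces.
    """

    rows: tuple[tuple[str, str, str], ...]
    _lookup: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen_pairs: set[tuple[str, str]] = set()
        lookup: dict[str, str] = {}
        for ns, ext, target in self.rows:
            if (ns, ext) in seen_pairs:
                raise SchemaError(f"idmap: duplicate entry ({ns!r}, {ext!r})")
            seen_pairs.add((ns, ext))
            if lookup.get(ext, target) != target:
                raise SchemaError(
                    f"idmap: external id {ext!r} maps to both {lookup[ext]!r} and {target!r}"
                )
            lookup[ext] = target
        self._lookup = lookup

    @classmethod
    def from_tsv(cls, path, net: ReferenceNetwork | None = None) -> "IdMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        needed = {"namespace", "external_id", "ref_id"}
        if not needed <= set(df.columns):
            raise SchemaError(f"{path}: idmap needs columns {sorted(needed)}")
        idmap = cls(tuple(df[["namespace", "external_id", "ref_id"]].itertuples(index=False, name=None)))
        if net is not None:
            idmap.validate(net)
        return idmap

    def validate(self, net: ReferenceNetwork) -> None:
        bad = set(self._lookup.values()) - net.metabolites.keys()
        if bad:
            raise IntegrityError(f"idmap targets not in reference network: {sorted(bad)}")

    def get(self, external_id: str) -> str | None:
        return self._lookup.get(external_id)


# ---------------------------------------------------------------------------
# Matched models
# ---------------------------------------------------------------------------

@dataclass
class GemModel:
    model_id: str
    source: str  # AGORA | EMBL | synthetic | both
    lineage: dict[str, str]
    human_gut: bool = False
    mouse_gut: bool = False
    matched_rxns: frozenset[str] = frozenset()
    unmatched_count: int = 0

    def __post_init__(self) -> None:
        self.lineage = {r: self.lineage.get(r, "") for r in LINEAGE_RANKS}
        # species-level models become a pseudo-strain named after the species
        if self.lineage["species"] and not self.lineage["strain"]:
            self.lineage["strain"] = self.lineage["species"]
        if self.lineage["species"] and not self.lineage["genus"]:
            raise SchemaError(
                f"model {self.model_id!r}: species set but genus empty"
            )

    @property
    def genus(self) -> str:
        return self.lineage["genus"]


def _mapped_side(side: frozenset[str], idmap: IdMap, currency: frozenset[str]) -> frozenset[str]:
    """Map a reaction side into the reference namespace.

    Unmapped species are kept as ``?``-prefixed sentinels so that a reaction
    carrying an unknown non-currency species can never satisfy set equality.
    """
    out = set()
    for base in side:
        target = idmap.get(base)
        if target is None:
            out.add("?" + base)
        elif target not in currency:
            out.add(target)
    return frozenset(out)


def match_to_reference(
    raw: RawGem,
    idmap: IdMap,
    net: ReferenceNetwork,
    lineage: dict[str, str] | None = None,
    source: str = "synthetic",
) -> GemModel:
    """Decide which reference reactions a parsed GEM carries.

    ``matched_rxns`` holds every reference reaction whose non-currency
    substrate and product sets equal those of some mapped GEM reaction
    (orientation may flip when either reaction is reversible).
    ``unmatched_count`` counts GEM reactions that touch at least one mapped
    tryptophan-pathway metabolite yet match nothing — a gauge of how much of
    the organism's tryptophan chemistry falls outside the curation.
    """
    currency = net.currency_ids
    ref_sides = {
        rid: (
            frozenset(r.substrate_ids - currency),
            frozenset(r.product_ids - currency),
            r.reversible,
        )
        for rid, r in net.reactions.items()
    }
    matched: set[str] = set()
    unmatched = 0
    for rxn in raw.reactions:
        subs = _mapped_side(rxn.substrates, idmap, currency)
        prods = _mapped_side(rxn.products, idmap, currency)
        touches = any(not m.startswith("?") for m in subs | prods)
        hits = {
            rid
            for rid, (rsub, rprod, rrev) in ref_sides.items()
            if (subs, prods) == (rsub, rprod)
            or ((rxn.reversible or rrev) and (prods, subs) == (rsub, rprod))
        }
        if hits:
            matched |= hits
        elif touches:
            unmatched += 1
    return GemModel(
        model_id=raw.model_id,
        source=source,
        lineage=dict(lineage or {}),
        matched_rxns=frozenset(matched),
        unmatched_count=unmatched,
    )


def merge_duplicates(models: list[GemModel]) -> list[GemModel]:
    """Merge models that describe the same strain.

    Models sharing an identical strain-level lineage collapse to one entry:
    matched reactions are unioned, host flags OR-ed, and the source recorded
    as ``both`` when the duplicates came from different collections.  The
    same strain name under conflicting higher-rank lineages is an error.
    The result is sorted by model id; the operation is idempotent and
    order-independent.
    """
    by_strain: dict[str, list[GemModel]] = {}
    for m in models:
        key = m.lineage["strain"] or m.model_id
        by_strain.setdefault(key, []).append(m)
    out: list[GemModel] = []
    for strain, group in by_strain.items():
        lineages = {tuple(m.lineage[r] for r in LINEAGE_RANKS) for m in group}
        if len(lineages) > 1:
            raise IntegrityError(
                f"strain {strain!r} has conflicting lineages: {sorted(lineages)}"
            )
        group = sorted(group, key=lambda m: m.model_id)
        first = group[0]
        if len(group) == 1:
            out.append(first)
            continue
        sources = {m.source for m in group}
        merged = replace(
            first,
            source=first.source if len(sources) == 1 else "both",
            human_gut=any(m.human_gut for m in group),
            mouse_gut=any(m.mouse_gut for m in group),
            matched_rxns=frozenset().union(*(m.matched_rxns for m in group)),
            unmatched_count=max(m.unmatched_count for m in group),
        )
        out.append(merged)
    return sorted(out, key=lambda m: m.model_id)


def load_host_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"name", "rank", "human_gut", "mouse_gut"}
    if not needed <= set(df.columns):
        raise SchemaError(f"{path}: host table needs columns {sorted(needed)}")
    return df


def annotate_host(
    models: list[GemModel], table: pd.DataFrame
) -> tuple[list[GemModel], list[str]]:
    """Set host-habitat flags from an annotation table.

    The table is keyed by species or strain name; strain-level entries
    override species-level ones.  Returns the annotated models plus the list
    of model ids that matched no entry (their flags stay False).  Annotation
    keys matching no model only produce a warning.
    """
    entries: dict[tuple[str, str], tuple[bool, bool]] = {}
    for row in table.itertuples(index=False):
        entries[(row.rank, row.name)] = (
            str(row.human_gut) in {"1", "True", "true"},
            str(row.mouse_gut) in {"1", "True", "true"},
        )
    used: set[tuple[str, str]] = set()
    annotated: list[GemModel] = []
    unannotated: list[str] = []
    for m in models:
        hit = None
        for rank in ("strain", "species"):  # strain precedence
            key = (rank, m.lineage[rank])
            if m.lineage[rank] and key in entries:
                used.add(key)
                if hit is None:
                    hit = entries[key]
        if hit is None:
            unannotated.append(m.model_id)
            annotated.append(replace(m, human_gut=False, mouse_gut=False))
        else:
            annotated.append(replace(m, human_gut=hit[0], mouse_gut=hit[1]))
    unused = entries.keys() - used
    if unused:
        warnings.warn(f"host annotations matching no model: {sorted(unused)}")
    return annotated, unannotated


def models_table(models: list[GemModel]) -> pd.DataFrame:
    """Summary table (one row per model) for TSV export."""
    rows = []
    for m in models:
        row = {"model_id": m.model_id, "source": m.source}
        row.update({r: m.lineage[r] for r in LINEAGE_RANKS})
        row.update(
            human_gut=int(m.human_gut),
            mouse_gut=int(m.mouse_gut),
            n_matched=len(m.matched_rxns),
            n_unmatched=m.unmatched_count,
            matched_rxns=";".join(sorted(m.matched_rxns)),
        )
        rows.append(row)
    return pd.DataFrame(rows)
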