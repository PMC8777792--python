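"""Synthetic fixtures for every pipeline stage, with known ground truth.

The hosted curation database and the case-study datasets behind this method
are not redistributable, so validation rests on simulation: every generator
here is a pure function of a :class:`SimSpec` and its seed, and each returns
the ground truth alongside the files/objects, so tests can check recovery
exactly.

What is emulated (and what is not): reference networks have the real
network's *shape* (a root, three tagged branches, currency species, at least
one multi-substrate reaction) at reduced size; GEMs are minimal SBML models
carrying a known reference-reaction subset plus decoy reactions in a foreign
id dialect with compartment suffixes; capability databases draw production
flags from the same logistic model the fitting stage assumes, with planted
genus/host log-odds; study abundances are Dirichlet-compositional with a
fold-change intervention on one genus, and pseudo-metabolomics tables are the
true potentials under multiplicative log-normal noise (mimicking LC-MS
intensity scatter without modelling spectra).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_network import (
    DEFAULT_CURRENCY_NAMES,
    MetaboliteRecord,
    ReactionRecord,
    ReferenceNetwork,
    save_reference_network,
)
from .capability_analysis import CapabilityMatrix
from .sample_prediction import AbundanceTable

__all__ = [
    "SimSpec",
    "gen_reference_network",
    "gen_random_network",
    "gen_gems",
    "GemSim",
    "gen_capability_db",
    "default_betas",
    "gen_study",
    "Study",
    "write_study",
]

_BRANCHES = ("indole", "serotonin", "kynurenine")
_EC_POOL = ("4.1.99.1", "2.6.1.27", "1.1.1.110", "4.2.1.-", "1.3.1.-", "4.1.1.28")


@dataclass(frozen=True)
class SimSpec:
    """All knobs for the synthetic generators (defaults = the study conditions)."""

    seed: int = 0
    # reference-network shape
    n_metabolites: int = 12
    n_reactions: int = 10
    n_currency: int = 2
    # GEM emulation
    n_gems: int = 50
    n_decoys: int = 2
    subset_rate: float = 0.6
    # capability database: planted log-odds
    n_genera: int = 13
    n_models_per_genus: int = 40
    # rare genera below the dominance cutoff: they form the regression baseline,
    # as the long tail of low-prevalence genera does in a real database
    n_rare_genera: int = 6
    n_models_per_rare_genus: int = 5
    metabolites: tuple[str, ...] = (
        "IA", "Indole", "IAAlD", "IAM", "IAA", "ILA", "IPA", "Tryptamine",
    )
    intercept: float = -2.0
    host_effect: float = 1.0
    strong_effect: float = 3.5
    n_strong: int = 2
    weak_sd: float = 0.3
    host_family: str = "mouse"
    # two-group study design (default: the 8 vs 8 cecal-sample scale)
    n_case: int = 8
    n_control: int = 8
    fold_change: float = 5.0
    target_genus: str | None = None
    target_metabolite: str | None = None
    dirichlet_alpha: float = 5.0
    metabolomics_noise_sd: float = 0.3

    def rng(self, stream: int) -> np.random.Generator:
        # independent, reproducible stream per generator
        return np.random.default_rng([self.seed, stream])

    def genera(self) -> list[str]:
        return [f"Genus{i:02d}" for i in range(self.n_genera)]


# ---------------------------------------------------------------------------
# Reference networks
# ---------------------------------------------------------------------------

def gen_reference_network(spec: SimSpec, out_path=None) -> ReferenceNetwork:
    """A connected network rooted at ``trp`` with three tagged branches.

    Guarantees: every non-currency metabolite is reachable from the root when
    all reactions are present; at least one reaction has two non-currency
    substrates; at least two currency species exist; the result passes full
    network validation (and round-trips through the TSV format when
    ``out_path`` is given).
    """
    if spec.n_metabolites < 5 or spec.n_reactions < 4:
        raise ValueError("need n_metabolites >= 5 and n_reactions >= 4")
    if spec.n_currency < 2:
        raise ValueError("need at least two currency species")
    n_chain = spec.n_metabolites - 1 - spec.n_currency
    if n_chain < len(_BRANCHES):
        raise ValueError("infeasible shape: fewer chain metabolites than branch tags")
    if spec.n_reactions < n_chain:
        raise ValueError(
            f"infeasible shape: {n_chain} metabolites need producers but only "
            f"{spec.n_reactions} reactions allowed"
        )
    rng = spec.rng(1)
    currency_pool = sorted(DEFAULT_CURRENCY_NAMES)
    metabolites: dict[str, MetaboliteRecord] = {
        "trp": MetaboliteRecord("trp", "L-tryptophan", "Trp", origin="both")
    }
    for i in range(spec.n_currency):
        cid = currency_pool[i % len(currency_pool)] if i < len(currency_pool) else f"cur{i:02d}"
        metabolites[cid] = MetaboliteRecord(cid, cid, cid.upper(), is_currency=True, origin="both")
    currency_ids = [m for m, r in metabolites.items() if r.is_currency]

    branches: dict[str, list[str]] = {b: [] for b in _BRANCHES}
    for i in range(n_chain):
        branch = _BRANCHES[i % len(_BRANCHES)]
        mid = f"m_{branch[:3]}{len(branches[branch]):02d}"
        branches[branch].append(mid)
        terminal_guess = i >= n_chain - len(_BRANCHES)
        bioactive = bool(terminal_guess or rng.random() < 0.5)
        metabolites[mid] = MetaboliteRecord(
            mid, mid, mid.upper(), is_currency=False,
            origin=str(rng.choice(["host", "microbe", "both"])),
            is_bioactive=bioactive,
        )

    reactions: dict[str, ReactionRecord] = {}
    tags: dict[str, str] = {}
    counter = 0

    def add_reaction(subs, prods, tag, reversible=None):
        nonlocal counter
        counter += 1
        rid = f"R{counter:02d}"
        if rng.random() < 0.5:
            subs = subs + [(str(rng.choice(currency_ids)), 1.0)]
        if rng.random() < 0.5:
            used = {m for m, _ in subs}
            free = [c for c in currency_ids if c not in used]
            if free:
                prods = prods + [(str(rng.choice(free)), 1.0)]
        reactions[rid] = ReactionRecord(
            rxn_id=rid,
            substrates=tuple(subs),
            products=tuple(prods),
            reversible=bool(rng.random() < 0.3) if reversible is None else reversible,
            enzymes=(str(rng.choice(_EC_POOL)),),
            origin=str(rng.choice(["host", "microbe", "both"])),
            evidence=(str(rng.integers(10_000_000, 35_000_000)),),
        )
        tags[rid] = tag
        return rid

    for branch, mets in branches.items():
        prev = "trp"
        for met in mets:
            add_reaction([(prev, 1.0)], [(met, 1.0)], branch)
            prev = met

    extras = spec.n_reactions - n_chain
    non_currency = [m for b in branches.values() for m in b]
    if extras == 0:
        # fold a co-substrate from another branch into the last chain reaction
        last_id = f"R{counter:02d}"
        last = reactions[last_id]
        co = branches[_BRANCHES[0]][0]
        if co not in last.substrate_ids:
            reactions[last_id] = ReactionRecord(
                rxn_id=last_id,
                substrates=last.substrates + ((co, 1.0),),
                products=last.products,
                reversible=last.reversible,
                enzymes=last.enzymes,
                origin=last.origin,
                evidence=last.evidence,
            )
    else:
        # first extra: guaranteed multi-substrate combiner between branches
        s1, s2 = branches[_BRANCHES[0]][-1], branches[_BRANCHES[1]][-1]
        add_reaction([(s1, 1.0), (s2, 1.0)], [(branches[_BRANCHES[2]][-1], 1.0)],
                     _BRANCHES[2], reversible=False)
        for _ in range(extras - 1):
            a, b = rng.choice(non_currency, size=2, replace=False)
            add_reaction([(str(a), 1.0)], [(str(b), 1.0)], str(rng.choice(_BRANCHES)))

    net = ReferenceNetwork(metabolites, reactions, root_met="trp", pathway_tags=tags)
    if out_path is not None:
        save_reference_network(net, out_path)
    return net


def gen_random_network(
    rng: np.random.Generator,
    max_metabolites: int = 15,
    max_reactions: int = 20,
) -> ReferenceNetwork:
    """Unconstrained random network for fuzzing reachability queries.

    Unlike :func:`gen_reference_network` there is no connectivity guarantee:
    reactions draw random disjoint substrate/product sets, currency flags are
    random, and whole regions may be unreachable — exactly the cases a
    reachability oracle must agree on.
    """
    n_mets = int(rng.integers(5, max_metabolites + 1))
    n_rxns = int(rng.integers(4, max_reactions + 1))
    met_ids = [f"M{i:02d}" for i in range(n_mets)]
    metabolites = {}
    for i, m in enumerate(met_ids):
        currency = bool(i > 0 and rng.random() < 0.2)  # root stays non-currency
        bioactive = (not currency) and bool(rng.random() < 0.5)
        metabolites[m] = MetaboliteRecord(m, m, m, is_currency=currency,
                                          is_bioactive=bioactive)
    reactions = {}
    for j in range(n_rxns):
        k_s = int(rng.integers(1, 4))
        k_p = int(rng.integers(1, 4))
        picks = rng.choice(met_ids, size=min(k_s + k_p, n_mets), replace=False)
        subs, prods = picks[:k_s], picks[k_s:]
        if len(prods) == 0:
            continue
        rid = f"R{j:02d}"
        reactions[rid] = ReactionRecord(
            rxn_id=rid,
            substrates=tuple((str(m), 1.0) for m in subs),
            products=tuple((str(m), 1.0) for m in prods),
            reversible=bool(rng.random() < 0.3),
        )
    return ReferenceNetwork(metabolites, reactions, root_met=met_ids[0])


# ---------------------------------------------------------------------------
# Synthetic GEMs (SBML + id map + taxonomy + host annotations)
# ---------------------------------------------------------------------------

@dataclass
class GemSim:
    sbml_dir: Path
    idmap_path: Path
    taxonomy_path: Path
    hosts_path: Path
    truth: dict[str, frozenset[str]]  # model_id -> planted reference-reaction subset
    lineages: dict[str, dict[str, str]]


def _lineage_for(i: int, spec: SimSpec) -> dict[str, str]:
    genus = spec.genera()[i % spec.n_genera]
    g_idx = i % spec.n_genera
    species = f"{genus} sp{i // spec.n_genera:02d}"
    return {
        "phylum": f"Phylum{g_idx % 4}",
        "class": f"Class{g_idx % 4}",
        "order": f"Order{g_idx % 6}",
        "family": f"Family{g_idx % 8}",
        "genus": genus,
        "species": species,
        "strain": f"{species} strain{i:03d}",
    }


def gen_gems(spec: SimSpec, net: ReferenceNetwork, out_dir) -> GemSim:
    """Write synthetic SBML models with known reference-reaction subsets.

    Each model carries a random subset of reference reactions translated into
    a foreign id dialect (``x_<met_id>_c``, compartment suffix included) plus
    ``n_decoys`` decoy reactions over species absent from the id map; the id
    map, taxonomy and host-annotation TSVs the mining pipeline consumes are
    written alongside.  Matching a generated model against the reference must
    recover its subset exactly.
    """
    import logging

    import cobra
    import cobra.io

    logging.getLogger("cobra.io.sbml").setLevel(logging.CRITICAL)  # toy models have no FBA objective
    rng = spec.rng(2)
    out_dir = Path(out_dir)
    sbml_dir = out_dir / "sbml"
    sbml_dir.mkdir(parents=True, exist_ok=True)
    rxn_ids = sorted(net.reactions)
    truth: dict[str, frozenset[str]] = {}
    lineages: dict[str, dict[str, str]] = {}
    host_rows: dict[str, tuple[str, int, int]] = {}

    for i in range(spec.n_gems):
        model_id = f"synth{i:03d}"
        subset = frozenset(r for r in rxn_ids if rng.random() < spec.subset_rate)
        truth[model_id] = subset
        lineage = _lineage_for(i, spec)
        lineages[model_id] = lineage
        if lineage["species"] not in host_rows:
            host_rows[lineage["species"]] = (
                "species", int(rng.random() < 0.7), int(rng.random() < 0.4)
            )
        model = cobra.Model(model_id)
        mets: dict[str, "cobra.Metabolite"] = {}

        def met_for(ext_base: str) -> "cobra.Metabolite":
            mid = f"{ext_base}_c"
            if mid not in mets:
                mets[mid] = cobra.Metabolite(mid, compartment="c")
            return mets[mid]

        rxns = []
        for j, rid in enumerate(sorted(subset)):
            ref = net.reactions[rid]
            rxn = cobra.Reaction(f"RX{j:03d}")
            stoich: dict = {}
            for m, c in ref.substrates:
                stoich[met_for(f"x_{m}")] = stoich.get(met_for(f"x_{m}"), 0) - c
            for m, c in ref.products:
                stoich[met_for(f"x_{m}")] = stoich.get(met_for(f"x_{m}"), 0) + c
            rxn.add_metabolites(stoich)
            rxn.lower_bound = -1000.0 if ref.reversible else 0.0
            rxn.upper_bound = 1000.0
            rxns.append(rxn)
        for j in range(spec.n_decoys):
            rxn = cobra.Reaction(f"DECOY{j:02d}")
            rxn.add_metabolites(
                {met_for(f"decoy{2 * j}"): -1.0, met_for(f"decoy{2 * j + 1}"): 1.0}
            )
            rxn.lower_bound, rxn.upper_bound = 0.0, 1000.0
            rxns.append(rxn)
        model.add_reactions(rxns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(model, str(sbml_dir / f"{model_id}.xml"))

    idmap_path = out_dir / "idmap.tsv"
    pd.DataFrame(
        [("synthetic", f"x_{m}", m) for m in sorted(net.metabolites)],
        columns=["namespace", "external_id", "ref_id"],
    ).to_csv(idmap_path, sep="\t", index=False)

    taxonomy_path = out_dir / "taxonomy.tsv"
    tax = pd.DataFrame(
        [{"model_id": mid, **lin} for mid, lin in lineages.items()]
    )
    tax.to_csv(taxonomy_path, sep="\t", index=False)

    hosts_path = out_dir / "hosts.tsv"
    pd.DataFrame(
        [
            {"name": name, "rank": rank, "human_gut": hg, "mouse_gut": mg,
             "pmid": "00000000"}
            for name, (rank, hg, mg) in sorted(host_rows.items())
        ]
    ).to_csv(hosts_path, sep="\t", index=False)

    return GemSim(
        sbml_dir=sbml_dir,
        idmap_path=idmap_path,
        taxonomy_path=taxonomy_path,
        hosts_path=hosts_path,
        truth=truth,
        lineages=lineages,
    )


# ---------------------------------------------------------------------------
# Capability databases with planted effects
# ---------------------------------------------------------------------------

def default_betas(spec: SimSpec, rng: np.random.Generator | None = None) -> dict:
    """Planted log-odds per metabolite: a few strong producer genera, weak rest.

    Mirrors the structure of real odds-ratio tables, where one or two genera
    dominate a metabolite (odds ratios in the hundreds) while most sit near 1.
    """
    rng = spec.rng(3) if rng is None else rng
    genera = spec.genera()
    betas = {}
    for met in spec.metabolites:
        strong = rng.choice(spec.n_genera, size=spec.n_strong, replace=False)
        genus_effects = {}
        for gi, g in enumerate(genera):
            if gi in strong:
                genus_effects[g] = spec.strong_effect
            else:
                genus_effects[g] = float(rng.normal(0.0, spec.weak_sd))
        betas[met] = {
            "intercept": spec.intercept,
            "host": spec.host_effect,
            "genus": genus_effects,
        }
    return betas


def gen_capability_db(
    spec: SimSpec, betas: dict | None = None
) -> tuple[CapabilityMatrix, dict]:
    """Draw a capability database from the logistic generative model.

    ``produces(model, M) ~ Bernoulli(logistic(b0 + b_genus + b_host * flag))``
    with the host flag Bernoulli(1/2) per model.  Besides the dominant
    genera, a pool of rare genera (few models each, genus effect 0) emulates
    the long low-prevalence tail that forms the regression baseline in a real
    database.  Returns the matrix plus the planted truth for recovery checks.
    """
    rng = spec.rng(4)
    if betas is None:
        betas = default_betas(spec)
    genera = spec.genera()
    host_col = f"{spec.host_family}_gut"
    other_col = "human_gut" if host_col == "mouse_gut" else "mouse_gut"
    rows, meta_rows, index = [], [], []
    roster = [(g, spec.n_models_per_genus, gi // 4) for gi, g in enumerate(genera)]
    roster += [
        (f"Rare{r:02d}", spec.n_models_per_rare_genus, r % 4)
        for r in range(spec.n_rare_genera)
    ]
    for g, n_models, phylum_idx in roster:
        for j in range(n_models):
            host_flag = bool(rng.random() < 0.5)
            row = {}
            for met in spec.metabolites:
                b = betas[met]
                eta = (b["intercept"] + b["genus"].get(g, 0.0)
                       + (b["host"] if host_flag else 0.0))
                row[met] = bool(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            rows.append(row)
            meta = {
                "phylum": f"Phylum{phylum_idx}", "class": f"Class{phylum_idx}",
                "order": "Order0", "family": "Family0",
                "genus": g, "species": f"{g} sp", "strain": f"{g} str{j:03d}",
            }
            meta.update(source="synthetic")
            meta[host_col] = host_flag
            meta[other_col] = False
            meta_rows.append(meta)
            index.append(f"db_{g}_{j:03d}")
    idx = pd.Index(index, name="model_id")
    values = pd.DataFrame(rows, index=idx, columns=list(spec.metabolites))
    meta = pd.DataFrame(meta_rows, index=idx)[
        ["phylum", "class", "order", "family", "genus", "species", "strain",
         "source", "human_gut", "mouse_gut"]
    ]
    cap = CapabilityMatrix(values=values, meta=meta)
    return cap, {"betas": betas, "host_family": spec.host_family}


def true_probability_matrix(spec: SimSpec, betas: dict) -> pd.DataFrame:
    """Genera x metabolites matrix of the planted production probabilities (host flag on)."""
    genera = spec.genera()
    out = pd.DataFrame(index=genera, columns=list(spec.metabolites), dtype=float)
    for met in spec.metabolites:
        b = betas[met]
        for g in genera:
            out.loc[g, met] = 1.0 / (1.0 + np.exp(-(b["intercept"] + b["genus"][g] + b["host"])))
    return out


# ---------------------------------------------------------------------------
# Two-group studies
# ---------------------------------------------------------------------------

@dataclass
class Study:
    abundance: AbundanceTable
    groups: pd.Series
    true_potential: pd.DataFrame
    metabolomics: pd.DataFrame
    target_genus: str
    target_metabolite: str


def gen_study(spec: SimSpec, prob_matrix: pd.DataFrame, stream: int = 5) -> Study:
    """Simulate a case/control 16S study with a fold-change on one genus.

    Case samples have the target genus's relative abundance multiplied by
    ``fold_change`` before renormalisation (fold 1 is the null: both groups
    are exchangeable draws).  ``prob_matrix`` supplies P(M, G) — either the
    planted truth or a fitted bundle's probabilities.  The pseudo-metabolomics
    table is the true potential with multiplicative log-normal noise.
    """
    if spec.fold_change <= 0:
        raise ValueError("fold change must be positive")
    rng = spec.rng(stream)
    genera = list(prob_matrix.index)
    target_met = spec.target_metabolite
    if target_met is None:
        spread = prob_matrix.max(axis=0) - prob_matrix.median(axis=0)
        target_met = str(spread.idxmax())
    target_genus = spec.target_genus
    if target_genus is None:
        target_genus = str(prob_matrix[target_met].idxmax())
    n = spec.n_case + spec.n_control
    A = rng.dirichlet(np.full(len(genera), spec.dirichlet_alpha), size=n)
    samples = [f"case{i:02d}" for i in range(spec.n_case)] + [
        f"ctrl{i:02d}" for i in range(spec.n_control)
    ]
    ab = pd.DataFrame(A, index=pd.Index(samples, name="sample"), columns=genera)
    t_idx = genera.index(target_genus)
    ab.iloc[: spec.n_case, t_idx] *= spec.fold_change
    ab = ab.div(ab.sum(axis=1), axis=0)
    groups = pd.Series(
        ["case"] * spec.n_case + ["control"] * spec.n_control, index=ab.index, name="group"
    )
    true_pot = ab @ prob_matrix.loc[genera]
    noise = rng.lognormal(mean=0.0, sigma=spec.metabolomics_noise_sd, size=true_pot.shape)
    metabolomics = true_pot * noise
    return Study(
        abundance=AbundanceTable(values=ab, groups=groups, kind="relative"),
        groups=groups,
        true_potential=true_pot,
        metabolomics=metabolomics,
        target_genus=target_genus,
        target_metabolite=target_met,
    )


def write_study(study: Study, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out_dir / "abundance.tsv",
        "metadata": out_dir / "metadata.tsv",
        "metabolomics": out_dir / "metabolomics.tsv",
    }
    study.abundance.values.to_csv(paths["abundance"], sep="\t")
    study.groups.to_frame().to_csv(paths["metadata"], sep="\t")
    study.metabolomics.to_csv(paths["metabolomics"], sep="\t")
    return paths
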