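"""trpcap: tryptophan-degradation capability mining and 16S-based metabolite prediction.

The pipeline, in the order the method runs:

1. :mod:`trpcap.reference_network` — the curated tryptophan reaction network
   and producibility (reachability) queries against reaction subsets.
2. :mod:`trpcap.gem_mining` — SBML genome-scale models mapped onto the
   reference network, with taxonomy and host-habitat annotation.
3. :mod:`trpcap.capability_analysis` — the taxa x metabolites capability
   matrix, genus prevalence, and metabolic-vs-phylogenetic dendrograms.
4. :mod:`trpcap.metabolite_models` — per-metabolite Bayesian logistic
   regression (MAP + Laplace), AIC ranking, PSIS-LOO, ROC validation.
5. :mod:`trpcap.sample_prediction` — per-sample production potentials from
   genus abundances, TSS normalisation, differential calls, concordance.
6. :mod:`trpcap.synthetic_data` — seeded generators with ground truth for
   every stage.
"""

from importlib.resources import files as _files

from .reference_network import (
    TrpcapError,
    SchemaError,
    IntegrityError,
    MetaboliteRecord,
    ReactionRecord,
    ReferenceNetwork,
    load_reference_network,
    save_reference_network,
    producible_set,
    subset_by_taxa,
)
from .gem_mining import (
    GemModel,
    IdMap,
    RawGem,
    parse_sbml,
    match_to_reference,
    merge_duplicates,
    annotate_host,
)
from .capability_analysis import (
    CapabilityMatrix,
    Dendrogram,
    build_capability_matrix,
    genus_prevalence,
    metabolic_distance,
    cluster_complete,
    entanglement,
)
from .metabolite_models import (
    PriorSpec,
    DesignMatrix,
    MetaboliteModel,
    dominant_taxa,
    build_design,
    fit_bayes_logit,
    wald_tests,
    aic_rank,
    psis_loo,
    roc_holdout,
    save_models,
    load_models,
)
from .sample_prediction import (
    AbundanceTable,
    PotentialTable,
    genus_probability,
    sample_potentials,
    tss_normalize,
    differential_metabolites,
    concordance_report,
)
from .synthetic_data import SimSpec

__version__ = "0.1.0"


def bundled_reference_path():
    """Path to the shipped synthetic reference-network fixture (12 metabolites, 10 reactions)."""
    return _files("trpcap").joinpath("data/synthetic_reference_network.tsv")
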