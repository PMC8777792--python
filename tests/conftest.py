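from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trpcap import bundled_reference_path, load_reference_network
from trpcap.gem_mining import GemModel
from trpcap.capability_analysis import CapabilityMatrix
from trpcap.gem_mining import LINEAGE_RANKS


@pytest.fixture(scope="session")
def fixture_net():
    return load_reference_network(bundled_reference_path())


def make_model(model_id, genus="Bacteroides", rxns=(), human=True, mouse=False,
               species=None, strain=None, source="synthetic"):
    species = species or f"{genus} testii"
    return GemModel(
        model_id=model_id,
        source=source,
        lineage={
            "phylum": "TestPhylum",
            "genus": genus,
            "species": species,
            "strain": strain or f"{species} {model_id}",
        },
        human_gut=human,
        mouse_gut=mouse,
        matched_rxns=frozenset(rxns),
    )


def make_capability(rows: dict[str, dict], genera: dict[str, str],
                    mouse_flags: dict[str, bool] | None = None,
                    columns=None) -> CapabilityMatrix:
    """Hand-built capability matrix: rows model_id -> {met: bool}."""
    index = pd.Index(list(rows), name="model_id")
    values = pd.DataFrame([rows[m] for m in index], index=index)
    if columns is not None:
        values = values.reindex(columns=columns, fill_value=False)
    meta = pd.DataFrame(index=index)
    for rank in LINEAGE_RANKS:
        meta[rank] = ""
    meta["genus"] = [genera[m] for m in index]
    meta["species"] = meta["genus"] + " sp"
    meta["strain"] = meta["species"] + " " + meta.index
    meta["source"] = "synthetic"
    meta["human_gut"] = True
    meta["mouse_gut"] = [bool((mouse_flags or {}).get(m, False)) for m in index]
    return CapabilityMatrix(values=values.astype(bool), meta=meta)
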