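"""From a 16S genus abundance table to per-sample metabolite production potentials.

The prediction step is deliberately simple and linear: for sample *s* and
metabolite *M* the raw production potential is

    T(s, M) = sum_G P(M, G) * a(s, G)

where ``a`` is the genus abundance and ``P(M, G)`` the fitted per-genus
production probability for the requested host.  Count tables are converted to
relative abundances per sample first, so potentials are comparable across
samples; tables already given as proportions are used as-is, keeping raw
potentials exactly linear in the supplied abundances.  Each sample's
metabolite profile is then total-sum-scaled (TSS, rows sum to one) to put
predictions on the same compositional footing as metabolomics intensities.

Genera absent from the training database contribute the host-baseline
probability (intercept + host effect) rather than zero, and their abundance
mass is reported per sample so users can judge how far outside the database a
community falls.  Group comparisons use a two-sided Mann-Whitney U per
metabolite with Benjamini-Hochberg correction across metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .reference_network import TrpcapError
from .metabolite_models import INTERCEPT, MetaboliteModel

__all__ = [
    "AbundanceTable",
    "PotentialTable",
    "load_abundance",
    "genus_probability",
    "probability_matrix",
    "sample_potentials",
    "tss_normalize",
    "differential_metabolites",
    "concordance_report",
    "ConcordanceReport",
]


@dataclass
class AbundanceTable:
    """Samples x genera abundances with optional group labels.

    ``kind`` is ``"counts"`` (row-normalised before prediction) or
    ``"relative"`` (used as given).
    """

    values: pd.DataFrame
    groups: pd.Series | None = None
    kind: str = "counts"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance table contains negative cells")
        if any(not str(g) for g in self.values.columns):
            raise ValueError("abundance table has an empty genus name")
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.index)
            if self.groups.isna().any():
                missing = list(self.values.index[self.groups.isna()])
                raise ValueError(f"samples without a group label: {missing}")


def load_abundance(abundance_path, meta_path=None, kind: str = "counts") -> AbundanceTable:
    values = pd.read_csv(abundance_path, sep="\t", index_col=0)
    groups = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if "group" not in meta.columns:
            raise TrpcapError(f"{meta_path}: metadata needs a 'group' column")
        groups = meta["group"].astype(str)
    return AbundanceTable(values=values, groups=groups, kind=kind)


@dataclass
class PotentialTable:
    """Raw and TSS-normalised production potentials plus coverage flags."""

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None
    unseen_genera: tuple[str, ...] = ()
    unseen_mass: pd.Series | None = None
    zero_rows: tuple[str, ...] = ()


def genus_probability(model: MetaboliteModel, genus: str, host: str) -> tuple[float, bool]:
    """P(M, G) = logistic(beta_0 + beta_G + beta_host); returns (p, unseen flag).

    A genus without its own indicator column (not dominant in training, or
    entirely novel) falls back to the host baseline logistic(beta_0 +
    beta_host) with the flag set.
    """
    if host != model.host_family:
        raise TrpcapError(
            f"model for {model.metabolite!r} was fitted for host "
            f"{model.host_family!r}, requested {host!r}"
        )
    beta = pd.Series(model.beta, index=model.columns)
    eta = beta.get(INTERCEPT, 0.0) + beta.get(f"{host}_gut", 0.0)
    unseen = genus not in beta.index
    if not unseen:
        eta += beta[genus]
    return float(expit(eta)), unseen


def probability_matrix(
    models: dict[str, MetaboliteModel], genera, host: str
) -> tuple[pd.DataFrame, list[str]]:
    """Genera x metabolites matrix of P(M, G); second return is the unseen-genus list."""
    mets = sorted(models)
    probs = pd.DataFrame(index=list(genera), columns=mets, dtype=float)
    unseen: set[str] = set()
    for g in genera:
        for met in mets:
            p, flag = genus_probability(models[met], g, host)
            probs.loc[g, met] = p
            if flag:
                unseen.add(g)
    return probs, sorted(unseen)


def sample_potentials(
    models: dict[str, MetaboliteModel],
    ab: AbundanceTable,
    host: str,
    metabolites: list[str] | None = None,
) -> PotentialTable:
    """Accumulated production potential T(s, M) = sum_G P(M, G) * a(s, G).

    Count tables are TSS-normalised per sample first; relative tables enter
    as given (so raw potentials are exactly linear in them).  All-zero
    samples yield zero potentials with a warning.
    """
    use = dict(models) if metabolites is None else {}
    if metabolites is not None:
        missing = [m for m in metabolites if m not in models]
        if missing:
            raise KeyError(f"model bundle lacks metabolites {missing}")
        use = {m: models[m] for m in metabolites}
    A = ab.values.astype(float)
    row_sums = A.sum(axis=1)
    zero_rows = tuple(A.index[row_sums == 0])
    if zero_rows:
        warnings.warn(f"samples with all-zero abundance: {list(zero_rows)}")
    if ab.kind == "counts":
        A = A.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    probs, unseen = probability_matrix(use, A.columns, host)
    raw = A @ probs
    raw.index.name = "sample"
    if ab.kind == "counts":
        mass_basis = A
    else:
        mass_basis = A.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    unseen_mass = mass_basis[list(unseen)].sum(axis=1) if unseen else pd.Series(0.0, index=A.index)
    return PotentialTable(
        raw=raw,
        unseen_genera=tuple(unseen),
        unseen_mass=unseen_mass.rename("unseen_mass"),
        zero_rows=zero_rows,
    )


def tss_normalize(pot: PotentialTable, axis: str = "sample") -> PotentialTable:
    """Total-sum scaling of potentials.

    Default axis ``"sample"``: each sample's metabolite profile sums to one.
    ``axis="metabolite"`` instead scales each metabolite across samples.
    Zero-sum rows (or columns) are left at zero and flagged.
    """
    raw = pot.raw
    if axis == "sample":
        sums = raw.sum(axis=1)
        normalized = raw.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
        zero = tuple(raw.index[sums == 0])
    elif axis == "metabolite":
        sums = raw.sum(axis=0)
        normalized = raw.div(sums.replace(0, np.nan), axis=1).fillna(0.0)
        zero = tuple(raw.columns[sums == 0])
    else:
        raise ValueError(f"axis must be 'sample' or 'metabolite', got {axis!r}")
    return PotentialTable(
        raw=raw,
        normalized=normalized,
        unseen_genera=pot.unseen_genera,
        unseen_mass=pot.unseen_mass,
        zero_rows=tuple(sorted(set(pot.zero_rows) | set(zero))),
    )


def differential_metabolites(
    pot: PotentialTable,
    groups: pd.Series,
    group_pair: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per metabolite on TSS potentials, BH-corrected.

    ``group_pair = (case, control)`` orients the direction column (sign of the
    case-minus-control median difference).  Metabolites constant across all
    samples get p = 1 with a tie flag.  Requires >= 3 samples per group.
    """
    table = pot.normalized if pot.normalized is not None else tss_normalize(pot).normalized
    groups = groups.reindex(table.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    levels = sorted(groups.unique()) if group_pair is None else list(group_pair)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    case, control = levels
    a = table.loc[groups == case]
    b = table.loc[groups == control]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 samples per group")
    rows = []
    for met in table.columns:
        x, y = a[met].to_numpy(), b[met].to_numpy()
        tie = np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0])
        if tie:
            u, p = len(x) * len(y) / 2, 1.0
        else:
            u, p = mannwhitneyu(x, y, alternative="two-sided")
        diff = float(np.median(x) - np.median(y))
        rows.append(
            {
                "metabolite": met,
                "median_case": float(np.median(x)),
                "median_control": float(np.median(y)),
                "U": float(u),
                "p": float(p),
                "direction": int(np.sign(diff)),
                "all_tied": bool(tie),
            }
        )
    out = pd.DataFrame(rows).set_index("metabolite")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out[["median_case", "median_control", "U", "p", "q", "direction",
                "significant", "all_tied"]]


@dataclass
class ConcordanceReport:
    table: pd.DataFrame
    prediction_only: tuple[str, ...]
    metabolomics_only: tuple[str, ...]
    n_shared_samples: int


def concordance_report(
    pot: PotentialTable,
    metabolomics: pd.DataFrame,
    groups: pd.Series | None = None,
    group_pair: tuple[str, str] | None = None,
) -> ConcordanceReport:
    """Compare predicted potentials against measured metabolite intensities.

    For each shared metabolite: Spearman rank correlation across shared
    samples, and (when group labels are supplied) whether the predicted and
    measured case-vs-control median directions agree.  Both tables are
    row-TSS-scaled over the *shared* metabolite set first, so predictions and
    intensities are compared on the same compositional basis (intensity units
    are arbitrary per sample).  Metabolites present in only one source are
    listed separately rather than dropped silently.
    """
    shared_mets = [m for m in pot.raw.columns if m in metabolomics.columns]
    if not shared_mets:
        raise TrpcapError("no shared metabolites between prediction and metabolomics")
    shared_samples = pot.raw.index.intersection(metabolomics.index)

    def tss_rows(df: pd.DataFrame) -> pd.DataFrame:
        sums = df.sum(axis=1)
        return df.div(sums.replace(0, np.nan), axis=0).fillna(0.0)

    pred = tss_rows(pot.raw.loc[shared_samples, shared_mets])
    meas = tss_rows(metabolomics.loc[shared_samples, shared_mets].astype(float))

    def directions(table: pd.DataFrame) -> dict[str, int]:
        if groups is None:
            return {}
        g = groups.reindex(shared_samples)
        levels = sorted(g.dropna().unique()) if group_pair is None else list(group_pair)
        case, control = levels
        return {
            m: int(np.sign(table.loc[g == case, m].median() - table.loc[g == control, m].median()))
            for m in shared_mets
        }

    pred_dir, meas_dir = directions(pred), directions(meas)
    rows = []
    for m in shared_mets:
        rho = spearmanr(pred[m], meas[m]).statistic if len(shared_samples) > 2 else np.nan
        row = {"metabolite": m, "spearman_rho": float(rho)}
        if groups is not None:
            row.update(
                pred_direction=pred_dir[m],
                measured_direction=meas_dir[m],
                direction_agree=pred_dir[m] == meas_dir[m],
            )
        rows.append(row)
    return ConcordanceReport(
        table=pd.DataFrame(rows).set_index("metabolite"),
        prediction_only=tuple(m for m in pot.raw.columns if m not in metabolomics.columns),
        metabolomics_only=tuple(m for m in metabolomics.columns if m not in pot.raw.columns),
        n_shared_samples=len(shared_samples),
    )
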