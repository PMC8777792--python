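"""Production potentials, TSS, differential calls, concordance."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trpcap.metabolite_models import INTERCEPT, MetaboliteModel, PriorSpec
from trpcap.reference_network import TrpcapError
from trpcap.sample_prediction import (
    AbundanceTable,
    PotentialTable,
    concordance_report,
    differential_metabolites,
    genus_probability,
    sample_potentials,
    tss_normalize,
)
from _oracles import bh_adjust_oracle


def stub_model(metabolite="X", host="mouse", intercept=0.0, host_beta=0.0, genus_betas=None):
    genus_betas = genus_betas or {}
    columns = [INTERCEPT] + list(genus_betas) + [f"{host}_gut"]
    beta = np.array([intercept] + list(genus_betas.values()) + [host_beta])
    return MetaboliteModel(
        metabolite=metabolite, host_family=host, columns=columns, beta=beta,
        cov=np.eye(len(beta)), prior=PriorSpec(), log_lik=0.0, n_obs=10,
    )


class TestGenusProbability:
    def test_all_zero_betas_give_half(self):
        p, unseen = genus_probability(stub_model(genus_betas={"G": 0.0}), "G", "mouse")
        assert p == pytest.approx(0.5)
        assert not unseen

    def test_saturation_at_large_negative_intercept(self):
        p, _ = genus_probability(stub_model(intercept=-20.0, genus_betas={"G": 0.0}), "G", "mouse")
        assert p < 1e-8

    def test_unseen_genus_uses_baseline_and_flags(self):
        m = stub_model(intercept=1.0, host_beta=0.5, genus_betas={"G": 2.0})
        p, unseen = genus_probability(m, "Novelgenus", "mouse")
        assert unseen
        assert p == pytest.approx(1 / (1 + np.exp(-1.5)))

    def test_host_mismatch_raises(self):
        with pytest.raises(TrpcapError, match="host"):
            genus_probability(stub_model(host="mouse"), "G", "human")


def relative_table(data, samples=None):
    df = pd.DataFrame(data) if not isinstance(data, pd.DataFrame) else data
    if samples is not None:
        df.index = samples
    return AbundanceTable(values=df, kind="relative")


class TestSamplePotentials:
    def test_single_genus_product(self):
        m = stub_model(genus_betas={"G": 0.0})  # P = 0.5
        ab = relative_table({"G": [10.0]}, samples=["s1"])
        pot = sample_potentials({"X": m}, ab, "mouse")
        assert pot.raw.loc["s1", "X"] == pytest.approx(5.0)

    def test_linearity_doubling(self):
        m = stub_model(intercept=0.3, genus_betas={"G": 1.0, "H": -0.5})
        ab1 = relative_table({"G": [3.0, 1.0], "H": [7.0, 2.0]}, samples=["a", "b"])
        ab2 = relative_table({"G": [6.0, 2.0], "H": [14.0, 4.0]}, samples=["a", "b"])
        p1 = sample_potentials({"X": m}, ab1, "mouse").raw
        p2 = sample_potentials({"X": m}, ab2, "mouse").raw
        assert np.array_equal(2 * p1.to_numpy(), p2.to_numpy())

    def test_two_genus_dot_product(self):
        # (a1, a2) = (3, 7), (P1, P2) = (0.2, 0.9) -> T = 0.6 + 6.3 = 6.9
        logit = lambda p: np.log(p / (1 - p))
        m = stub_model(genus_betas={"G1": logit(0.2), "G2": logit(0.9)})
        ab = relative_table({"G1": [3.0], "G2": [7.0]}, samples=["s"])
        pot = sample_potentials({"X": m}, ab, "mouse")
        assert pot.raw.loc["s", "X"] == pytest.approx(6.9)

    def test_counts_are_tss_normalised_first(self):
        m = stub_model(genus_betas={"G": 0.0, "H": 0.0})
        ab = AbundanceTable(values=pd.DataFrame({"G": [30.0], "H": [70.0]}, index=["s"]),
                            kind="counts")
        pot = sample_potentials({"X": m}, ab, "mouse")
        assert pot.raw.loc["s", "X"] == pytest.approx(0.5)  # 0.3*0.5 + 0.7*0.5

    def test_unseen_mass_reported(self):
        m = stub_model(genus_betas={"G": 0.0})
        ab = relative_table({"G": [0.4], "Novel": [0.6]}, samples=["s"])
        pot = sample_potentials({"X": m}, ab, "mouse")
        assert pot.unseen_genera == ("Novel",)
        assert pot.unseen_mass.loc["s"] == pytest.approx(0.6)

    def test_zero_sample_warns(self):
        m = stub_model(genus_betas={"G": 0.0})
        ab = AbundanceTable(values=pd.DataFrame({"G": [0.0]}, index=["s"]), kind="counts")
        with pytest.warns(UserWarning, match="all-zero"):
            pot = sample_potentials({"X": m}, ab, "mouse")
        assert pot.raw.loc["s", "X"] == 0.0

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            AbundanceTable(values=pd.DataFrame({"G": [-1.0]}), kind="counts")


class TestTssNormalize:
    def make_pot(self, data, samples):
        return PotentialTable(raw=pd.DataFrame(data, index=samples))

    def test_example_row(self):
        pot = tss_normalize(self.make_pot({"A": [2.0], "B": [3.0], "C": [5.0]}, ["s"]))
        assert list(pot.normalized.loc["s"]) == pytest.approx([0.2, 0.3, 0.5])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.random((20, 5)) * 10, index=[f"s{i}" for i in range(20)])
        pot = tss_normalize(PotentialTable(raw=raw))
        assert np.allclose(pot.normalized.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_left_zero_and_flagged(self):
        pot = tss_normalize(self.make_pot({"A": [0.0, 1.0], "B": [0.0, 1.0]}, ["z", "s"]))
        assert (pot.normalized.loc["z"] == 0).all()
        assert "z" in pot.zero_rows

    def test_metabolite_axis_option(self):
        pot = tss_normalize(self.make_pot({"A": [1.0, 3.0], "B": [2.0, 2.0]}, ["s1", "s2"]),
                            axis="metabolite")
        assert np.allclose(pot.normalized.sum(axis=0), 1.0)


class TestDifferentialMetabolites:
    def pot_from(self, case_vals, ctrl_vals, mets=("X",)):
        rows = {}
        for i, v in enumerate(case_vals):
            rows[f"case{i}"] = v if isinstance(v, (list, tuple)) else [v] * len(mets)
        for i, v in enumerate(ctrl_vals):
            rows[f"ctrl{i}"] = v if isinstance(v, (list, tuple)) else [v] * len(mets)
        raw = pd.DataFrame.from_dict(rows, orient="index", columns=list(mets))
        groups = pd.Series(
            ["case"] * len(case_vals) + ["control"] * len(ctrl_vals), index=raw.index
        )
        # pass pre-normalised values straight through
        return PotentialTable(raw=raw, normalized=raw), groups

    def test_identical_groups_tie(self):
        pot, groups = self.pot_from([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        out = differential_metabolites(pot, groups, group_pair=("case", "control"))
        assert out.loc["X", "U"] == pytest.approx(4.5)  # n1*n2/2
        assert out.loc["X", "p"] == 1.0
        assert out.loc["X", "all_tied"]

    def test_fully_separated_three_vs_three_exact_p(self):
        pot, groups = self.pot_from([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        out = differential_metabolites(pot, groups, group_pair=("case", "control"))
        assert out.loc["X", "U"] == 0.0
        assert out.loc["X", "p"] == pytest.approx(0.1)  # exact two-sided, n=3+3
        assert out.loc["X", "direction"] == -1

    def test_bh_adjustment_matches_hand_stepup(self):
        rng = np.random.default_rng(1)
        case = [list(v) for v in rng.random((6, 5)) + np.array([2, 0.5, 0, 0, 0])]
        ctrl = [list(v) for v in rng.random((6, 5))]
        pot, groups = self.pot_from(case, ctrl, mets=[f"M{i}" for i in range(5)])
        out = differential_metabolites(pot, groups, group_pair=("case", "control"))
        assert list(out["q"]) == pytest.approx(bh_adjust_oracle(list(out["p"])))

    def test_too_few_samples_raise(self):
        pot, groups = self.pot_from([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="3 samples"):
            differential_metabolites(pot, groups)

    def test_permuted_labels_control_false_positives(self):
        rng = np.random.default_rng(7)
        raw = pd.DataFrame(rng.random((16, 8)), index=[f"s{i}" for i in range(16)],
                           columns=[f"M{i}" for i in range(8)])
        pot = tss_normalize(PotentialTable(raw=raw))
        frac = []
        for _ in range(25):
            labels = pd.Series(rng.permutation(["a"] * 8 + ["b"] * 8), index=raw.index)
            out = differential_metabolites(pot, labels, group_pair=("a", "b"))
            frac.append(out["significant"].mean())
        assert np.mean(frac) <= 0.05


class TestConcordance:
    def pot(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(rng.random((10, 3)) + 0.1, index=[f"s{i}" for i in range(10)],
                           columns=["X", "Y", "Z"])
        return tss_normalize(PotentialTable(raw=raw))

    def test_scaled_copy_gives_perfect_agreement(self):
        pot = self.pot()
        meas = pot.normalized * 7.3
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=pot.raw.index)
        rep = concordance_report(pot, meas, groups=groups, group_pair=("a", "b"))
        assert np.allclose(rep.table["spearman_rho"], 1.0)
        assert rep.table["direction_agree"].all()

    def test_prediction_only_metabolite_listed(self):
        pot = self.pot()
        meas = (pot.normalized * 2).drop(columns=["Z"])
        rep = concordance_report(pot, meas)
        assert rep.prediction_only == ("Z",)

    def test_independent_noise_has_low_rank_correlation(self):
        rng = np.random.default_rng(11)
        rhos = []
        for _ in range(50):
            raw = pd.DataFrame(rng.random((16, 4)), index=[f"s{i}" for i in range(16)],
                               columns=list("WXYZ"))
            pot = tss_normalize(PotentialTable(raw=raw))
            noise = pd.DataFrame(rng.random((16, 4)), index=raw.index, columns=raw.columns)
            rep = concordance_report(pot, noise)
            rhos.extend(np.abs(rep.table["spearman_rho"]))
        assert np.mean(rhos) < 0.3

    def test_no_shared_metabolites_raises(self):
        pot = self.pot()
        with pytest.raises(TrpcapError, match="shared"):
            concordance_report(pot, pot.normalized.rename(columns=str.lower))


from hypothesis import given, settings, strategies as st


class TestTssProperties:
    """Property-based checks of total-sum scaling."""

    @given(
        st.lists(
            st.lists(st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
                     min_size=3, max_size=6),
            min_size=1, max_size=8,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rows_sum_to_one_or_stay_zero(self, rows):
        raw = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
        pot = tss_normalize(PotentialTable(raw=raw))
        sums = pot.normalized.sum(axis=1).to_numpy()
        zero = raw.sum(axis=1).to_numpy() == 0
        assert np.allclose(sums[~zero], 1.0, atol=1e-12)
        assert np.all(sums[zero] == 0.0)
        # idempotence: normalising the normalised table changes nothing
        again = tss_normalize(PotentialTable(raw=pot.normalized))
        assert np.allclose(again.normalized.to_numpy(), pot.normalized.to_numpy())
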