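import numpy as np
import pandas as pd
import pytest

from albupred import (
    build_discriminators,
    delta_regression,
    distribution_crosstab,
    microalbuminuria_discrimination,
    pooled_measurements,
    subgroup_cutoffs,
    uacr_threshold_table,
)
from albupred.cohort import DiscriminatorSet, false_positive_audit
from conftest import make_patient


@pytest.fixture
def ds(small_cohort):
    return build_discriminators(small_cohort)


class TestBuildDiscriminators:
    def test_sums(self, ds):
        row = ds.frame.set_index("id").loc["A"]
        assert row["uPCR1.2.3"] == pytest.approx(0.02 + 0.03 + 0.04)
        assert row["uPCR1.3"] == pytest.approx(0.06)

    def test_labels_follow_patient_rule(self, ds):
        labels = ds.frame.set_index("id")["positive"]
        assert not labels["A"]
        assert labels["C"]        # uACR (12, 45, 38): two of three micro
        assert labels["E"]        # one of each category counts as micro

    def test_visit_permutation_keeps_sum_and_label(self):
        p1 = make_patient("x", [(0.05, 10), (0.08, 40), (0.10, 60)])
        p2 = make_patient("y", [(0.10, 60), (0.05, 10), (0.08, 40)])
        f = build_discriminators([p1, p2]).frame.set_index("id")
        assert f.loc["x", "uPCR1"] != f.loc["y", "uPCR1"]
        assert f.loc["x", "uPCR1.2.3"] == pytest.approx(
            f.loc["y", "uPCR1.2.3"])
        assert f.loc["x", "positive"] == f.loc["y", "positive"]

    def test_incomplete_patient_skipped(self, small_cohort):
        short = make_patient("short", [(0.05, 10), (0.08, 40)],
                             days=(0, 80))
        out = build_discriminators(small_cohort + [short])
        assert out.skipped == ["short"]
        assert len(out.frame) == len(small_cohort)


class TestThresholdTable:
    def test_deterministic_relation(self):
        # uACR = 500 * uPCR exactly: the cutoff solves 500 * CO = X
        upcr = np.linspace(0.01, 0.4, 120)
        records = pd.DataFrame({"upcr": upcr, "uacr": 500 * upcr})
        table = uacr_threshold_table(records, thresholds=(30, 60, 100))
        assert (table["auc"] == 1).all()
        for _, row in table.iterrows():
            assert 500 * row["cutoff"] >= row["uacr_threshold"]
            assert row["cutoff"] == pytest.approx(
                row["uacr_threshold"] / 500, abs=0.01)
        # cutoffs rise with the target and counts fall
        assert table["cutoff"].is_monotonic_increasing
        assert table["n_ge_x"].is_monotonic_decreasing

    def test_degenerate_threshold_flagged(self):
        records = pd.DataFrame({"upcr": [0.1, 0.2], "uacr": [50.0, 60.0]})
        table = uacr_threshold_table(records, thresholds=(10, 300))
        assert list(table["degenerate"]) == [True, True]


class TestMicroalbuminuriaDiscrimination:
    def test_uacr_discriminator_near_perfect(self, ds):
        table, _ = microalbuminuria_discrimination(ds)
        assert table.loc["uACR2", "auc"] >= 0.9

    def test_pairwise_includes_all_pairs(self, ds):
        table, pairwise = microalbuminuria_discrimination(ds)
        assert len(pairwise) == 45
        assert ((pairwise["p"] >= 0) & (pairwise["p"] <= 1)).all()

    def test_summed_upcr_beats_singles_under_exchangeable_noise(self):
        """With exchangeable visit noise the three-visit sum is a less
        noisy measure of the patient's mean proteinuria, so its AUC should
        not fall below the best single visit."""
        rng = np.random.default_rng(7)
        n = 300
        mu = rng.normal(np.log(0.08), 0.7, n)
        upcr = np.exp(mu[:, None] + rng.normal(0, 0.5, (n, 3)))
        positive = rng.random(n) < 1 / (1 + np.exp(-(mu - np.log(0.08)) * 2))
        frame = pd.DataFrame({
            "uPCR1": upcr[:, 0], "uPCR2": upcr[:, 1], "uPCR3": upcr[:, 2],
            "uPCR1.2": upcr[:, 0] + upcr[:, 1],
            "uPCR2.3": upcr[:, 1] + upcr[:, 2],
            "uPCR1.3": upcr[:, 0] + upcr[:, 2],
            "uPCR1.2.3": upcr.sum(axis=1),
            "uACR1": upcr[:, 0], "uACR2": upcr[:, 1], "uACR3": upcr[:, 2],
            "positive": positive,
        })
        table, _ = microalbuminuria_discrimination(
            DiscriminatorSet(frame=frame, skipped=[]))
        singles = table.loc[["uPCR1", "uPCR2", "uPCR3"], "auc"]
        assert table.loc["uPCR1.2.3", "auc"] >= singles.max() - 1e-9


class TestSubgroups:
    def test_partition_and_counts(self, ds):
        for axis in ("age", "sex", "gfr", "diabetes"):
            sub = subgroup_cutoffs(ds.frame, "uPCR2", "positive", axis)
            assert sub["n"].sum() == len(ds.frame)

    def test_single_group_equals_unstratified(self, ds):
        from albupred import roc_points, youden_cutoff
        sub = subgroup_cutoffs(ds.frame, "uPCR2", "positive", "diabetes")
        assert len(sub) == 1  # fixture cohort is all non-diabetic
        roc = roc_points(ds.frame["uPCR2"].to_numpy(),
                         ds.frame["positive"].to_numpy())
        assert sub.iloc[0]["auc"] == pytest.approx(roc.auc)
        assert sub.iloc[0]["cutoff"] == youden_cutoff(roc).cutoff

    def test_gfr_shift_raises_late_stage_cutoff(self):
        """If the uACR|uPCR curve sits lower in advanced GFR stages, the
        uPCR cutoff for uACR >= 30 must come out higher there."""
        rng = np.random.default_rng(13)
        n = 400
        upcr = np.exp(rng.normal(np.log(0.08), 0.8, n))
        group = np.where(rng.random(n) < 0.5, "early", "late")
        gain = np.where(group == "early", 450.0, 280.0)
        uacr = gain * upcr * np.exp(rng.normal(0, 0.3, n))
        frame = pd.DataFrame({"uPCR2": upcr, "positive": uacr >= 30,
                              "gfr_group": group})
        sub = subgroup_cutoffs(frame, "uPCR2", "positive", "gfr")
        sub = sub.set_index("subgroup")
        assert sub.loc["late", "cutoff"] > sub.loc["early", "cutoff"]

    def test_unknown_axis_rejected(self, ds):
        with pytest.raises(ValueError):
            subgroup_cutoffs(ds.frame, "uPCR2", "positive", "smoking")


class TestCrosstab:
    def test_single_record_single_cell(self):
        records = pd.DataFrame({"upcr": [0.10], "uacr": [50.0],
                                "gfr_category": ["G2"]})
        tab = distribution_crosstab(records)
        assert tab.to_numpy().sum() == 1

    def test_marginals_conserved(self, small_cohort):
        records = pooled_measurements(small_cohort)
        tab = distribution_crosstab(records)
        assert tab.to_numpy().sum() == len(records)

    def test_false_positive_audit_recount(self):
        rng = np.random.default_rng(2)
        records = pd.DataFrame({
            "upcr": rng.uniform(0, 0.3, 500),
            "uacr": rng.uniform(0, 60, 500),
            "gfr_category": "G2",
        })
        audit = false_positive_audit(records, cutoff=0.09)
        fp = records[(records.upcr >= 0.09) & (records.uacr < 30)]
        assert audit["n_false_positive"] == len(fp)
        assert audit["fraction"] == pytest.approx(
            (fp.uacr >= 10).mean())


class TestDeltaRegression:
    def _frame(self, d21, d32, base_upcr=0.05):
        rows = []
        for i, (a, b) in enumerate(zip(d21, d32)):
            u1 = base_upcr + 0.002 * i
            u2, u3 = u1 + a, u1 + a + b
            rows.append(make_patient(f"p{i}", [(u1, 500 * u1),
                                               (u2, 500 * u2),
                                               (u3, 500 * u3)]))
        return build_discriminators(rows)

    def test_exact_line(self):
        ds = self._frame([0.01, -0.02, 0.03, 0.005], [0.02, 0.01, -0.01, 0.0])
        table = delta_regression(ds)
        low = table[table["split"].str.startswith("first_upcr<")]
        assert low["slope"].to_numpy() == pytest.approx([500.0, 500.0])
        assert low["r"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(17)
        ds = self._frame(rng.uniform(-0.02, 0.03, 8), rng.uniform(-0.02, 0.03, 8))
        f = ds.frame
        dx = (f["uPCR2"] - f["uPCR1"]).to_numpy()
        dy = (f["uACR2"] - f["uACR1"]).to_numpy()
        slope = ((dx - dx.mean()) @ (dy - dy.mean())) / ((dx - dx.mean()) ** 2).sum()
        table = delta_regression(ds).set_index(["split", "pair"])
        assert table.loc[("first_upcr<0.15", "2-1"), "slope"] == \
            pytest.approx(slope)

    def test_too_few_patients_rejected(self):
        ds = self._frame([0.01], [0.02])
        with pytest.raises(ValueError):
            delta_regression(ds)
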