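"""OAV screening rules against the packaged reference table, and the
univariate group-difference tests against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from aromakey import io, screening
from aromakey.datamodel import (
    CompoundCatalog,
    CompoundRecord,
    RunConfig,
    ValidationError,
)
from aromakey.screening import OavMatrix


def _catalog(thresholds):
    return CompoundCatalog(
        [
            CompoundRecord(cid, cid, "alcohol", odor_threshold_air=ot)
            for cid, ot in thresholds.items()
        ]
    )


class TestComputeOav:
    def test_reference_ratio(self):
        """1621.01 ng/g over a 160.02 ng/g threshold -> OAV 10.13."""
        means = pd.DataFrame({"pea": [1621.01]}, index=["Heyuan"])
        oav = screening.compute_oav(means, _catalog({"pea": 160.02}))
        assert oav.table.loc["pea", "Heyuan"] == pytest.approx(10.13, abs=0.01)

    def test_unit_and_zero_ratios(self):
        means = pd.DataFrame({"a": [50.0], "b": [0.0]}, index=["G"])
        oav = screening.compute_oav(means, _catalog({"a": 50.0, "b": 3.0}))
        assert oav.table.loc["a", "G"] == 1.0
        assert oav.table.loc["b", "G"] == 0.0

    def test_missing_threshold_excluded_and_listed(self):
        catalog = CompoundCatalog(
            [
                CompoundRecord("a", "a", "alcohol", odor_threshold_air=10.0),
                CompoundRecord("b", "b", "alcohol"),
            ]
        )
        means = pd.DataFrame({"a": [5.0], "b": [5.0]}, index=["G"])
        oav = screening.compute_oav(means, catalog)
        assert list(oav.table.index) == ["a"]
        assert oav.excluded == ("b",)

    def test_nonpositive_threshold_names_compound(self):
        catalog = _catalog({"a": 10.0})
        object.__setattr__(catalog["a"], "odor_threshold_air", -1.0)
        means = pd.DataFrame({"a": [5.0]}, index=["G"])
        with pytest.raises(ValidationError, match="'a'"):
            screening.compute_oav(means, catalog)

    def test_scale_consistency(self):
        """Scaling a compound's concentrations and threshold together leaves
        its OAVs unchanged."""
        means = pd.DataFrame({"a": [5.0, 20.0]}, index=["G1", "G2"])
        base = screening.compute_oav(means, _catalog({"a": 2.0}))
        scaled = screening.compute_oav(means * 7.0, _catalog({"a": 14.0}))
        assert np.allclose(base.table.values, scaled.table.values)


@pytest.fixture(scope="module")
def table1_screen():
    oav_frame, _ = io.load_table1_oav()
    vip = pd.Series(2.0, index=oav_frame.index)  # all eight are VIP-selected
    report = screening.screen_key_active(
        vip, OavMatrix(table=oav_frame), RunConfig()
    )
    return oav_frame, report


class TestTable1Screening:
    def test_eight_key_active_compounds(self, table1_screen):
        _, report = table1_screen
        assert len(report.key_active) == 8

    def test_six_compounds_active_in_every_district(self, table1_screen):
        oav_frame, report = table1_screen
        n_groups = oav_frame.shape[1]
        everywhere = {
            c for c, gs in report.qualifying_groups.items() if len(gs) == n_groups
        }
        assert everywhere == {
            "phenylethyl alcohol",
            "methyl salicylate",
            "p-cresol",
            "benzeneacetaldehyde",
            "linalool",
            "geraniol",
        }

    def test_benzaldehyde_only_luokeng(self, table1_screen):
        oav_frame, report = table1_screen
        assert report.qualifying_groups["benzaldehyde"] == frozenset({"Luokeng"})
        assert oav_frame.loc["benzaldehyde", "Luokeng"] == pytest.approx(1.18)

    def test_branched_acid_qualifying_set(self, table1_screen):
        _, report = table1_screen
        assert report.qualifying_groups["3-methyl-butanoic acid"] == frozenset(
            {"Meizhou", "Heyuan", "Lianshan", "Chaozhou"}
        )

    def test_row_maxima(self, table1_screen):
        oav_frame, _ = table1_screen
        expected = {
            "linalool": 42.48,
            "geraniol": 150.63,
            "p-cresol": 5.49,
            "phenylethyl alcohol": 10.13,
        }
        for compound, value in expected.items():
            assert oav_frame.loc[compound].max() == pytest.approx(value)

    def test_key_active_subset_of_vip_selected(self, table1_screen):
        _, report = table1_screen
        assert report.key_active <= report.vip_selected


def test_key_active_monotone_in_cutoffs():
    """Raising either cutoff never enlarges the key-active set."""
    oav_frame, _ = io.load_table1_oav()
    vip = pd.Series(np.linspace(0.5, 3.0, len(oav_frame)), index=oav_frame.index)
    oav = OavMatrix(table=oav_frame)
    base = screening.screen_key_active(vip, oav, RunConfig()).key_active
    for v_cut, o_cut in [(1.5, 1.0), (1.0, 2.0), (2.5, 5.0)]:
        tighter = screening.screen_key_active(
            vip, oav, RunConfig(vip_cutoff=v_cut, oav_cutoff=o_cut)
        ).key_active
        assert tighter <= base


def _conc_from_groups(values_by_group):
    rows, index = [], []
    i = 0
    for group, values in values_by_group.items():
        for v in values:
            rows.append([v])
            index.append((f"S{i}", group, 1))
            i += 1
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "group", "replicate"]),
        columns=["c"],
    )


def _brute_force_anova(groups):
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(all_v) - len(groups)
    from scipy import stats

    f = (ssb / df_b) / (ssw / df_w)
    return f, float(stats.f.sf(f, df_b, df_w))


class TestAnova:
    def test_identical_groups(self):
        conc = _conc_from_groups({"A": [1, 2, 3], "B": [1, 2, 3]})
        f, p = screening.anova_by_group(conc, "c")
        assert (f, p) == (0.0, 1.0) or p > 0.9  # equal means, no separation

    def test_constant_everywhere(self):
        conc = _conc_from_groups({"A": [5.0, 5.0], "B": [5.0, 5.0]})
        assert screening.anova_by_group(conc, "c") == (0.0, 1.0)

    def test_separation_limit(self):
        conc = _conc_from_groups(
            {"A": [0, 1e-9, 0, 1e-9], "B": [1, 1 + 1e-9, 1, 1 + 1e-9]}
        )
        _, p = screening.anova_by_group(conc, "c")
        assert p < 1e-10

    def test_hand_case_matches_brute_force(self):
        """{1,2,3},{2,3,4},{6,7,8}: SSB = 42 (df 2), SSW = 6 (df 6) -> F = 21."""
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([6.0, 7, 8])]
        f_oracle, p_oracle = _brute_force_anova(groups)
        assert f_oracle == pytest.approx(21.0)
        conc = _conc_from_groups({"A": groups[0], "B": groups[1], "C": groups[2]})
        f, p = screening.anova_by_group(conc, "c")
        assert f == pytest.approx(f_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            groups = [rng.normal(size=rng.integers(2, 6)) for _ in range(3)]
            conc = _conc_from_groups({f"G{i}": g for i, g in enumerate(groups)})
            f, p = screening.anova_by_group(conc, "c")
            f_o, p_o = _brute_force_anova(groups)
            assert f == pytest.approx(f_o, abs=1e-10)

    def test_requires_two_injections_per_group(self):
        conc = _conc_from_groups({"A": [1.0], "B": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            screening.anova_by_group(conc, "c")


class TestTopGroupFlags:
    def test_strong_separation(self):
        rng = np.random.default_rng(22)
        conc = _conc_from_groups(
            {
                "A": rng.normal(10.0, 0.1, 6),
                "B": rng.normal(0.0, 0.1, 6),
                "C": rng.normal(0.0, 0.1, 6),
            }
        )
        top, flag = screening.top_group_flags(conc, "c", RunConfig())
        assert (top, flag) == ("A", "**")

    def test_identical_groups_tie(self):
        conc = _conc_from_groups({"A": [1.0, 2.0], "B": [1.0, 2.0]})
        top, flag = screening.top_group_flags(conc, "c", RunConfig())
        assert top is None and flag == "none"

    def test_overlapping_groups_not_flagged(self):
        conc = _conc_from_groups(
            {"A": [0.0, 1.0, 2.0, 3.0], "B": [0.6, 1.4, 2.6, 3.0]}
        )
        _, flag = screening.top_group_flags(conc, "c", RunConfig())
        assert flag == "none"
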