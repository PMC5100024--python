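"""Trait formulas, maturity grouping, correlations, contrast selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import stemnsc as sn
from stemnsc.traits import StemSample


class TestTncRemobilized:
    def test_complete_remobilization(self):
        s = StemSample(tnc_hd=20, tnc_mt=0, stm_hd=100, stm_mt=90)
        assert sn.tnc_remobilized(s) == pytest.approx(100.0)

    def test_no_change_zero(self):
        s = StemSample(tnc_hd=15, tnc_mt=15, stm_hd=80, stm_mt=80)
        assert sn.tnc_remobilized(s) == pytest.approx(0.0)

    def test_hand_arithmetic_both_variants(self):
        s = StemSample(tnc_hd=16.7, tnc_mt=7.7, stm_hd=100, stm_mt=120)
        corrected = 100 * (16.7 * 100 - 7.7 * 120) / (16.7 * 100)
        printed = 100 * (16.7 * 100 - 7.7 * 100) / (16.7 * 100)
        assert sn.tnc_remobilized(s) == pytest.approx(corrected)          # ~44.67
        assert sn.tnc_remobilized(s, as_printed=True) == pytest.approx(printed)  # ~53.89

    def test_variants_agree_when_stem_weight_constant(self):
        s = StemSample(tnc_hd=12, tnc_mt=9, stm_hd=70, stm_mt=70)
        assert sn.tnc_remobilized(s) == sn.tnc_remobilized(s, as_printed=True)

    def test_negative_means_reaccumulation(self):
        s = StemSample(tnc_hd=10, tnc_mt=12, stm_hd=80, stm_mt=90)
        assert sn.tnc_remobilized(s) < 0

    def test_zero_heading_mass_rejected(self):
        s = StemSample(tnc_hd=0, tnc_mt=5, stm_hd=100, stm_mt=100)
        with pytest.raises(ValueError):
            sn.tnc_remobilized(s)


class TestTnc:
    def test_values(self):
        assert sn.tnc(0, 0) == 0
        assert sn.tnc(10, 6.7) == pytest.approx(16.7)
        assert sn.tnc(3, 4) == sn.tnc(4, 3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sn.tnc(-1, 2)


class TestMaturityGroup:
    @pytest.mark.parametrize("days,expected", [
        (104, "Early"), (119, "Early"), (119.9, "Early"),
        (120, "Medium"), (125, "Medium"), (129, "Medium"),
        (130, "Late"), (141, "Late"),
    ])
    def test_boundaries(self, days, expected):
        assert sn.maturity_group(days) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sn.maturity_group(0)

    def test_panel_partition_counts(self):
        # a duration vector built to have the panel's 10/10/13 class sizes
        durations = [104 + i for i in range(10)] + [120 + i % 10 for i in range(10)] \
            + [130 + i % 12 for i in range(13)]
        groups = pd.Series([sn.maturity_group(d) for d in durations])
        assert groups.value_counts().to_dict() == {"Late": 13, "Early": 10, "Medium": 10}


class TestCorrelationMatrix:
    def test_self_and_collinear(self):
        t = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 6]})
        r, p, annot = sn.correlation_matrix(t)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert annot.loc["a", "b"] == "***"

    def test_textbook_oracle(self):
        t = pd.DataFrame({"x": [1.0, 2, 4, 5, 8], "y": [2.0, 1, 5, 4, 9]})
        x, y = t["x"], t["y"]
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        t_stat = r_hand * np.sqrt(3 / (1 - r_hand**2))
        from scipy.stats import t as t_dist
        p_hand = 2 * t_dist.sf(abs(t_stat), df=3)
        r, p, _ = sn.correlation_matrix(t)
        assert r.loc["x", "y"] == pytest.approx(r_hand, abs=1e-12)
        assert p.loc["x", "y"] == pytest.approx(p_hand, rel=1e-6)

    def test_pairwise_complete(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, np.nan, 5], "b": [1.0, 2, 3, 4, 5]})
        r, _, _ = sn.correlation_matrix(t)
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_constant_column_missing(self):
        t = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        r, _, _ = sn.correlation_matrix(t)
        assert np.isnan(r.loc["a", "b"])


class TestSelectContrasting:
    @pytest.fixture()
    def clustered(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0, 0, 0], [8.0, 0, 0, 0], [0, 8.0, 0, 0], [8.0, 8.0, 8.0, 0]])
        rows, names = [], []
        for c, center in enumerate(centers):
            for i in range(5):
                rows.append(center + rng.normal(0, 0.3, 4))
                names.append(f"C{c}_{i}")
        return pd.DataFrame(rows, index=names,
                            columns=["STCH_HD", "SUC_HD", "STCH_HV", "SUC_HV"])

    def test_one_per_separated_cluster(self, clustered):
        selected, diag = sn.select_contrasting(clustered, n_select=4, n_clusters=4)
        picked_clusters = {s.split("_")[0] for s in selected}
        assert len(picked_clusters) == 4

    def test_matches_exhaustive_maximin_per_cluster(self, clustered):
        """The greedy pick scores close to the exhaustive maximin optimum
        over all cluster-covering 4-subsets of the PC plane (coverage of the
        joint clusters is part of the selection procedure)."""
        selected, diag = sn.select_contrasting(clustered, n_select=4, n_clusters=4)
        pts = diag[["PC1", "PC2"]].to_numpy()
        ids = list(diag.index)
        joint = diag["joint_cluster"].to_numpy()

        def min_pairwise(subset):
            return min(np.linalg.norm(pts[a] - pts[b])
                       for a, b in itertools.combinations(subset, 2))

        covering = [s for s in itertools.combinations(range(len(ids)), 4)
                    if len({joint[i] for i in s}) == 4]
        best = max(min_pairwise(s) for s in covering)
        sel_score = min_pairwise([ids.index(s) for s in selected])
        assert sel_score >= 0.8 * best  # greedy maximin guarantee on this geometry

    def test_all_selected_when_n_equals_lines(self, clustered):
        selected, _ = sn.select_contrasting(clustered, n_select=len(clustered))
        assert sorted(selected) == sorted(clustered.index)

    def test_duplicates_not_both_selected(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(6, 3))
        table = pd.DataFrame(np.vstack([base, base[0]]),
                             index=[f"L{i}" for i in range(6)] + ["L0_dup"],
                             columns=["a", "b", "c"])
        selected, _ = sn.select_contrasting(table, n_select=4, n_clusters=3)
        assert not {"L0", "L0_dup"} <= set(selected)

    def test_deterministic_and_variance_ordering(self, clustered):
        s1, d1 = sn.select_contrasting(clustered, n_select=5, n_clusters=4)
        s2, d2 = sn.select_contrasting(clustered, n_select=5, n_clusters=4)
        assert s1 == s2
        evr = d1.attrs["explained_variance_ratio"]
        assert np.all(np.diff(evr) <= 1e-12)

    def test_validation(self, clustered):
        with pytest.raises(ValueError):
            sn.select_contrasting(clustered, n_select=100)
        with pytest.raises(ValueError):
            sn.select_contrasting(clustered[["STCH_HD"]], n_select=2)
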