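import itertools

import numpy as np
import pandas as pd
import pytest

from petscreen.groups import (
    FactorProfile,
    GroupSplit,
    SignificantFactor,
    cluster_accessory_domains,
    differential_conservation,
    factor_profile,
    kyte_doolittle_profile,
    mann_whitney_u,
    map_to_reference,
    position_property_test,
    split_groups,
)
from petscreen.seqio import Alignment, SequenceRecord
from tests.conftest import make_assay_rows
from petscreen.assay import per_condition_table


def property_frame(entries):
    return pd.DataFrame(
        [{"enzyme_id": e, "column": c, "property": p, "value": v} for e, c, p, v in entries]
    )


class TestSplitGroups:
    def _pc(self):
        return per_condition_table(
            make_assay_rows(
                [
                    ("DP001", "cryPow", 4.5, 40.0, 0.30, 0.08),  # acid
                    ("DP002", "cryPow", 4.5, 40.0, 0.09, 0.08),  # neutral (active at 7.5)
                    ("DP002", "cryPow", 7.5, 40.0, 0.30, 0.08),
                    ("DP003", "cryPow", 7.5, 40.0, 0.30, 0.08),  # untested at 4.5 -> excluded
                    ("DP004", "cryPow", 4.5, 40.0, 0.09, 0.08),  # inactive -> in no group
                ]
            )
        )

    def test_assignments(self):
        split = split_groups(self._pc())
        assert split.acid_group == ["DP001"]
        assert split.neutral_group == ["DP002"]
        assert split.excluded == ["DP003"]

    def test_groups_disjoint_invariant(self):
        with pytest.raises(ValueError):
            GroupSplit(acid_group=["a"], neutral_group=["a"])


def mw_permutation_oracle(x, y):
    """Full permutation enumeration over group-label assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(g1, g2):
        u = 0.0
        for a in g1:
            for b in g2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    mu = n1 * len(y) / 2.0
    obs = abs(u_stat(x, y) - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        if abs(u_stat(g1, g2) - mu) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_spec_exact_example(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_exact_matches_permutation_oracle(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 6))
            x = rng.integers(0, 6, size=n1).astype(float)  # integer values force ties
            y = rng.integers(0, 6, size=n2).astype(float)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(mw_permutation_oracle(x, y))

    def test_u1_plus_u2_identity(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 10)))
            y = rng.normal(size=int(rng.integers(3, 10)))
            u1, _ = mann_whitney_u(x, y)
            u2, _ = mann_whitney_u(y, x)
            assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_exact_close_to_asymptotic_at_n12(self, rng):
        diffs = []
        for _ in range(30):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p_exact = mann_whitney_u(x, y)
            from scipy.stats import mannwhitneyu

            p_asym = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            diffs.append(abs(p_exact - p_asym))
        assert np.median(diffs) < 0.02
        assert max(diffs) < 0.06

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPositionPropertyTest:
    def _split(self):
        return GroupSplit(
            acid_group=[f"a{i}" for i in range(10)],
            neutral_group=[f"n{i}" for i in range(12)],
        )

    def test_shifted_column_detected(self, rng):
        split = self._split()
        entries = [(e, 5, "pKa", rng.normal(-0.8, 0.2)) for e in split.acid_group]
        entries += [(e, 5, "pKa", rng.normal(0.0, 0.2)) for e in split.neutral_group]
        factors = position_property_test(property_frame(entries), split)
        assert len(factors) == 1
        assert factors[0].column == 5
        assert factors[0].mean_difference < 0

    def test_small_groups_skipped(self):
        split = GroupSplit(acid_group=["a1", "a2"], neutral_group=["n1", "n2", "n3"])
        entries = [("a1", 0, "pKa", 0.0), ("a2", 0, "pKa", 1.0)]
        entries += [("n1", 0, "pKa", 5.0), ("n2", 0, "pKa", 6.0), ("n3", 0, "pKa", 7.0)]
        assert position_property_test(property_frame(entries), split) == []

    def test_all_tied_not_significant(self):
        split = GroupSplit(acid_group=["a1", "a2", "a3"], neutral_group=["n1", "n2", "n3"])
        entries = [(e, 0, "pKa", 2.0) for e in split.acid_group + split.neutral_group]
        assert position_property_test(property_frame(entries), split) == []

    def test_null_calibration_five_percent(self, rng):
        # permuted split over null data: ~5% of positions flagged
        ids = [f"e{i}" for i in range(40)]
        split = GroupSplit(acid_group=ids[:18], neutral_group=ids[18:])
        entries = [
            (e, c, "pKa", rng.normal()) for c in range(300) for e in ids
        ]
        factors = position_property_test(property_frame(entries), split)
        frac = len(factors) / 300
        # binomial sd at p=0.05, n=300 is 0.0126; allow 3 sigma
        assert abs(frac - 0.05) < 0.04


class TestDifferentialConservation:
    def test_extreme_case_flagged(self):
        aln = Alignment(
            [
                SequenceRecord("a1", "HH"),
                SequenceRecord("a2", "HH"),
                SequenceRecord("n1", "DH"),
                SequenceRecord("n2", "DH"),
            ]
        )
        split = GroupSplit(acid_group=["a1", "a2"], neutral_group=["n1", "n2"])
        flags = differential_conservation(aln, split)
        acid_pos = [
            f for f in flags if f["column"] == 0 and f["class"] == "positive"
        ]
        assert acid_pos and acid_pos[0]["conserved_in"] == "acid"
        # column 1 identical in both groups: never flagged
        assert not any(f["column"] == 1 for f in flags)

    def test_null_no_flags(self):
        aln = Alignment(
            [
                SequenceRecord("a1", "HKV"),
                SequenceRecord("a2", "DRV"),
                SequenceRecord("n1", "HKV"),
                SequenceRecord("n2", "DRV"),
            ]
        )
        split = GroupSplit(acid_group=["a1", "a2"], neutral_group=["n1", "n2"])
        assert differential_conservation(aln, split) == []

    def test_missing_member_rejected(self):
        aln = Alignment([SequenceRecord("a1", "MK")])
        split = GroupSplit(acid_group=["a1"], neutral_group=["zz"])
        with pytest.raises(ValueError):
            differential_conservation(aln, split)


class TestKyteDoolittle:
    def test_poly_isoleucine(self):
        assert np.allclose(kyte_doolittle_profile("I" * 20, 9), 4.5)

    def test_poly_arginine(self):
        assert np.allclose(kyte_doolittle_profile("R" * 20, 9), -4.5)

    def test_window_one_raw_values(self):
        prof = kyte_doolittle_profile("IRW", 1)
        assert list(prof) == [4.5, -4.5, -0.9]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            kyte_doolittle_profile("IIII", 4)


class TestFactorProfile:
    def _factors(self):
        return [
            SignificantFactor(1, "pKa", -1.0, 1.0, -2.0, 0.01),
            SignificantFactor(2, "pKa", 5.0, 3.0, 2.0, 0.02),
        ]

    def test_value_at_acid_mean_counts(self):
        props = property_frame([("e", 1, "pKa", -1.0), ("e", 2, "pKa", 5.0)])
        prof = factor_profile(props, self._factors(), "e")
        assert prof.count == 2

    def test_equidistant_not_exhibited(self):
        props = property_frame([("e", 1, "pKa", 0.0)])
        prof = factor_profile(props, self._factors(), "e")
        assert prof.exhibited[(1, "pKa")] is False

    def test_missing_value_not_exhibited(self):
        prof = factor_profile(property_frame([]), self._factors(), "e")
        assert prof.count == 0

    def test_count_bounded_and_monotone(self):
        props = property_frame([("e", 1, "pKa", -1.0)])
        few = factor_profile(props, self._factors()[:1], "e")
        more = factor_profile(props, self._factors(), "e")
        assert few.count <= more.count <= len(self._factors())


class TestMapToReference:
    def test_gap_free_identity(self):
        aln = Alignment([SequenceRecord("ref", "MKV"), SequenceRecord("a", "MRV")])
        assert map_to_reference(aln, "ref") == {0: 1, 1: 2, 2: 3}

    def test_gapped_reference(self):
        aln = Alignment([SequenceRecord("ref", "A-C"), SequenceRecord("a", "AKC")])
        assert map_to_reference(aln, "ref") == {0: 1, 1: None, 2: 2}

    def test_random_gaps_invert_through_degapping(self, rng):
        residues = "".join(rng.choice(list("MKVLA-"), size=40))
        if residues.replace("-", "") == "":
            residues = "M" + residues[1:]
        aln = Alignment([SequenceRecord("ref", residues), SequenceRecord("a", "K" * 40)])
        mapping = map_to_reference(aln, "ref")
        degapped = residues.replace("-", "")
        for col, resno in mapping.items():
            if resno is not None:
                assert degapped[resno - 1] == residues[col]

    def test_absent_reference(self):
        aln = Alignment([SequenceRecord("a", "MK")])
        with pytest.raises(KeyError):
            map_to_reference(aln, "zz")


class TestAccessoryClusters:
    def _hmm(self):
        from petscreen.hmm import build_profile

        core = "MKVLAWGTDERPYQSN" * 3
        aln = Alignment([SequenceRecord(f"s{i}", core) for i in range(4)])
        return build_profile(aln), core

    def test_no_accessory_empty(self):
        hmm, core = self._hmm()
        records = [SequenceRecord("x", core)]
        assert cluster_accessory_domains(records, hmm, {}) == []

    def test_identical_segments_single_cluster(self):
        hmm, core = self._hmm()
        tail = "WWCCHHGGKKPPLLRRAAEEDDSSNNQQTTVVMMYYFFII"  # 40 residues
        records = [SequenceRecord("x", core + tail), SequenceRecord("y", core + tail)]
        clusters = cluster_accessory_domains(
            records, hmm, {"x": True, "y": False}, min_length=40
        )
        assert len(clusters) == 1
        assert clusters[0].members == ["x", "y"]
        assert clusters[0].hit_rate_low_ph == pytest.approx(0.5)
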