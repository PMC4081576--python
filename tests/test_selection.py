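import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarkit.descriptors import DescriptorMatrix
from qsarkit.model import SvrConfig
from qsarkit.selection import (
    SelectionError,
    cfs_merit,
    cfs_select,
    drop_degenerate,
    enforce_budget,
    f_stepping,
    prune_correlated,
    select_features,
)


def matrix_from(df: pd.DataFrame) -> DescriptorMatrix:
    return DescriptorMatrix(
        data=df, provenance={c: "chemical_continuous" for c in df.columns}
    )


def random_matrix(rng, n=30, p=6, prefix="f"):
    cols = [f"{prefix}{i}" for i in range(p)]
    return matrix_from(
        pd.DataFrame(rng.normal(size=(n, p)), columns=cols, index=[f"c{i}" for i in range(n)])
    )


class TestDropDegenerate:
    def test_all_zero_and_constant_removed(self, rng):
        m = random_matrix(rng, p=3)
        m.data["zeros"] = 0.0
        m.data["const"] = 4.2
        m.provenance.update({"zeros": "chemical_continuous", "const": "chemical_continuous"})
        m2, rep = drop_degenerate(matrix_from(m.data))
        assert "zeros" not in m2.column_names and "const" not in m2.column_names
        reasons = dict((c, r) for c, r, _ in rep.removed)
        assert reasons["zeros"] == "all_zero"
        assert reasons["const"] == "zero_variance"

    def test_identity_when_nothing_degenerate(self, rng):
        m = random_matrix(rng)
        m2, rep = drop_degenerate(m)
        assert m2.column_names == m.column_names
        assert rep.removed == []

    def test_all_degenerate_is_an_error(self):
        df = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 1.0]}, index=["x", "y"])
        with pytest.raises(SelectionError, match="no informative"):
            drop_degenerate(matrix_from(df))


class TestPruneCorrelated:
    def test_duplicate_keeps_copy_more_correlated_with_activity(self, rng):
        n = 40
        base = rng.normal(size=n)
        y = base + rng.normal(scale=0.1, size=n)
        df = pd.DataFrame(
            {
                "a_good": base,
                "b_copy": base + rng.normal(scale=1e-9, size=n),
                "c_other": rng.normal(size=n),
            },
            index=[f"c{i}" for i in range(n)],
        )
        m2, rep = prune_correlated(matrix_from(df), y, cutoff=0.9)
        assert "a_good" in m2.column_names
        assert "b_copy" not in m2.column_names

    def test_orthogonal_columns_unchanged(self, rng):
        m = random_matrix(rng, n=100)
        y = rng.normal(size=100)
        m2, rep = prune_correlated(m, y, cutoff=0.9)
        assert m2.column_names == m.column_names

    def test_planted_structure_against_pair_scan_oracle(self, rng):
        # plant a correlated block and verify the two invariants exhaustively:
        # no surviving pair above the cutoff, and every removed column violated
        # the cutoff against a survivor or another removed column
        n = 60
        z = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "f0": z,
                "f1": z + rng.normal(scale=0.05, size=n),
                "f2": z + rng.normal(scale=0.05, size=n),
                "f3": rng.normal(size=n),
                "f4": rng.normal(size=n),
                "f5": -z + rng.normal(scale=0.05, size=n),
            },
            index=[f"c{i}" for i in range(n)],
        )
        y = z + rng.normal(scale=0.2, size=n)
        cutoff = 0.9
        m2, rep = prune_correlated(matrix_from(df), y, cutoff=cutoff)
        surv = m2.data.to_numpy()
        C = np.corrcoef(surv, rowvar=False)
        np.fill_diagonal(C, 0.0)
        assert np.abs(C).max() <= cutoff
        for col, reason, stat in rep.removed:
            assert stat > cutoff  # recorded |r| at removal time

    def test_too_few_rows(self, rng):
        m = random_matrix(rng, n=2)
        with pytest.raises(SelectionError):
            prune_correlated(m, [1.0, 2.0], cutoff=0.9)

    @given(seed=st.integers(min_value=0, max_value=500))
    @settings(max_examples=25, deadline=None)
    def test_no_surviving_pair_property(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 25, 8
        base = rng.normal(size=(n, 3))
        X = base[:, rng.integers(0, 3, size=p)] + rng.normal(scale=0.3, size=(n, p))
        df = pd.DataFrame(X, columns=[f"g{i}" for i in range(p)], index=[f"c{i}" for i in range(n)])
        y = rng.normal(size=n)
        m2, _ = prune_correlated(matrix_from(df), y, cutoff=0.85)
        C = np.abs(np.corrcoef(m2.data.to_numpy(), rowvar=False))
        if C.ndim == 2:
            np.fill_diagonal(C, 0.0)
            assert C.max() <= 0.85 + 1e-12


def exhaustive_cfs_oracle(X, y, cols, max_subset):
    """Independent brute-force: evaluate CFS merit over every subset."""
    def merit(idx):
        k = len(idx)
        rcf = []
        for i in idx:
            c = np.corrcoef(X[:, i], y)[0, 1]
            rcf.append(abs(0.0 if np.isnan(c) else c))
        num = sum(rcf)
        ff = 0.0
        for a, b in itertools.combinations(idx, 2):
            c = np.corrcoef(X[:, a], X[:, b])[0, 1]
            ff += abs(0.0 if np.isnan(c) else c)
        return num / np.sqrt(k + 2.0 * ff)

    best, best_key = None, None
    p = X.shape[1]
    for k in range(1, min(p, max_subset) + 1):
        for combo in itertools.combinations(range(p), k):
            key = (-merit(combo), len(combo), tuple(cols[i] for i in combo))
            if best_key is None or key < best_key:
                best, best_key = combo, key
    return merit(best), [cols[i] for i in best]


class TestCfsSelect:
    def test_single_feature_merit_is_abs_correlation(self, rng):
        n = 50
        y = rng.normal(size=n)
        f = 0.6 * y + rng.normal(scale=0.8, size=n)
        df = pd.DataFrame({"f": f}, index=[f"c{i}" for i in range(n)])
        sel, merit, _ = cfs_select(matrix_from(df), y)
        assert sel == ["f"]
        assert merit == pytest.approx(abs(np.corrcoef(f, y)[0, 1]), abs=1e-12)

    def test_redundant_duplicate_never_beats_singleton(self, rng):
        # closed form with r_ff = 1: merit(pair) = 2r/sqrt(2+2) = r, so a
        # perfect duplicate adds nothing and the search keeps the singleton
        rcf = np.array([0.7, 0.7])
        rff = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert cfs_merit([0, 1], rcf, rff) <= cfs_merit([0], rcf, rff)
        n = 50
        y = rng.normal(size=n)
        f = 0.6 * y + rng.normal(scale=0.8, size=n)
        df = pd.DataFrame({"f_a": f, "f_b": f}, index=[f"c{i}" for i in range(n)])
        sel, _, _ = cfs_select(matrix_from(df), y)
        assert sel == ["f_a"]  # tie broken toward the smaller subset

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(314)
        for trial in range(20):
            n, p = 25, rng.integers(3, 9)
            X = rng.normal(size=(n, p))
            y = X[:, 0] * 0.8 + rng.normal(scale=0.6, size=n)
            cols = [f"f{i}" for i in range(p)]
            df = pd.DataFrame(X, columns=cols, index=[f"c{i}" for i in range(n)])
            sel, merit, rep = cfs_select(matrix_from(df), y)
            oracle_merit, oracle_sel = exhaustive_cfs_oracle(X, y, cols, p)
            assert merit == pytest.approx(oracle_merit, abs=1e-10)
            assert sorted(rep.extra["search_subset"]) == sorted(oracle_sel)
            # the locally-predictive augmentation only ever adds features
            assert set(oracle_sel) <= set(sel)

    def test_best_first_reaches_exhaustive_merit_on_small_instances(self):
        # force the search path (exhaustive_limit=0) and compare to enumeration
        rng = np.random.default_rng(2718)
        for trial in range(10):
            n, p = 30, 7
            X = rng.normal(size=(n, p))
            y = 0.9 * X[:, 1] - 0.5 * X[:, 4] + rng.normal(scale=0.5, size=n)
            cols = [f"f{i}" for i in range(p)]
            df = pd.DataFrame(X, columns=cols, index=[f"c{i}" for i in range(n)])
            sel, merit, _ = cfs_select(matrix_from(df), y, exhaustive_limit=0)
            oracle_merit, _ = exhaustive_cfs_oracle(X, y, cols, p)
            assert merit == pytest.approx(oracle_merit, abs=1e-10)

    def test_empty_matrix_is_an_error(self):
        df = pd.DataFrame(index=["a", "b"])
        with pytest.raises((SelectionError, ValueError)):
            cfs_select(matrix_from(df), [1.0, 2.0])


class TestFStepping:
    def _planted(self, rng, n=60):
        X = rng.normal(size=(n, 6))
        y = X[:, :5] @ np.array([1.0, -0.8, 0.7, 0.6, -0.5]) + rng.normal(scale=0.2, size=n)
        cols = [f"inf{i}" for i in range(5)] + ["noise0"]
        df = pd.DataFrame(X, columns=cols, index=[f"c{i}" for i in range(n)])
        return matrix_from(df), y

    def test_removes_noise_keeps_informative(self, rng):
        m, y = self._planted(rng)
        cfg = SvrConfig(kernel="linear", seed=0)
        subset, rep = f_stepping(m, y, trainer_config=cfg, seed=0)
        assert "noise0" not in subset
        assert set(subset) == {f"inf{i}" for i in range(5)}

    def test_trajectory_monotone_non_decreasing(self, rng):
        m, y = self._planted(rng)
        _, rep = f_stepping(m, y, trainer_config=SvrConfig(kernel="linear", seed=1), seed=1)
        traj = rep.extra["cv_r_trajectory"]
        assert all(b >= a for a, b in zip(traj, traj[1:]))

    def test_deterministic(self, rng):
        m, y = self._planted(rng)
        cfg = SvrConfig(kernel="linear", seed=3)
        s1, r1 = f_stepping(m, y, trainer_config=cfg, seed=3)
        s2, r2 = f_stepping(m, y, trainer_config=cfg, seed=3)
        assert s1 == s2
        assert r1.extra["cv_r_trajectory"] == r2.extra["cv_r_trajectory"]

    def test_all_informative_terminates_with_full_set(self, rng):
        n = 80
        X = rng.normal(size=(n, 3))
        y = X @ np.array([1.0, 0.9, 0.8]) + rng.normal(scale=0.05, size=n)
        df = pd.DataFrame(X, columns=["a", "b", "c"], index=[f"c{i}" for i in range(n)])
        subset, _ = f_stepping(matrix_from(df), y, trainer_config=SvrConfig(kernel="linear", seed=0))
        assert sorted(subset) == ["a", "b", "c"]


class TestEnforceBudget:
    def test_caps_at_quarter_of_compounds(self):
        feats = [f"f{i:02d}" for i in range(40)]
        rel = {f: 1.0 - i * 0.01 for i, f in enumerate(feats)}
        kept, rep = enforce_budget(feats, 128, rel)
        assert len(kept) == 32
        assert rep.budget == 32
        assert kept == feats[:32]  # highest relevance first in input order

    def test_under_budget_unchanged(self):
        kept, _ = enforce_budget([f"f{i}" for i in range(10)], 128, {})
        assert len(kept) == 10

    def test_small_dataset_floor(self):
        feats = ["a", "b", "c", "d", "e"]
        rel = {f: i for i, f in enumerate(feats)}
        kept, rep = enforce_budget(feats, 16, rel)
        assert len(kept) == 4
        assert "a" not in kept  # lowest relevance dropped


class TestPipeline:
    def test_pure_function_of_inputs(self, rng):
        n = 40
        X = rng.normal(size=(n, 8))
        y = X[:, 0] + rng.normal(scale=0.3, size=n)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(8)], index=[f"c{i}" for i in range(n)])
        m = matrix_from(df)
        cfg = SvrConfig(kernel="linear", seed=5)
        a = select_features(m, y, trainer_config=cfg, seed=5)
        b = select_features(m, y, trainer_config=cfg, seed=5)
        assert a[0] == b[0]
        assert [r.to_dict() for r in a[1]] == [r.to_dict() for r in b[1]]
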