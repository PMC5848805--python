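"""Tests for profile standardization and fuzzy c-means clustering."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from serumcmp.fuzzy_clustering import (
    ProfileMatrix,
    _classify_centroid,
    choose_cluster_number,
    estimate_fuzzifier,
    fuzzy_cmeans,
    standardize_profiles,
    trajectory_classes,
)

TIMES = ["Pre", "T0", "T12", "T24"]


def _pm(values, ids=None):
    values = np.asarray(values, dtype=float)
    return ProfileMatrix(
        ids=ids or [f"w{i}" for i in range(values.shape[0])],
        times=[f"t{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestStandardize:
    def _scores(self, rows):
        cols = [f"{sp}_{t}_r{r}" for sp in ("human",) for t in TIMES for r in (1, 2)]
        rep_map = {c: (c.split("_")[0], c.split("_")[1]) for c in cols}
        return pd.DataFrame(rows, columns=cols, index=[f"w{i}" for i in range(len(rows))]), rep_map

    def test_constant_row_dropped(self):
        scores, rep_map = self._scores([[1.0] * 8, [1, 1, 2, 2, 4, 4, 8, 8]])
        pm = standardize_profiles(scores, rep_map, "human", TIMES)
        assert pm.n == 1 and pm.n_dropped == 1

    def test_rows_are_zscored(self):
        rng = np.random.default_rng(0)
        scores, rep_map = self._scores(rng.uniform(0, 100, size=(20, 8)))
        pm = standardize_profiles(scores, rep_map, "human", TIMES)
        np.testing.assert_allclose(pm.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(pm.values.std(axis=1), 1.0, atol=1e-9)

    def test_hand_computed_example(self):
        scores, rep_map = self._scores([[0, 2, 3, 5, 7, 9, 15, 17]])
        pm = standardize_profiles(scores, rep_map, "human", TIMES, offset=1.0)
        means = np.array([1.0, 4.0, 8.0, 16.0])
        logged = np.log2(means + 1.0)
        expect = (logged - logged.mean()) / logged.std()
        np.testing.assert_allclose(pm.values[0], expect, rtol=1e-12)

    def test_all_constant_raises(self):
        scores, rep_map = self._scores([[5.0] * 8, [7.0] * 8])
        with pytest.raises(ValueError):
            standardize_profiles(scores, rep_map, "human", TIMES)


class TestFuzzifier:
    def test_plugin_formula_value(self):
        n, d = 1000, 4
        expect = (
            1.0
            + (1418.0 / n + 22.05) * d**-2
            + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
        )
        pm = _pm(np.random.default_rng(0).normal(size=(n, d)))
        assert estimate_fuzzifier(pm) == pytest.approx(expect, rel=1e-12)

    def test_always_above_one_and_monotone_in_n(self):
        rng = np.random.default_rng(1)
        prev = np.inf
        for n in (10, 100, 1000, 10000):
            m = estimate_fuzzifier(_pm(rng.normal(size=(n, 4))))
            assert m > 1.0
            assert m < prev
            prev = m

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            estimate_fuzzifier(_pm(np.zeros((1, 4))))


class TestFuzzyCMeans:
    def test_separated_blobs_memberships_saturate(self):
        rng = np.random.default_rng(2)
        a = rng.normal(loc=(-5, -5, -5), scale=0.05, size=(30, 3))
        b = rng.normal(loc=(5, 5, 5), scale=0.05, size=(30, 3))
        pm = _pm(np.vstack([a, b]))
        fc = fuzzy_cmeans(pm, c=2, m=2.0, seed=0)
        assert np.all(fc.memberships.max(axis=1) >= 0.99)

    def test_membership_rows_sum_to_one(self):
        pm = _pm(np.random.default_rng(3).normal(size=(40, 4)))
        fc = fuzzy_cmeans(pm, c=3, m=1.8, seed=1)
        np.testing.assert_allclose(fc.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((fc.memberships >= 0) & (fc.memberships <= 1))

    def test_objective_non_increasing(self):
        # re-run the update loop manually, tracking the objective
        pm = _pm(np.random.default_rng(4).normal(size=(60, 4)))
        x, c, m = pm.values, 4, 1.6
        rng = np.random.default_rng(5)
        u = rng.random((60, c))
        u /= u.sum(axis=1, keepdims=True)
        prev = np.inf
        for _ in range(30):
            um = u**m
            cent = (um.T @ x) / um.sum(axis=0)[:, None]
            d2 = np.maximum(((x[:, None, :] - cent[None]) ** 2).sum(-1), 1e-300)
            obj = float((um * d2).sum())
            assert obj <= prev + 1e-9
            prev = obj
            inv = d2 ** (-1.0 / (m - 1.0))
            u = inv / inv.sum(axis=1, keepdims=True)

    def test_invalid_c_raises(self):
        pm = _pm(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            fuzzy_cmeans(pm, c=5, m=2.0)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_e1071_reference_fixed_point(self):
        """Independent oracle: e1071::cmeans from the same well-separated
        start converges to the same memberships (<1e-4)."""
        rng = np.random.default_rng(6)
        x = np.vstack(
            [
                rng.normal(loc=(-3, 0, 3), scale=0.15, size=(10, 3)),
                rng.normal(loc=(3, 0, -3), scale=0.15, size=(10, 3)),
            ]
        )
        pm = _pm(x)
        fc = fuzzy_cmeans(pm, c=2, m=2.0, seed=0, tol=1e-10)
        with tempfile.TemporaryDirectory() as td:
            td = Path(td)
            np.savetxt(td / "x.txt", x)
            np.savetxt(td / "cent.txt", fc.centroids)
            script = td / "cm.R"
            script.write_text(
                'x <- as.matrix(read.table("%s"))\n'
                'cent <- as.matrix(read.table("%s"))\n'
                "library(e1071)\n"
                'r <- cmeans(x, centers=cent, m=2.0, iter.max=500, method="cmeans")\n'
                'write.table(r$membership, "%s", row.names=FALSE, col.names=FALSE)\n'
                % (td / "x.txt", td / "cent.txt", td / "u.txt")
            )
            subprocess.run(
                ["Rscript", "--vanilla", str(script)], check=True,
                capture_output=True, timeout=120,
            )
            u_ref = np.loadtxt(td / "u.txt")
        assert np.max(np.abs(fc.memberships - u_ref)) < 1e-4


class TestChooseClusterNumber:
    def test_three_planted_shapes_recovered(self):
        rng = np.random.default_rng(7)
        shapes = np.array([[-1.2, -0.4, 0.4, 1.2], [1.2, 0.4, -0.4, -1.2], [-1.0, 1.0, 1.0, -1.0]])
        rows = np.vstack([
            s + rng.normal(scale=0.1, size=(60, 4)) for s in shapes
        ])
        pm = _pm(rows)
        c, dmin = choose_cluster_number(pm, (2, 6), m=1.8, seed=0)
        assert c == 3
        assert set(dmin) == {2, 3, 4, 5, 6}

    def test_degenerate_range_returns_lower_bound(self):
        pm = _pm(np.random.default_rng(8).normal(size=(30, 3)))
        c, dmin = choose_cluster_number(pm, (2, 2), m=2.0, seed=0)
        assert c == 2 and list(dmin) == [2]

    def test_empty_or_invalid_range_raises(self):
        pm = _pm(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            choose_cluster_number(pm, (5, 3), m=2.0)


class TestTrajectoryClasses:
    @pytest.mark.parametrize(
        "centroid,expect",
        [
            ((-1.0, 0.0, 1.0), "opening"),
            ((1.0, 0.0, -1.0), "closing"),
            ((-1.0, 1.0, -1.0), "transient_up"),
            ((1.0, -1.0, 1.0), "transient_down"),
            ((0.1, 0.0, 0.1), "other"),
        ],
    )
    def test_centroid_shape_rules(self, centroid, expect):
        assert _classify_centroid(np.array(centroid), t0_index=0) == expect

    def test_low_membership_labeled_other(self):
        rng = np.random.default_rng(9)
        x = np.vstack([
            np.array([-1.2, -1.0, 0.9, 1.3]) + rng.normal(scale=0.05, size=(20, 4)),
            np.array([1.3, 0.9, -1.0, -1.2]) + rng.normal(scale=0.05, size=(20, 4)),
        ])
        pm = ProfileMatrix(ids=[f"w{i}" for i in range(40)], times=TIMES, values=x)
        fc = fuzzy_cmeans(pm, c=2, m=2.0, seed=0)
        labels_strict = trajectory_classes(fc, pm, membership_min=1.01)
        assert set(labels_strict) == {"other"}
        labels = trajectory_classes(fc, pm, membership_min=0.6)
        assert set(labels[:20]) == {"opening"} and set(labels[20:]) == {"closing"}

    def test_row_permutation_invariance(self, dhs_fixture):
        peaks, _, _ = dhs_fixture
        from serumcmp.dhs_windows import build_windows, score_and_classify, score_matrix

        wins = score_and_classify(build_windows(peaks), peaks)
        samples = sorted({p.sample for p in peaks})
        scores = score_matrix(wins, samples)
        rep_map = {"_".join(s): (s[0], s[1]) for s in samples}
        pm = standardize_profiles(scores, rep_map, "human", TIMES)
        fc = fuzzy_cmeans(pm, c=3, m=2.0, seed=0)
        lab = trajectory_classes(fc, pm)

        rng = np.random.default_rng(10)
        perm = rng.permutation(pm.n)
        pm2 = ProfileMatrix(
            ids=[pm.ids[i] for i in perm], times=pm.times, values=pm.values[perm]
        )
        fc2 = fuzzy_cmeans(pm2, c=3, m=2.0, seed=0)
        lab2 = trajectory_classes(fc2, pm2)
        # same windows get the same labels regardless of row order
        assert (lab.sort_index() == lab2.sort_index()).all()
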