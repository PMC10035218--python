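import subprocess
import textwrap

import numpy as np
import pytest

import sweepscan as sw
from sweepscan.amova import DistanceMatrix, classical_mds, permanova
from conftest import make_genotypes
from oracles import hamming_oracle, single_factor_r2_oracle


def labels_for(pops):
    """pops: population -> (n_samples, weight, geography)"""
    population, weight, geo = {}, {}, {}
    for p, (n, w, g) in pops.items():
        weight[p], geo[p] = w, g
        for k in range(n):
            population[f"{p}_{k}"] = p
    return sw.CohortLabels(population, weight, geo)


class TestHamming:
    def test_identical_samples_have_zero_distance(self):
        g = make_genotypes([[0, 1, 2], [0, 1, 2]])
        D = sw.hamming_distance_matrix(g)
        assert D.values[0, 1] == 0.0

    def test_maximal_difference_and_normalization(self):
        g = make_genotypes([[0, 2], [2, 0]])
        assert sw.hamming_distance_matrix(g).values[0, 1] == 4.0
        assert sw.hamming_distance_matrix(
            g, normalize=True).values[0, 1] == pytest.approx(1.0)

    def test_missing_markers_excluded_pairwise(self):
        g = make_genotypes([[0, sw.MISSING, 1], [0, 2, 2]])
        D = sw.hamming_distance_matrix(g)
        assert D.values[0, 1] == 1.0
        assert D.comparable[0, 1] == 2
        Dn = sw.hamming_distance_matrix(g, normalize=True)
        assert Dn.values[0, 1] == pytest.approx(0.25)

    def test_matches_direct_loop_oracle(self):
        rng = np.random.default_rng(41)
        dosage = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.07] = sw.MISSING
        g = make_genotypes(dosage)
        D = sw.hamming_distance_matrix(g)
        for i in range(12):
            for j in range(i + 1, 12):
                raw, comp = hamming_oracle(dosage[i], dosage[j])
                assert D.values[i, j] == pytest.approx(raw)
                assert D.comparable[i, j] == comp

    def test_genotype_mismatch_mode(self):
        g = make_genotypes([[0, 2, 1], [2, 0, 1]])
        D = sw.hamming_distance_matrix(g, mode="genotype")
        assert D.values[0, 1] == 2.0

    def test_disconnected_pair_rejected(self):
        g = make_genotypes([[0, sw.MISSING], [sw.MISSING, 1]])
        with pytest.raises(sw.ConfigError):
            sw.hamming_distance_matrix(g)


class TestPermanova:
    def test_two_clean_groups_explain_everything(self):
        # d=1 between groups, 0 within: SS_total = 1, R2 = 1, F infinite
        labels = labels_for({"P1": (2, "heavy", "north"),
                             "P2": (2, "light", "south")})
        samples = ["P1_0", "P1_1", "P2_0", "P2_1"]
        D = np.ones((4, 4)) - np.eye(4)
        D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 0.0
        table = permanova(DistanceMatrix(samples, D), labels, ["weight"],
                          n_perm=20, seed=1)
        t = table.terms
        assert t[t.term == "total"].SS.iloc[0] == pytest.approx(1.0)
        assert table.r2("weight") == pytest.approx(1.0)
        assert np.isinf(t[t.term == "weight"].F.iloc[0])

    def test_single_level_factor_rejected(self):
        labels = labels_for({"P1": (2, "heavy", "north"),
                             "P2": (2, "heavy", "south")})
        samples = ["P1_0", "P1_1", "P2_0", "P2_1"]
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(sw.ConfigError):
            permanova(DistanceMatrix(samples, D), labels, ["weight"],
                      n_perm=5)

    def test_ss_additivity_and_r2_bounds(self):
        rng = np.random.default_rng(42)
        labels = labels_for({"P1": (5, "heavy", "north"),
                             "P2": (5, "heavy", "south"),
                             "P3": (5, "light", "north"),
                             "P4": (5, "light", "south")})
        samples = sorted(labels.population)
        X = rng.normal(size=(20, 6))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        table = permanova(DistanceMatrix(samples, D), labels,
                          ["weight", "geography"], n_perm=30, seed=2)
        t = table.terms
        total = t[t.term == "total"].SS.iloc[0]
        parts = t[t.term != "total"].SS.sum()
        assert parts == pytest.approx(total, abs=1e-9)
        r2 = t[~t.term.isin(["total"])].R2
        assert ((r2 > -1e-12) & (r2 < 1 + 1e-12)).all()

    def test_single_factor_r2_matches_pair_sum_oracle(self):
        rng = np.random.default_rng(43)
        labels = labels_for({"P1": (4, "heavy", "north"),
                             "P2": (4, "heavy", "north"),
                             "P3": (4, "light", "south"),
                             "P4": (4, "light", "south")})
        samples = sorted(labels.population)
        X = rng.normal(size=(16, 4))
        X[8:] += 1.0
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        table = permanova(DistanceMatrix(samples, D), labels, ["weight"],
                          n_perm=10, seed=3)
        groups = np.array([labels.factor_of_sample(s, "weight")
                           for s in samples])
        assert table.r2("weight") == pytest.approx(
            single_factor_r2_oracle(D, groups), abs=1e-9)

    def test_p_value_invariant_to_sample_order(self):
        rng = np.random.default_rng(44)
        labels = labels_for({"P1": (3, "heavy", "north"),
                             "P2": (3, "heavy", "south"),
                             "P3": (3, "light", "north"),
                             "P4": (3, "light", "south")})
        samples = sorted(labels.population)
        X = rng.normal(size=(12, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        t1 = permanova(DistanceMatrix(samples, D), labels, ["weight"],
                       n_perm=200, seed=7)
        perm = rng.permutation(12)
        D2 = D[np.ix_(perm, perm)]
        samples2 = [samples[i] for i in perm]
        t2 = permanova(DistanceMatrix(samples2, D2), labels, ["weight"],
                       n_perm=200, seed=7)
        assert t1.p_value("weight") == t2.p_value("weight")
        assert t1.r2("weight") == pytest.approx(t2.r2("weight"), abs=1e-12)

    def test_excluded_none_samples(self):
        labels = labels_for({"P1": (3, "heavy", "north"),
                             "P2": (3, "light", "south"),
                             "P3": (3, "none", "none")})
        samples = sorted(labels.population)
        rng = np.random.default_rng(45)
        X = rng.normal(size=(9, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        table = permanova(DistanceMatrix(samples, D), labels, ["weight"],
                          n_perm=10, seed=1)
        # residual df reflects 6 usable samples: n - 1 - df_term = 4
        t = table.terms
        assert t[t.term == "residual"].df.iloc[0] == 4

    def test_agrees_with_vegan_adonis2(self, tmp_path):
        """Independent cross-check of SS/R2/F against the reference R
        implementation on a small two-factor design."""
        rng = np.random.default_rng(46)
        labels = labels_for({"P1": (5, "heavy", "north"),
                             "P2": (5, "heavy", "south"),
                             "P3": (5, "light", "north"),
                             "P4": (5, "light", "south")})
        samples = sorted(labels.population)
        X = rng.normal(size=(20, 5))
        X[:10, 0] += 1.2      # weight effect
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        table = permanova(DistanceMatrix(samples, D), labels,
                          ["weight", "geography"], n_perm=99, seed=5)
        np.savetxt(tmp_path / "D.csv", D, delimiter=",")
        w = [labels.factor_of_sample(s, "weight") for s in samples]
        geo = [labels.factor_of_sample(s, "geography") for s in samples]
        (tmp_path / "f.csv").write_text(
            "w,g\n" + "\n".join(f"{a},{b}" for a, b in zip(w, geo)))
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            D <- as.dist(as.matrix(read.csv("D.csv", header=FALSE)))
            f <- read.csv("f.csv")
            fit <- adonis2(D ~ w + g, data=f, permutations=49, by="terms")
            cat(fit$SumOfSqs[1], fit$SumOfSqs[2], fit$R2[1], fit$R2[2],
                fit$F[1], fit$F[2], sep="\\n")
        """)
        (tmp_path / "run.R").write_text(script)
        out = subprocess.run(["Rscript", "run.R"], cwd=tmp_path,
                             capture_output=True, text=True, check=True)
        ss_w, ss_g, r2_w, r2_g, f_w, f_g = map(float,
                                               out.stdout.split())
        t = table.terms
        assert t[t.term == "weight"].SS.iloc[0] == pytest.approx(ss_w,
                                                                 rel=1e-6)
        assert t[t.term == "geography"].SS.iloc[0] == pytest.approx(
            ss_g, rel=1e-6)
        assert table.r2("weight") == pytest.approx(r2_w, rel=1e-6)
        assert table.r2("geography") == pytest.approx(r2_g, rel=1e-6)
        assert t[t.term == "weight"].F.iloc[0] == pytest.approx(f_w,
                                                                rel=1e-6)


class TestClassicalMds:
    def test_equilateral_triangle_recovered(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, _ = classical_mds(
            DistanceMatrix(["a", "b", "c"], D), k=2)
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.linalg.norm(coords[i] - coords[j])
                assert d == pytest.approx(1.0, abs=1e-9)

    def test_zero_matrix_gives_no_spread(self):
        D = np.zeros((4, 4))
        coords, _ = classical_mds(DistanceMatrix(list("abcd"), D), k=2)
        assert coords.size == 0 or np.allclose(coords, 0)

    def test_round_trip_from_known_configuration(self):
        rng = np.random.default_rng(47)
        X = rng.normal(size=(10, 2))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        coords, _ = classical_mds(
            DistanceMatrix([f"s{i}" for i in range(10)], D), k=2)
        D2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2)
                     .sum(-1))
        np.testing.assert_allclose(D2, D, atol=1e-9)
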