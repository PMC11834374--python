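"""H2' specialisation, fixed-marginal nulls, projection and sharing."""

import numpy as np
import pandas as pd
import pytest

from symnet.network import (
    _entropy,
    h2_components,
    h2_ses,
    patefield_sample,
    project_parasitoid_symbiont,
    shared_pair_summary,
    write_edge_list,
)


def enumerate_tables(r, c):
    """All non-negative integer tables with row sums r and column sums c."""
    n, p = len(r), len(c)

    def rec(i, cols_left):
        if i == n - 1:
            if all(x >= 0 for x in cols_left):
                yield (tuple(cols_left),)
            return

        def comps(j, rem):
            if j == p - 1:
                if rem <= cols_left[j]:
                    yield (rem,)
                return
            for v in range(min(rem, cols_left[j]) + 1):
                for rest in comps(j + 1, rem - v):
                    yield (v,) + rest

        for row in comps(0, r[i]):
            left = tuple(cl - v for cl, v in zip(cols_left, row))
            for rest in rec(i + 1, left):
                yield (row,) + rest

    yield from rec(0, tuple(c))


class TestH2Components:
    def test_perfect_specialisation(self):
        _, _, _, h2p = h2_components(np.diag([5, 5, 5]))
        assert h2p == pytest.approx(1.0)

    def test_independence_table(self):
        _, _, _, h2p = h2_components(np.array([[2, 2], [2, 2]]))
        assert h2p == pytest.approx(0.0)

    def test_enumeration_example(self):
        # brute-force over all 2x2 tables with marginals (4,4)/(4,4)
        H2, H2min, H2max, h2p = h2_components(np.array([[3, 1], [1, 3]]))
        ents = [
            _entropy(np.array(T)) for T in enumerate_tables((4, 4), (4, 4))
        ]
        assert H2min == pytest.approx(min(ents))  # [[4,0],[0,4]] => ln 2
        assert H2max == pytest.approx(max(ents))  # [[2,2],[2,2]] => ln 4
        assert H2 == pytest.approx(1.2555, abs=1e-4)
        assert h2p == pytest.approx(0.189, abs=1e-3)

    def test_single_row_or_column_rejected(self):
        with pytest.raises(ValueError):
            h2_components(np.array([[1, 2, 3]]))

    def test_degenerate_marginals_warn(self):
        # unit marginals: every table has entropy ln 2, so no range exists
        with pytest.warns(UserWarning):
            _, _, _, h2p = h2_components(np.array([[1, 0], [0, 1]]))
        assert h2p == 0.0

    def test_bounds_bracket_on_random_marginals(self, rng):
        for _ in range(10):
            A = rng.integers(0, 4, size=(3, 3))
            if A.sum() < 2 or (A.sum(0) == 0).any() or (A.sum(1) == 0).any():
                continue
            H2, H2min, H2max, h2p = h2_components(A)
            assert H2min - 1e-9 <= H2 <= H2max + 1e-9
            assert 0 <= h2p <= 1


class TestPatefield:
    def test_single_row(self):
        T = patefield_sample([6], [2, 3, 1], seed=0)
        assert T.tolist() == [[2, 3, 1]]

    def test_marginals_exact_every_draw(self, rng):
        r, c = [5, 3, 9], [6, 4, 7]
        for k in range(50):
            T = patefield_sample(r, c, seed=rng)
            assert T.sum(axis=1).tolist() == r
            assert T.sum(axis=0).tolist() == c

    def test_mismatched_marginals(self):
        with pytest.raises(ValueError):
            patefield_sample([2, 2], [1, 1])

    def test_unit_two_by_two_law(self):
        # marginals (1,1)/(1,1): only two tables, each with probability 1/2
        rng = np.random.default_rng(7)
        n = 2000
        diag = sum(
            patefield_sample([1, 1], [1, 1], seed=rng)[0, 0] for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(diag / n - 0.5) < 3 * se


class TestH2SES:
    def test_diagonal_matrix_strongly_specialised(self):
        res = h2_ses(np.diag([8] * 10), n_null=200, seed=0)
        assert res.ses is not None and res.ses > 3

    def test_null_draw_centred(self):
        # score tables drawn from the null itself: mean SES ~ 0
        rng = np.random.default_rng(3)
        r = [12, 9, 6, 9]
        c = [9, 9, 9, 9]
        ses = []
        for k in range(40):
            A = patefield_sample(r, c, seed=rng)
            res = h2_ses(A, n_null=150, seed=int(rng.integers(2**31)))
            if res.ses is not None:
                ses.append(res.ses)
        m = np.mean(ses)
        se = np.std(ses, ddof=1) / np.sqrt(len(ses))
        assert abs(m) < 3 * se + 0.2

    def test_seeded_reproducible(self):
        A = np.array([[5, 1, 0], [1, 4, 2], [0, 0, 6]])
        a = h2_ses(A, n_null=100, seed=11)
        b = h2_ses(A, n_null=100, seed=11)
        assert a.ses == b.ses and a.null_mean == b.null_mean


class TestProjection:
    def test_single_aphid_single_parasitoid(self):
        A = pd.DataFrame([[3]], index=["aph"], columns=["wasp"])
        S = pd.DataFrame([[4, 2]], index=["aph"], columns=["h1", "h2"])
        B, dropped = project_parasitoid_symbiont(A, S)
        assert B.loc["wasp"].tolist() == [4, 2]
        assert dropped == []

    def test_even_attack_split(self):
        A = pd.DataFrame([[1, 1]], index=["aph"], columns=["w1", "w2"])
        S = pd.DataFrame([[4, 2]], index=["aph"], columns=["h1", "h2"])
        B, _ = project_parasitoid_symbiont(A, S)
        assert B.loc["w1"].tolist() == [2, 1]
        assert B.loc["w2"].tolist() == [2, 1]

    def test_conservation(self, rng):
        A = pd.DataFrame(
            rng.integers(0, 5, size=(6, 4)),
            index=[f"a{k}" for k in range(6)], columns=[f"w{k}" for k in range(4)],
        )
        S = pd.DataFrame(
            rng.integers(0, 5, size=(6, 5)),
            index=[f"a{k}" for k in range(6)], columns=[f"h{k}" for k in range(5)],
        )
        B, dropped = project_parasitoid_symbiont(A, S)
        kept = [a for a in S.index if a not in dropped]
        assert B.to_numpy().sum() == pytest.approx(
            S.loc[kept].to_numpy().sum(), abs=1e-9
        )

    def test_no_overlap_error(self):
        A = pd.DataFrame([[1]], index=["a1"], columns=["w"])
        S = pd.DataFrame([[1]], index=["a2"], columns=["h"])
        with pytest.raises(ValueError):
            project_parasitoid_symbiont(A, S)

    def test_edge_list_roundtrip(self, tmp_path, rng):
        B = pd.DataFrame(
            [[0.5, 0], [1.5, 2.0]], index=["w1", "w2"], columns=["h1", "h2"]
        )
        p = tmp_path / "edges.csv"
        write_edge_list(B, p)
        edges = pd.read_csv(p)
        assert len(edges) == 3  # zero-weight edge omitted
        assert edges.weight.sum() == pytest.approx(4.0)


class TestSharedPairSummary:
    def _sim(self, values, labels):
        return pd.DataFrame(values, index=labels, columns=labels, dtype=float)

    def test_disjoint_strains_no_sharing(self):
        labels = ["a", "b", "c"]
        strain = self._sim(np.eye(3), labels)
        par = self._sim(np.ones((3, 3)), labels)
        out = shared_pair_summary(strain, par)
        assert out.n_strain_sharing == 0

    def test_counts_match_exhaustive_enumeration(self):
        labels = list("abcd")
        strain = self._sim(
            [[1, 0.4, 0, 0.2], [0.4, 1, 0, 0], [0, 0, 1, 0.1], [0.2, 0, 0.1, 1]],
            labels,
        )
        par = self._sim(
            [[1, 0.3, 0, 0], [0.3, 1, 0.5, 0], [0, 0.5, 1, 0], [0, 0, 0, 1]],
            labels,
        )
        out = shared_pair_summary(strain, par)
        # brute force over all C(4,2)=6 pairs:
        # strain sharing: (a,b), (a,d), (c,d) -> 3
        # of those, parasitoid sharing: only (a,b) -> 1
        assert out.n_pairs == 6
        assert out.n_strain_sharing == 3
        assert out.n_strain_and_partner_sharing == 1
        assert out.pct_partner_among_strain_sharing == pytest.approx(100 / 3)
        # species sharing strains: {a,b,c,d}; linked via parasitoids: {a,b}
        assert out.n_species_sharing_strains == 4
        assert out.n_species_linked_by_partner == 2
        assert out.pct_species_linked == pytest.approx(50.0)

    def test_threshold_excludes_weak_partner_overlap(self):
        labels = ["a", "b"]
        strain = self._sim([[1, 0.5], [0.5, 1]], labels)
        par = self._sim([[1, 0.08], [0.08, 1]], labels)
        assert shared_pair_summary(strain, par).n_strain_and_partner_sharing == 1
        assert (
            shared_pair_summary(strain, par, threshold=0.1).n_strain_and_partner_sharing
            == 0
        )

    def test_strain_spread_from_count_matrix(self):
        labels = ["a", "b"]
        strain_sim = self._sim([[1, 0.5], [0.5, 1]], labels)
        par = self._sim([[1, 0], [0, 1]], labels)
        counts = pd.DataFrame(
            [[2, 1, 0], [1, 0, 3]], index=labels, columns=["h1", "h2", "h3"]
        )
        out = shared_pair_summary(strain_sim, par, strain_matrix=counts)
        assert out.n_strains == 3
        assert out.strains_in_multiple_species == 1

    def test_label_mismatch(self):
        a = self._sim(np.eye(2), ["a", "b"])
        b = self._sim(np.eye(2), ["a", "c"])
        with pytest.raises(ValueError):
            shared_pair_summary(a, b)
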