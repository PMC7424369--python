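import numpy as np
import pandas as pd
import pytest

from oracles import fisher_two_sided_exact
from reokit.rankcomp import DOWN, NONE, UP, fisher_exact_2x2, rankcompv2
from reokit.simulate import GeneratorConfig, generate
from conftest import group_samples


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected_3dp",
        [
            ((31, 18, 33, 11), 0.266),  # smoker/nonsmoker x male/female
            ((14, 20, 35, 24), 0.131),  # white/black x smoker/nonsmoker
            ((25, 9, 39, 20), 0.495),  # male/female x white/black
        ],
    )
    def test_cohort_contingency_tables(self, table, expected_3dp):
        assert round(fisher_exact_2x2(*table), 3) == expected_3dp

    def test_no_association_gives_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_agrees_with_exhaustive_enumeration(self, rng):
        tables = [(10, 0, 2, 8)]
        for _ in range(60):
            tables.append(tuple(int(x) for x in rng.integers(0, 21, size=4)))
        for a, b, c, d in tables:
            if a + b + c + d == 0:
                continue
            exact = float(fisher_two_sided_exact(a, b, c, d))
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(exact, rel=1e-7), (
                a, b, c, d,
            )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


def _shifted_gene_matrix():
    """41 genes, strict shared order, one gene moved from bottom to top in
    group 2: all 40 of its stable partners flip, nothing else changes."""
    g = 41
    rng = np.random.default_rng(7)
    base = np.arange(g, dtype=float)
    genes = [f"g{i:02d}" for i in range(g)]
    n = 8
    v1 = base[:, None] + rng.uniform(0, 0.4, size=(g, n))
    v2 = base[:, None] + rng.uniform(0, 0.4, size=(g, n))
    v2[0] += g + 1.0  # g00 jumps over every other gene
    cols1 = [f"a{i}" for i in range(n)]
    cols2 = [f"b{i}" for i in range(n)]
    matrix = pd.DataFrame(
        np.hstack([v1, v2]), index=pd.Index(genes, name="gene_id"), columns=cols1 + cols2
    )
    return matrix, cols1, cols2


class TestRankCompV2:
    def test_null_data_flags_nothing_beyond_bh_expectation(self):
        config = GeneratorConfig(
            n_genes=60, samples_per_group=(15, 15), n_deg=0, seed=99
        )
        matrix, meta, _ = generate(config)
        deg = rankcompv2(
            matrix, group_samples(meta, "group1"), group_samples(meta, "group2")
        )
        assert len(deg.flagged) <= 0.05 * matrix.shape[0]

    def test_planted_degs_recovered_with_directions(self, smoking_like):
        matrix, meta, truth = smoking_like
        deg = rankcompv2(
            matrix, group_samples(meta, "nonsmoker"), group_samples(meta, "smoker")
        )
        truth_dir = dict(zip(truth.degs.gene_id, truth.degs.direction))
        assert set(deg.flagged) == set(truth_dir)  # no false negatives or positives
        for gene, direction in truth_dir.items():
            assert deg.frame.loc[gene, "direction"] == direction

    def test_fully_flipped_gene_flagged_at_iteration_zero(self):
        matrix, cols1, cols2 = _shifted_gene_matrix()
        deg = rankcompv2(matrix, cols1, cols2)
        row = deg.frame.loc["g00"]
        assert (row.g1_gt, row.g1_lt, row.g2_gt, row.g2_lt) == (0, 40, 40, 0)
        assert row.direction == UP
        assert row.flagged_iteration == 0
        assert deg.flagged == ["g00"]
        # the observed table is the most extreme for its margins
        assert row.fisher_p == pytest.approx(
            float(fisher_two_sided_exact(0, 40, 40, 0)), rel=1e-7
        )

    def test_converged_run_is_a_fixed_point(self, smoking_like):
        matrix, meta, _ = smoking_like
        g1, g2 = group_samples(meta, "nonsmoker"), group_samples(meta, "smoker")
        deg = rankcompv2(matrix, g1, g2, max_iter=10)
        assert deg.converged
        more = rankcompv2(matrix, g1, g2, max_iter=deg.iterations_run + 3)
        assert set(more.flagged) == set(deg.flagged)
        pd.testing.assert_frame_equal(more.frame, deg.frame)

    def test_partner_count_invariant(self, smoking_like):
        matrix, meta, _ = smoking_like
        deg = rankcompv2(
            matrix, group_samples(meta, "nonsmoker"), group_samples(meta, "smoker")
        )
        f = deg.frame
        np.testing.assert_array_equal(
            (f.g1_gt + f.g1_lt).to_numpy(), (f.g2_gt + f.g2_lt).to_numpy()
        )
        assert set(f.direction.unique()) <= {UP, DOWN, NONE}

    def test_monotone_transform_invariance(self, smoking_like):
        matrix, meta, _ = smoking_like
        g1, g2 = group_samples(meta, "nonsmoker"), group_samples(meta, "smoker")
        base = rankcompv2(matrix, g1, g2).frame
        logged = rankcompv2(np.log(matrix), g1, g2).frame
        pd.testing.assert_frame_equal(base, logged)

    def test_no_common_pairs_is_explicit_error(self, rng):
        matrix = pd.DataFrame(
            rng.normal(size=(5, 8)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        with pytest.raises(ValueError, match="cannot proceed"):
            # alpha so strict that no pair is stable in either group
            rankcompv2(
                matrix,
                [f"s{i}" for i in range(4)],
                [f"s{i}" for i in range(4, 8)],
                stable_alpha=1e-12,
            )

    def test_too_small_inputs_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            rankcompv2(tiny_matrix, ["s1"], ["s2", "s3"])
        with pytest.raises(ValueError):
            rankcompv2(tiny_matrix.iloc[:2], ["s1", "s2"], ["s3", "s4"])
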