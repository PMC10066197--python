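import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divstab.diversity import (
    BlockCoverMatrix,
    UndefinedPlotError,
    alpha_diversity,
    beta_additive,
    beta_jaccard_dispersion,
    beta_whittaker,
    gamma_diversity,
    plot_richness,
)


def _pcoa_dispersion_oracle(presence: np.ndarray) -> float:
    """Independent closed-form distance-to-centroid oracle.

    Avoids the eigendecomposition route entirely: in the Gower-centered
    geometry the centroid sits at the origin and the (sign-corrected)
    squared distance of plot i to it is the i-th diagonal entry of the
    double-centered matrix,

        d_i^2 = (1/n) sum_j D_ij^2 - (1/(2 n^2)) sum_jk D_jk^2,

    with negative values (non-Euclidean excess) clamped to zero.
    """
    n = presence.shape[0]
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            inter = np.sum(presence[i] & presence[j])
            union = np.sum(presence[i] | presence[j])
            d2[i, j] = (1.0 - inter / union) ** 2
    dists = []
    for i in range(n):
        di2 = d2[i].sum() / n - d2.sum() / (2 * n * n)
        dists.append(np.sqrt(max(di2, 0.0)))
    return float(np.mean(dists))


def _random_block(rng, n_plots=5, n_taxa=8) -> BlockCoverMatrix:
    while True:
        cover = rng.integers(0, 3, size=(n_plots, n_taxa)) * rng.uniform(1, 30, size=(n_plots, n_taxa))
        if (cover.sum(axis=1) > 0).all():
            return BlockCoverMatrix(
                [f"p{i}" for i in range(n_plots)], [f"t{j}" for j in range(n_taxa)], cover
            )


def test_plot_richness_examples():
    assert plot_richness([5, 0, 12]) == 2
    assert plot_richness([0.0, 0.0]) == 0


@given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=40))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_plot_richness_matches_exhaustive_count(row):
    assert plot_richness(row) == sum(1 for v in row if v > 0)


@pytest.mark.parametrize(
    "index,expected",
    [("richness", 4.0), ("shannon", np.log(4)), ("inv_simpson", 4.0), ("s_pie", 4.0)],
)
def test_uniform_plot_indices(index, expected):
    m = BlockCoverMatrix(["p1"], list("abcd"), np.full((1, 4), 25.0))
    assert alpha_diversity(m, index) == pytest.approx(expected)


def test_alpha_is_mean_of_per_plot_formula(rng):
    m = _random_block(rng, n_plots=6, n_taxa=10)
    # direct per-plot evaluation, independent of the library path
    expected = {"richness": [], "shannon": [], "inv_simpson": []}
    for row in m.cover:
        p = row[row > 0] / row.sum()
        expected["richness"].append((row > 0).sum())
        expected["shannon"].append(-(p * np.log(p)).sum())
        expected["inv_simpson"].append(1 / (p**2).sum())
    for index, vals in expected.items():
        assert alpha_diversity(m, index) == pytest.approx(np.mean(vals))
    assert alpha_diversity(m, "s_pie") == alpha_diversity(m, "inv_simpson")


def test_gamma_richness_union_oracle(rng):
    m = _random_block(rng, n_plots=7, n_taxa=12)
    union = set()
    for i, row in enumerate(m.cover):
        union |= {j for j, v in enumerate(row) if v > 0}
    assert gamma_diversity(m, "richness") == len(union)
    # shared species and disjoint sets
    shared = BlockCoverMatrix(["p1", "p2"], list("abcdefg"), np.tile(np.arange(1.0, 8.0), (2, 1)))
    assert gamma_diversity(shared) == 7
    disjoint = BlockCoverMatrix(
        ["p1", "p2"], ["a", "b", "c"], np.array([[5.0, 5.0, 0.0], [0.0, 0.0, 5.0]])
    )
    assert gamma_diversity(disjoint) == 3


def test_abundance_index_on_empty_plot_errors():
    m = BlockCoverMatrix(["p1", "p2"], ["a"], np.array([[5.0], [0.0]]))
    with pytest.raises(UndefinedPlotError, match="p2"):
        alpha_diversity(m, "shannon")


class TestBetaDispersion:
    def test_identical_plots_have_zero_dispersion(self):
        m = BlockCoverMatrix(
            [f"p{i}" for i in range(4)], list("abc"), np.tile([10.0, 5.0, 1.0], (4, 1))
        )
        assert beta_jaccard_dispersion(m) == pytest.approx(0.0, abs=1e-12)

    def test_two_plot_geometry(self):
        # {sp1, sp2} vs {sp2, sp3}: Jaccard 2/3, each plot d/2 from centroid
        m = BlockCoverMatrix(
            ["p1", "p2"], ["sp1", "sp2", "sp3"], np.array([[9.0, 4.0, 0.0], [0.0, 7.0, 2.0]])
        )
        assert beta_jaccard_dispersion(m) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_matches_independent_pcoa_oracle(self, rng):
        for _ in range(25):
            m = _random_block(rng)
            got = beta_jaccard_dispersion(m)
            want = _pcoa_dispersion_oracle(m.presence())
            assert got == pytest.approx(want, abs=1e-8)

    def test_invariance_to_plot_and_taxon_permutation(self, rng):
        m = _random_block(rng)
        base = beta_jaccard_dispersion(m)
        pp = rng.permutation(m.n_plots)
        tp = rng.permutation(len(m.taxa))
        shuffled = BlockCoverMatrix(
            [m.plot_ids[i] for i in pp], [m.taxa[j] for j in tp], m.cover[np.ix_(pp, tp)]
        )
        assert beta_jaccard_dispersion(shuffled) == pytest.approx(base, abs=1e-12)

    def test_ubiquitous_species_keeps_identical_plots_identical(self):
        m = BlockCoverMatrix(
            ["p1", "p2", "p3"], list("ab"), np.tile([3.0, 8.0], (3, 1))
        )
        with_everywhere = BlockCoverMatrix(
            ["p1", "p2", "p3"], list("abc"), np.column_stack([m.cover, np.full(3, 2.0)])
        )
        assert beta_jaccard_dispersion(with_everywhere) == pytest.approx(0.0, abs=1e-12)

    def test_empty_plot_errors(self):
        m = BlockCoverMatrix(["p1", "p2"], ["a"], np.array([[5.0], [0.0]]))
        with pytest.raises(UndefinedPlotError, match="p2"):
            beta_jaccard_dispersion(m)

    def test_ruzicka_variant_runs_and_differs(self, rng):
        m = _random_block(rng)
        j = beta_jaccard_dispersion(m, metric="jaccard")
        r = beta_jaccard_dispersion(m, metric="ruzicka")
        assert np.isfinite(r) and r >= 0 and r != pytest.approx(j, abs=1e-12)


def test_whittaker_conventions_and_additive():
    assert beta_whittaker(5, 10, "as_printed") == pytest.approx(0.5)
    assert beta_whittaker(4, 12, "conventional") == pytest.approx(3.0)
    assert beta_whittaker(6, 6, "as_printed") == 1 == beta_whittaker(6, 6, "conventional")
    assert beta_additive(6, 6) == 0
    assert beta_additive(4, 12) == 8
    with pytest.raises(ValueError, match="inconsistent"):
        beta_whittaker(10, 5)


def test_gamma_at_least_max_plot_richness(rng):
    for _ in range(10):
        m = _random_block(rng, n_plots=4, n_taxa=9)
        per_plot = [plot_richness(row) for row in m.cover]
        assert gamma_diversity(m) >= max(per_plot) >= 1
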