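import numpy as np
import pytest

from codonbias.metrics import GeneIndices, counts_from_mapping, rscu
from codonbias.multivariate import (
    RscuMatrix,
    _spearman,
    build_rscu_matrix,
    correlate_indices,
    correlation_frame,
    correspondence_analysis,
    pca,
)

from .conftest import random_count_table
from .oracles import ca_inertia_oracle, spearman_rho_oracle


def _random_rscu_matrix(rng, n_genes, n_codons):
    vals = rng.uniform(0.01, 3.0, size=(n_genes, n_codons))
    return RscuMatrix(
        genes=tuple(f"g{i}" for i in range(n_genes)),
        codons=tuple(f"c{j}" for j in range(n_codons)),
        values=vals,
        imputed={},
    )


def test_build_rscu_matrix_59_columns(table):
    rng = np.random.default_rng(3)
    tables = [random_count_table(rng, table) for _ in range(5)]
    per_gene = [rscu(t) for t in tables]
    m = build_rscu_matrix(per_gene, table)
    assert m.values.shape == (5, 59)
    assert not np.any(np.isnan(m.values))


def test_build_rscu_matrix_imputes_missing_family(table):
    full = rscu(
        counts_from_mapping({c: 2 for c in table.sense_codons}, table, scope="g1")
    )
    no_cys = rscu(
        counts_from_mapping(
            {c: 2 for c in table.sense_codons if table.codon_to_aa[c] != "Cys"},
            table,
            scope="g2",
        )
    )
    m = build_rscu_matrix([full, no_cys], table)
    j_tgt = m.codons.index("TGT")
    j_tgc = m.codons.index("TGC")
    assert m.values[1, j_tgt] == 0 and m.values[1, j_tgc] == 0
    assert m.imputed[no_cys.scope] == 2
    assert m.imputed[full.scope] == 0


def test_build_rscu_matrix_identical_genes(table):
    r = rscu(counts_from_mapping({c: 3 for c in table.sense_codons}, table))
    m = build_rscu_matrix([r, r], table)
    assert np.allclose(m.values[0], m.values[1])


def test_ca_inertia_fractions_sum_to_one():
    rng = np.random.default_rng(5)
    m = _random_rscu_matrix(rng, 6, 9)
    res = correspondence_analysis(m)
    assert res.inertia_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(res.inertia_fractions >= 0)
    assert res.n_axes <= min(6, 9) - 1


def test_ca_spectrum_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(8)
    m = _random_rscu_matrix(rng, 3, 4)
    res = correspondence_analysis(m)
    want = ca_inertia_oracle(m.values)[: res.n_axes]
    assert np.allclose(res.singular_values**2, want, atol=1e-9)


def test_ca_degenerate_matrix_returns_fewer_axes():
    # rank-1 table (outer product): zero inertia left after centering
    vals = np.outer([1.0, 2.0, 3.0], [0.5, 1.0, 1.5, 2.0])
    m = RscuMatrix(
        genes=("a", "b", "c"),
        codons=("w", "x", "y", "z"),
        values=vals,
        imputed={},
    )
    res = correspondence_analysis(m)
    assert res.n_axes == 0


def test_ca_axis_sign_convention():
    rng = np.random.default_rng(13)
    m = _random_rscu_matrix(rng, 5, 7)
    res = correspondence_analysis(m)
    for j in range(res.n_axes):
        col = res.codon_coords.iloc[:, j].to_numpy()
        assert col[np.argmax(np.abs(col))] > 0


def test_pca_constant_column_contributes_nothing():
    rng = np.random.default_rng(2)
    vals = rng.uniform(0, 2, size=(6, 4))
    vals[:, 2] = 1.3
    m = RscuMatrix(
        genes=tuple(f"g{i}" for i in range(6)),
        codons=("a", "b", "c", "d"),
        values=vals,
        imputed={},
    )
    res = pca(m)
    assert np.allclose(res.codon_coords.loc["c"].to_numpy(), 0, atol=1e-9)


def test_pca_2x2_hand_case():
    # rows (0,0) and (2,2): all variance on the 45-degree axis
    m = RscuMatrix(
        genes=("a", "b"),
        codons=("x", "y"),
        values=np.array([[0.0, 0.0], [2.0, 2.0]]),
        imputed={},
    )
    res = pca(m)
    assert res.n_axes == 1
    assert res.inertia_fractions[0] == pytest.approx(1.0)
    assert res.singular_values[0] ** 2 == pytest.approx(4.0)  # 2 * (sqrt(2))^2


def test_spearman_matches_rank_oracle_with_ties():
    x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0, 9.0, 10.0, 4.0, 4.0]
    y = [2.0, 1.0, 3.0, 3.0, 4.0, 7.0, 6.0, 6.0, 9.0, 12.0, 5.0, 5.0]
    rho, _ = _spearman(np.array(x), np.array(y))
    assert rho == pytest.approx(spearman_rho_oracle(x, y), abs=1e-12)


def test_spearman_exact_permutation_small_n():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    rho, p = _spearman(x, x)
    assert rho == 1.0
    assert p == pytest.approx(2 / 720)  # only the two perfect orderings


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(21)
    x = rng.normal(size=30)
    y = x + rng.normal(scale=0.5, size=30)
    r1, _ = _spearman(x, y)
    r2, _ = _spearman(np.exp(x), y**3)
    assert r1 == pytest.approx(r2, abs=1e-12)


def _indices_from_frame(df):
    return [
        GeneIndices(
            gene_id=row.gene,
            gc=row.gc, gc1=row.gc, gc2=row.gc, gc3=row.gc3, gc12=row.gc,
            gc3s=row.gc3s, a3s=0.3, t3s=0.3, g3s=0.2, c3s=0.2,
            a3=1, t3=1, g3=1, c3=1,
            enc=row.enc, n_codons=100,
        )
        for row in df.itertuples()
    ]


def test_correlate_indices_self_and_symmetry():
    from codonbias import datasets

    idx = _indices_from_frame(datasets.load_gene_indices())
    results = correlate_indices(idx, axes=None, method="spearman")
    by_pair = {(r.index_a, r.index_b): r for r in results}
    assert by_pair[("GC", "GC")].rho == 1.0
    enc_gc3s = by_pair[("ENC", "GC3s")]
    assert -1 <= enc_gc3s.rho <= 1
    assert enc_gc3s.p_value < 0.01  # strongly coupled in the study genome
    frame = correlation_frame(results)
    assert frame.loc["GC", "GC"].startswith("1.000")


def test_correlate_indices_requires_three_genes():
    from codonbias import datasets

    idx = _indices_from_frame(datasets.load_gene_indices())[:2]
    with pytest.raises(ValueError):
        correlate_indices(idx)
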