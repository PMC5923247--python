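"""Isoform encoding, compatibility, the exact log joint, model sampling."""

import itertools

import numpy as np
import pytest

from biisq import (
    GeneModel,
    GlobalState,
    Hyperparameters,
    InvalidIsoformError,
    InvalidStateError,
    Isoform,
    ReadTerm,
    ReadTermMatrix,
    SampleState,
    compatibility,
    decode_isoform,
    emission_simplex,
    encode_isoform,
    log_joint,
    log_likelihood,
    sample_dataset,
)


class TestEncoding:
    @pytest.mark.parametrize(
        "composition, code",
        [((1, 0, 1), 5), ((1,), 1), ((1, 1, 0), 6), ((0, 0, 0, 1), 1), ((1, 1, 1), 7)],
    )
    def test_msb_first_examples(self, composition, code):
        assert encode_isoform(composition) == code
        assert decode_isoform(code, len(composition)) == tuple(composition)

    def test_round_trip_exhaustive_up_to_E12(self):
        for E in range(1, 13):
            for code in range(1, 1 << E):
                assert encode_isoform(decode_isoform(code, E)) == code

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidIsoformError):
            encode_isoform((0, 0, 0))

    def test_code_out_of_range(self):
        with pytest.raises(InvalidIsoformError):
            decode_isoform(8, 3)
        with pytest.raises(InvalidIsoformError):
            decode_isoform(0, 3)


def _oracle_compatible(exon_set, composition) -> bool:
    """A term is consistent iff its exon set is an infix of the isoform's chain."""
    chain = [i + 1 for i, c in enumerate(composition) if c]
    es = list(exon_set)
    for i in range(len(chain) - len(es) + 1):
        if chain[i:i + len(es)] == es:
            return True
    return False


class TestCompatibility:
    @pytest.mark.parametrize(
        "exon_set, composition, expected",
        [
            ((1, 2), (1, 1, 0), True),
            ((1, 3), (1, 1, 1), False),   # the junction skips exon 2
            ((2,), (1, 0, 1), False),     # exon 2 absent
            ((1, 3), (1, 0, 1), True),
            ((2, 4), (1, 1, 0, 1), True),
        ],
    )
    def test_examples(self, exon_set, composition, expected):
        term = ReadTerm(0, 1, exon_set)
        assert compatibility(term, Isoform(composition)) is expected

    def test_agrees_with_infix_oracle_exhaustively(self):
        """All (term, isoform) pairs for E <= 6 match the junction-chain oracle."""
        for E in range(1, 7):
            compositions = [c for c in itertools.product((0, 1), repeat=E) if any(c)]
            exon_sets = [
                es for r in range(1, E + 1)
                for es in itertools.combinations(range(1, E + 1), r)
            ]
            for comp in compositions:
                iso = Isoform(comp)
                for es in exon_sets:
                    got = compatibility(ReadTerm(0, 1, es), iso)
                    assert got == _oracle_compatible(es, comp), (es, comp)


class TestEmissionSimplex:
    def test_sums_to_one_with_floor(self, hyp):
        catalog = [ReadTerm(i, i + 10, (1,)) for i in range(5)]
        catalog += [ReadTerm(100 + i, 110 + i, (2,)) for i in range(5)]
        beta = emission_simplex(Isoform((1, 0)), catalog, hyp.eps)
        assert beta.sum() == pytest.approx(1.0)
        assert beta.min() >= hyp.eps / len(catalog) / (1 + hyp.eps) * 0.99
        # compatible terms dominate
        assert beta[:5].sum() > 0.99


def _tiny_setup(K=2, V=3, m=1):
    catalog = [ReadTerm(0, 10, (1,)), ReadTerm(20, 30, (1, 2)), ReadTerm(40, 50, (2,))][:V]
    isoforms = [Isoform((1, 1)), Isoform((1, 0)), Isoform((0, 1))][:K]
    hyp = Hyperparameters(L_max=K, K_max=max(K, 2))
    weights = np.full(K, 1.0 / K)
    gs = GlobalState(isoforms, pi=np.full(2, 0.5), global_weights=weights)
    return catalog, isoforms, hyp, gs


def _brute_force_loglik(X, gs, ss, hyp):
    """Sum over every assignment of each read occurrence to a slot."""
    beta = gs.emissions(X.catalog, hyp)
    total = 0.0
    for j in range(ss.m):
        reads = [v for v in range(X.V) for _ in range(X.X[v, j])]
        L = ss.L
        ll_j = 0.0
        for assignment in itertools.product(range(L), repeat=len(reads)):
            p = 1.0
            for v, l in zip(reads, assignment):
                p *= ss.psi[j, l] * beta[ss.c[j, l], v]
            ll_j += p
        total += np.log(ll_j)
    return total


class TestLogJoint:
    def test_single_isoform_uniform_emission(self):
        catalog, isoforms, hyp, _ = _tiny_setup(K=1, V=3)
        gs = GlobalState(isoforms[:1], pi=np.full(2, 0.5), global_weights=np.ones(1))
        X = ReadTermMatrix(catalog, np.array([[2], [1], [1]]), ["s0"])
        ss = SampleState(psi=np.ones((1, 1)), c=np.zeros((1, 1), dtype=int))
        beta = emission_simplex(isoforms[0], catalog, hyp.eps)
        expected = float(np.array([2, 1, 1]) @ np.log(beta))
        assert log_likelihood(X, gs, ss, hyp) == pytest.approx(expected)

    def test_duplicated_sample_doubles_contribution(self):
        catalog, isoforms, hyp, gs = _tiny_setup(K=2, V=3)
        X1 = ReadTermMatrix(catalog, np.array([[2], [1], [0]]), ["s0"])
        X2 = ReadTermMatrix(catalog, np.array([[2, 2], [1, 1], [0, 0]]), ["s0", "s1"])
        ss1 = SampleState(psi=np.array([[0.6, 0.4]]), c=np.array([[0, 1]]))
        ss2 = SampleState(psi=np.array([[0.6, 0.4]] * 2), c=np.array([[0, 1]] * 2))
        assert log_likelihood(X2, gs, ss2, hyp) == pytest.approx(
            2 * log_likelihood(X1, gs, ss1, hyp)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, seed):
        """Marginalised likelihood equals the exhaustive assignment sum."""
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 4))
        catalog, isoforms, hyp, _ = _tiny_setup(K=3, V=3)
        isoforms = isoforms[:K]
        weights = rng.dirichlet(np.ones(K))
        gs = GlobalState(isoforms, pi=np.full(2, 0.5), global_weights=weights)
        psi = rng.dirichlet(np.ones(K), size=1)
        c = np.array([rng.permutation(K)])
        ss = SampleState(psi=psi, c=c)
        counts = rng.multinomial(4, np.ones(3) / 3)[:, None]
        X = ReadTermMatrix(catalog, counts, ["s0"])
        exact = log_likelihood(X, gs, ss, hyp)
        brute = _brute_force_loglik(X, gs, ss, hyp)
        assert exact == pytest.approx(brute, abs=1e-8)
        # the full joint adds finite prior terms
        assert np.isfinite(log_joint(X, gs, ss, hyp))

    def test_non_simplex_psi_rejected(self):
        catalog, isoforms, hyp, gs = _tiny_setup(K=2, V=3)
        with pytest.raises(InvalidStateError):
            SampleState(psi=np.array([[0.7, 0.7]]), c=np.array([[0, 1]]))


class TestSampleDataset:
    def test_single_isoform_psi_is_one(self, gene4, hyp):
        X, truth = sample_dataset(gene4, [Isoform((1, 1, 1, 1))], hyp, m=3,
                                  reads_per_sample=10, seed=0)
        np.testing.assert_allclose(truth["psi"], 1.0)
        np.testing.assert_array_equal(X.column_totals(), [10, 10, 10])

    def test_seed_determinism(self, gene4, hyp, disjoint_pair):
        X1, t1 = sample_dataset(gene4, disjoint_pair, hyp, 5, 20, seed=42)
        X2, t2 = sample_dataset(gene4, disjoint_pair, hyp, 5, 20, seed=42)
        np.testing.assert_array_equal(X1.X, X2.X)
        np.testing.assert_array_equal(t1["psi"], t2["psi"])
        assert X1.catalog == X2.catalog

    def test_large_alpha_concentrates_on_global_weights(self, gene4, disjoint_pair):
        """Dirichlet moments: with large alpha the sample mean approaches the
        global weights within three standard errors."""
        hyp = Hyperparameters(alpha=50.0)
        w = np.array([0.7, 0.3])
        m = 200
        _, truth = sample_dataset(gene4, disjoint_pair, hyp, m=m,
                                  reads_per_sample=5, seed=1, global_weights=w)
        conc = hyp.alpha * 2 * w
        var = w * (1 - w) / (conc.sum() + 1)
        se = np.sqrt(var / m)
        assert np.all(np.abs(truth["psi"].mean(axis=0) - w) < 3 * se)

    def test_zero_reads_gives_empty_columns(self, gene4, hyp, disjoint_pair):
        X, _ = sample_dataset(gene4, disjoint_pair, hyp, 3, 0, seed=0)
        assert X.X.sum() == 0

    def test_empty_isoform_list_rejected(self, gene4, hyp):
        with pytest.raises(InvalidIsoformError):
            sample_dataset(gene4, [], hyp, 3, 10, seed=0)
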