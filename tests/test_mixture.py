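import numpy as np
import pytest
from hypothesis import given, strategies as st

from domainmix import (
    DomainProfile,
    FitDegenerateError,
    FitOptions,
    InvalidProfileError,
    LineageRecord,
    SignatureMatrix,
    TaxonomicProfile,
    TaxonomyTable,
    aggregate_weights,
    bray_curtis,
    em_fit,
    fdu,
    log_likelihood,
    renormalize_subset,
)
from domainmix.containers import _fixed_point_normalize

from conftest import grid_search_loglik, naive_loglik, random_instance


def _refs(fams, cols):
    cols = np.asarray(cols, dtype=float)
    return SignatureMatrix(fams, [f"s{i}" for i in range(cols.shape[1])], cols)


class TestEmFit:
    def test_profile_in_hull_of_unit_vectors_recovered(self):
        refs = _refs(("f1", "f2"), [[1.0, 0.0], [0.0, 1.0]])
        y = DomainProfile(("f1", "f2"), np.array([0.3, 0.7]))
        fit = em_fit(y, refs)
        assert np.allclose(fit.weights, [0.3, 0.7], atol=1e-9)
        assert fit.fdu < 1e-9

    def test_single_reference_equal_to_profile(self):
        refs = _refs(("f1", "f2"), [[0.4], [0.6]])
        y = DomainProfile(("f1", "f2"), np.array([0.4, 0.6]))
        fit = em_fit(y, refs)
        assert fit.weights[0] == pytest.approx(1.0)
        assert fit.fdu < 1e-12

    def test_profile_outside_hull_hits_boundary(self):
        # grid search over w1 confirms the boundary optimum w=(1, 0)
        refs = _refs(("f1", "f2"), [[0.5, 0.0], [0.5, 1.0]])
        y = DomainProfile(("f1", "f2"), np.array([1.0, 0.0]))
        fit = em_fit(y, refs)
        assert np.allclose(fit.weights, [1.0, 0.0], atol=1e-9)
        assert np.allclose(fit.reconstruction.values, [0.5, 0.5])
        assert fit.fdu == pytest.approx(0.5)
        grid = np.linspace(0, 1, 1001)
        lls = [naive_loglik(y.values, refs.matrix, (a, 1 - a)) for a in grid]
        assert grid[int(np.argmax(lls))] == 1.0

    def test_no_supported_family_is_degenerate(self):
        refs = _refs(("f1", "f2"), [[1.0], [0.0]])
        y = DomainProfile(("f1", "f2"), np.array([0.0, 1.0]))
        with pytest.raises(FitDegenerateError):
            em_fit(y, refs)

    def test_unsupported_mass_reported_and_kept_in_fdu(self):
        refs = _refs(("f1", "f2", "f3"), [[1.0], [0.0], [0.0]])
        y = DomainProfile(("f1", "f2", "f3"), np.array([0.6, 0.4, 0.0]))
        fit = em_fit(y, refs)
        assert fit.unsupported_mass == pytest.approx(0.4)
        assert fit.fdu == pytest.approx(0.4)  # |0.6-1|/2 + |0.4-0|/2

    def test_misaligned_universes_rejected(self):
        refs = _refs(("f1", "f2"), [[1.0, 0.0], [0.0, 1.0]])
        y = DomainProfile(("f2", "f1"), np.array([0.3, 0.7]))
        with pytest.raises(Exception, match="align"):
            em_fit(y, refs)

    def test_monotone_trace_and_simplex_on_random_instances(self):
        for seed in range(30):
            profile, refs = random_instance(seed)
            fit = em_fit(profile, refs)
            trace = np.array(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-9)
            assert np.all(fit.weights >= 0)
            assert abs(fit.weights.sum() - 1.0) <= 1e-9

    def test_em_matches_simplex_grid_search(self):
        for seed in range(10):
            profile, refs = random_instance(seed, d_max=60, k_fixed=3)
            fit = em_fit(profile, refs)
            best = grid_search_loglik(profile.values, refs.matrix, step=0.01)
            assert fit.loglik >= best - 1e-6

    def test_exact_recovery_full_column_rank(self):
        g = np.random.default_rng(7)
        cols = g.dirichlet(np.full(50, 0.5), size=5).T
        cols /= cols.sum(axis=0)
        cols /= cols.sum(axis=0)
        refs = _refs([f"F{i}" for i in range(50)], cols)
        w_true = np.array([0.4, 0.25, 0.2, 0.1, 0.05])
        y = DomainProfile(refs.family_ids, _fixed_point_normalize(cols @ w_true))
        # interior optimum: run the concave maximization to tight tolerance
        fit = em_fit(y, refs, FitOptions(rel_tol=1e-14, max_iter=200_000))
        assert np.abs(fit.weights - w_true).sum() < 1e-4
        assert fit.fdu < 1e-6

    def test_deterministic_given_inputs(self):
        profile, refs = random_instance(3)
        f1, f2 = em_fit(profile, refs), em_fit(profile, refs)
        assert np.array_equal(f1.weights, f2.weights)
        assert f1.loglik_trace == f2.loglik_trace

    def test_custom_init_reaches_same_optimum(self):
        profile, refs = random_instance(11, d_max=50, k_fixed=4)
        w0 = np.array([0.7, 0.1, 0.1, 0.1])
        f_uniform = em_fit(profile, refs)
        f_custom = em_fit(profile, refs, FitOptions(init=w0))
        assert f_custom.loglik == pytest.approx(f_uniform.loglik, abs=1e-6)


class TestLogLikelihood:
    def test_perfect_single_family(self):
        refs = _refs(("f1", "f2"), [[1.0], [0.0]])
        y = DomainProfile(("f1", "f2"), np.array([1.0, 0.0]))
        assert log_likelihood(y, refs, [1.0]) == 0.0

    def test_uniform_two_family_closed_form(self):
        refs = _refs(("f1", "f2"), [[0.5], [0.5]])
        y = DomainProfile(("f1", "f2"), np.array([0.5, 0.5]))
        assert log_likelihood(y, refs, [1.0]) == pytest.approx(np.log(0.5))

    def test_matches_naive_loop_oracle(self):
        for seed in range(10):
            profile, refs = random_instance(seed, d_max=40, k_fixed=3)
            g = np.random.default_rng(seed + 100)
            w = g.dirichlet(np.ones(3))
            w = w / w.sum()
            got = log_likelihood(profile, refs, w)
            assert got == pytest.approx(
                naive_loglik(profile.values, refs.matrix, w), abs=1e-10
            )

    def test_off_simplex_weights_rejected(self):
        refs = _refs(("f1", "f2"), [[1.0, 0.0], [0.0, 1.0]])
        y = DomainProfile(("f1", "f2"), np.array([0.5, 0.5]))
        with pytest.raises(InvalidProfileError):
            log_likelihood(y, refs, [0.8, 0.3])


class TestFdu:
    @pytest.mark.parametrize(
        "y, yhat, expected",
        [
            ([0.5, 0.5], [0.5, 0.5], 0.0),
            ([1.0, 0.0], [0.0, 1.0], 1.0),
            ([0.6, 0.4], [0.5, 0.5], 0.1),
        ],
    )
    def test_known_values(self, y, yhat, expected):
        a = DomainProfile(("f1", "f2"), np.array(y))
        b = DomainProfile(("f1", "f2"), np.array(yhat))
        assert fdu(a, b) == pytest.approx(expected, abs=1e-15)

    def test_unnormalized_input_rejected(self):
        a = DomainProfile(("f1", "f2"), np.array([0.5, 0.6]))
        b = DomainProfile(("f1", "f2"), np.array([0.5, 0.5]))
        with pytest.raises(InvalidProfileError):
            fdu(a, b)

    @given(st.integers(0, 10_000))
    def test_under_equals_overpredicted_mass(self, seed):
        g = np.random.default_rng(seed)
        d = int(g.integers(2, 30))
        y = _fixed_point_normalize(g.dirichlet(np.ones(d)))
        z = _fixed_point_normalize(g.dirichlet(np.ones(d)))
        under = np.maximum(y - z, 0).sum()
        over = np.maximum(z - y, 0).sum()
        assert abs(under - over) < 1e-12
        fams = [f"F{i}" for i in range(d)]
        val = fdu(DomainProfile(fams, y), DomainProfile(fams, z))
        assert val == pytest.approx(under, abs=1e-12)
        assert 0.0 <= val <= 1.0

    def test_fdu_equals_bray_curtis_on_same_vectors(self, rng):
        d = 12
        y = _fixed_point_normalize(rng.dirichlet(np.ones(d)))
        z = _fixed_point_normalize(rng.dirichlet(np.ones(d)))
        fams = [f"F{i:02d}" for i in range(d)]
        as_taxa = lambda v: TaxonomicProfile("phylum", dict(zip(fams, v.tolist())))
        assert fdu(DomainProfile(fams, y), DomainProfile(fams, z)) == bray_curtis(
            as_taxa(y), as_taxa(z)
        )


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        p = TaxonomicProfile("phylum", {"A": 0.5, "B": 0.5})
        assert bray_curtis(p, p) == 0.0

    def test_disjoint_support_is_one(self):
        p = TaxonomicProfile("phylum", {"A": 1.0})
        q = TaxonomicProfile("phylum", {"B": 1.0})
        assert bray_curtis(p, q) == 1.0
        assert bray_curtis(q, p) == 1.0

    def test_arithmetic_example(self):
        p = TaxonomicProfile("phylum", {"A": 0.7, "B": 0.3})
        q = TaxonomicProfile("phylum", {"A": 0.4, "B": 0.6})
        assert bray_curtis(p, q) == pytest.approx(0.3)

    def test_rank_mismatch_rejected(self):
        p = TaxonomicProfile("phylum", {"A": 1.0})
        q = TaxonomicProfile("class", {"A": 1.0})
        with pytest.raises(InvalidProfileError):
            bray_curtis(p, q)


def _toy_fit(weights, sig_ids):
    from domainmix import MixtureFit

    return MixtureFit(
        signature_ids=tuple(sig_ids),
        weights=np.asarray(weights, dtype=float),
        reconstruction=DomainProfile(("f1",), np.array([1.0])),
        loglik_trace=(0.0,),
        n_iter=1,
        converged=True,
        fdu=0.0,
        unsupported_mass=0.0,
    )


class TestAggregation:
    TAX = TaxonomyTable(
        {
            "sigA": LineageRecord({"superkingdom": "Bacteria", "phylum": "Firmicutes"}),
            "sigB": LineageRecord({"superkingdom": "Archaea", "phylum": "Euryarchaeota"}),
            "sigC": LineageRecord({"superkingdom": "Viruses"}, source_type="metagenome"),
        }
    )

    def test_superkingdom_sums(self):
        fit = _toy_fit([0.6, 0.3, 0.1], ("sigA", "sigB", "sigC"))
        tp = aggregate_weights(fit, self.TAX, "superkingdom")
        assert tp.abundances == pytest.approx(
            {"Bacteria": 0.6, "Archaea": 0.3, "Viruses": 0.1}
        )

    def test_missing_rank_goes_to_unclassified(self):
        fit = _toy_fit([0.6, 0.3, 0.1], ("sigA", "sigB", "sigC"))
        tp = aggregate_weights(fit, self.TAX, "phylum")
        assert tp.get("unclassified Viruses") == pytest.approx(0.1)
        assert tp.get("Firmicutes") == pytest.approx(0.6)

    def test_mass_conserved_on_random_weights(self, rng):
        for _ in range(10):
            w = rng.dirichlet(np.ones(3))
            w = w / w.sum()
            w = w / w.sum()
            fit = _toy_fit(w, ("sigA", "sigB", "sigC"))
            for rank in ("superkingdom", "phylum", "genus"):
                tp = aggregate_weights(fit, self.TAX, rank)
                assert sum(tp.abundances.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_signature_listed_in_error(self):
        fit = _toy_fit([0.5, 0.5], ("sigA", "sigZ"))
        with pytest.raises(Exception, match="sigZ"):
            aggregate_weights(fit, self.TAX, "superkingdom")


class TestRenormalizeSubset:
    def test_two_domain_restriction(self):
        p = TaxonomicProfile(
            "superkingdom", {"Archaea": 0.2, "Bacteria": 0.6, "Viruses": 0.2}
        )
        out = renormalize_subset(p, {"Archaea", "Bacteria"})
        assert out.get("Archaea") == pytest.approx(0.25)
        assert out.get("Bacteria") == pytest.approx(0.75)

    def test_full_support_unchanged(self):
        p = TaxonomicProfile("superkingdom", {"Archaea": 0.25, "Bacteria": 0.75})
        out = renormalize_subset(p, {"Archaea", "Bacteria"})
        assert out.abundances == pytest.approx(p.abundances)

    def test_zero_mass_subset_rejected(self):
        p = TaxonomicProfile(
            "superkingdom", {"Archaea": 0.0, "Bacteria": 0.0, "Viruses": 1.0}
        )
        with pytest.raises(InvalidProfileError):
            renormalize_subset(p, {"Archaea", "Bacteria"})
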