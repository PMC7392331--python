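"""Sequential best-worst conditional logit: likelihood, fit, recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import bwspref as b
from bwspref import uganda
from bwspref.clogit import SeparationWarning
from bwspref.data import RESPONSES_COLUMNS
from tests.conftest import make_scenario


def enumeration_loglik(responses, utilities):
    """Independent brute-force oracle: per record, log P(best) +
    log P(worst | best) from first principles, pure python."""
    util = {
        item: float(u)
        for item, u in zip(responses.catalogue.ids, utilities)
    }
    total = 0.0
    for row in responses.responses.itertuples(index=False):
        task = responses.design.task_items(row.task_id)
        denom_b = sum(math.exp(util[j]) for j in task)
        total += math.log(math.exp(util[row.best]) / denom_b)
        remaining = [j for j in task if j != row.best]
        denom_w = sum(math.exp(-util[j]) for j in remaining)
        total += math.log(math.exp(-util[row.worst]) / denom_w)
    return total


def random_responses(design, rng):
    rows = []
    for resp in range(rng.integers(3, 7)):
        for t in range(1, design.n_tasks + 1):
            task = design.task_items(t)
            best, worst = rng.choice(len(task), size=2, replace=False)
            rows.append(
                (f"r{resp}", "s", t, task[best], task[worst])
            )
    return b.ResponseSet(
        design.catalogue,
        design,
        pd.DataFrame(rows, columns=RESPONSES_COLUMNS),
    )


class TestLikelihood:
    def test_matches_enumeration_oracle_small_instances(self):
        """On 30 random small instances (J <= 5, k = 3) the module
        log-likelihood equals brute-force enumeration of
        P(best) * P(worst|best) to 1e-10 at random utilities."""
        rng = np.random.default_rng(2024)
        for trial in range(30):
            J = int(rng.integers(3, 6))
            T = J  # T*k divisible by J with k=3 when T=J
            design = b.generate_design(J, k=3, T=T, seed=trial)
            rs = random_responses(design, rng)
            long = b.expand_to_choice_long(rs)
            beta = rng.normal(0, 1.2, J - 1)
            util = np.append(beta, -beta.sum())
            assert b.sequential_loglik(long, util) == pytest.approx(
                enumeration_loglik(rs, util), abs=1e-10
            )


class TestFit:
    def test_symmetric_data_gives_zero_estimates(self):
        """All 12 ordered (best, worst) pairs of one task, one each:
        perfect symmetry forces every estimate to zero."""
        cat = b.ItemCatalogue(
            tuple(b.Item(i, i) for i in ("a", "b", "c", "d"))
        )
        design = b.Design(cat, (("a", "b", "c", "d"),))
        rows = [
            (f"r{i}", "s", 1, best, worst)
            for i, (best, worst) in enumerate(
                itertools.permutations(cat.ids, 2)
            )
        ]
        rs = b.ResponseSet(
            cat, design, pd.DataFrame(rows, columns=RESPONSES_COLUMNS)
        )
        fit = b.fit_sequential_clogit(b.expand_to_choice_long(rs))
        assert np.all(np.abs(fit.utilities().to_numpy()) < 1e-6)

    def test_estimates_sum_to_zero(self, simulated_responses):
        fit = b.fit_sequential_clogit(
            b.expand_to_choice_long(simulated_responses)
        )
        assert abs(fit.utilities().sum()) < 1e-10
        assert fit.converged
        # convergence is by gradient norm or relative loglik change;
        # either way the gradient is far below estimation noise
        assert fit.grad_norm < 1e-5

    def test_omitted_level_invariance(self, design16):
        """Recovered per-item utilities (and SEs) do not depend on which
        item is omitted from the effects coding."""
        rs = b.simulate_responses(
            make_scenario(design16, uganda.clogit_utilities(), n=150, seed=8)
        )
        long = b.expand_to_choice_long(rs)
        fits = [
            b.fit_sequential_clogit(long, omitted=item)
            for item in ("health", "security", "ict", "legislature")
        ]
        ref = fits[0]
        for fit in fits[1:]:
            assert np.allclose(
                fit.utilities().to_numpy(),
                ref.utilities().to_numpy(),
                atol=1e-6,
            )
            assert np.allclose(
                fit.table["se"], ref.table["se"], atol=1e-6
            )
            assert fit.loglik == pytest.approx(ref.loglik, abs=1e-6)

    def test_catalogue_permutation_invariance(self, design16):
        """Relabelling/permuting the catalogue changes the coding but
        not the fitted per-item utilities."""
        rs = b.simulate_responses(
            make_scenario(design16, uganda.clogit_utilities(), n=120, seed=13)
        )
        fit = b.fit_sequential_clogit(b.expand_to_choice_long(rs))
        perm = np.random.default_rng(1).permutation(16)
        cat2 = b.ItemCatalogue(
            tuple(design16.catalogue.items[j] for j in perm)
        )
        design2 = b.Design(cat2, design16.tasks)
        rs2 = b.ResponseSet(cat2, design2, rs.responses.copy())
        fit2 = b.fit_sequential_clogit(b.expand_to_choice_long(rs2))
        u1, u2 = fit.utilities(), fit2.utilities()
        for item in design16.catalogue.ids:
            assert u2[item] == pytest.approx(u1[item], abs=1e-6)

    def test_ranking_agrees_with_count_analysis_at_large_n(self, design16):
        """At n=2000 and sigma=0 the logit and count analyses agree on
        the top item; under symmetric exposure they agree everywhere.

        Agreement at the bottom is not tested at the survey design:
        the two lowest utilities are 0.06 apart and unequal pairwise
        co-occurrence tilts expected count scores, so counts and logit
        can durably disagree there — exactly as the published tables
        do (count analysis ranks legislature last, the logit public
        administration).
        """
        rs = b.simulate_responses(
            make_scenario(design16, uganda.clogit_utilities(), n=2000, seed=5)
        )
        fit = b.fit_sequential_clogit(b.expand_to_choice_long(rs))
        count = b.mean_bw_scores(rs)
        assert fit.table.loc[fit.table["rank"] == 1, "item_id"].item() == \
            count.table.loc[count.table["rank"] == 1, "item_id"].item()
        # symmetric exposure: every task shows all items
        cat = b.ItemCatalogue.from_generic(4)
        sym = b.Design(cat, (tuple(cat.ids),) * 4)
        rs_sym = b.simulate_responses(
            make_scenario(sym, np.array([1.0, 0.3, -0.3, -1.0]), n=2000,
                          seed=6)
        )
        fit_sym = b.fit_sequential_clogit(b.expand_to_choice_long(rs_sym))
        count_sym = b.mean_bw_scores(rs_sym)
        assert list(fit_sym.table["rank"]) == list(count_sym.table["rank"])

    def test_separation_warning(self):
        """An item chosen best at every appearance triggers a
        separation warning."""
        cat = b.ItemCatalogue(
            tuple(b.Item(i, i) for i in ("a", "b", "c", "d"))
        )
        design = b.Design(cat, (("a", "b", "c", "d"),))
        rows = [
            (f"r{i}", "s", 1, "a", w) for i, w in enumerate(("b", "c", "d"))
        ]
        rs = b.ResponseSet(
            cat, design, pd.DataFrame(rows, columns=RESPONSES_COLUMNS)
        )
        with pytest.warns(SeparationWarning):
            fit = b.fit_sequential_clogit(
                b.expand_to_choice_long(rs), max_iter=500
            )
        assert fit.separation_flag


class TestOmittedRecovery:
    def test_forced_two_parameter_example(self):
        beta = np.array([0.5, 0.3])
        vcov = np.array([[0.04, 0.01], [0.01, 0.09]])
        beta_o, se_o = b.recover_omitted(beta, vcov)
        assert beta_o == pytest.approx(-0.8)
        assert se_o == pytest.approx(np.sqrt(0.15))

    def test_zero_coefficients(self):
        beta = np.zeros(4)
        vcov = np.eye(4) * 0.01
        beta_o, se_o = b.recover_omitted(beta, vcov)
        assert beta_o == 0.0
        assert se_o == pytest.approx(0.2)

    def test_matches_delta_method_oracle(self):
        """SE of the recovered level equals the delta-method SE of
        a' beta with a = -1 (computed independently)."""
        rng = np.random.default_rng(6)
        beta = rng.normal(size=5)
        A = rng.normal(size=(5, 5))
        vcov = A @ A.T / 10
        beta_o, se_o = b.recover_omitted(beta, vcov)
        a = -np.ones(5)
        assert beta_o == pytest.approx(a @ beta, abs=1e-12)
        assert se_o == pytest.approx(np.sqrt(a @ vcov @ a), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="does not match"):
            b.recover_omitted(np.zeros(3), np.eye(2))


class TestRanking:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rank_items_sorted_descending(self, small_design, seed):
        rng = np.random.default_rng(seed)
        rs = random_responses(small_design, rng)
        fit = b.fit_sequential_clogit(
            b.expand_to_choice_long(rs), max_iter=500
        )
        ranked = b.rank_items(fit)
        est = ranked["estimate"].to_numpy()
        assert list(ranked["rank"]) == list(range(1, len(est) + 1))
        assert np.all(np.diff(est) <= 1e-12)
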