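"""NMF consensus subtyping and the 4-metabolite logistic risk score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import NMF as SklearnNMF

from ctcmet.subtyping import (
    DEFAULT_PANEL,
    FINGERPRINT,
    RiskModel,
    assign_subgroups,
    consensus_cluster,
    fit_risk_model,
    nmf,
    published_risk_model,
    risk_score,
    select_fingerprint,
    youden_cutoff,
)
from ctcmet.synthetic import (
    CohortSimConfig,
    SingleCellMatrix,
    generate_ctc_cohort,
    simulate_from_risk_model,
)

from conftest import make_cells

# Frozen with 60-digit decimal arithmetic: 10**-3.694 / (1 + 10**-3.694)
SCORE_AT_ZERO = 2.02261000079601193684311809380018355322651361360006905876e-4


class TestNmf:
    def test_rank_one_exact(self, rng):
        w = rng.uniform(0.5, 2.0, 30)
        h = rng.uniform(0.5, 2.0, 8)
        V = np.outer(w, h)
        res = nmf(V, k=1, seed=0)
        rel = np.linalg.norm(V - res.W @ res.H) / np.linalg.norm(V)
        assert rel < 1e-6

    def test_objective_trace_never_increases(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            V = rng.uniform(0.0, 1.0, (50, 11))
            res = nmf(V, k=3, seed=seed, max_iter=300)
            t = res.objective_trace
            assert np.all(np.diff(t) <= 1e-10 * np.maximum(t[:-1], 1e-30))

    def test_block_structure_recovered(self, rng):
        # two 25-cell blocks active on disjoint metabolite sets
        V = np.full((50, 10), 1e-3)
        V[:25, :5] = rng.uniform(1.0, 2.0, (25, 5))
        V[25:, 5:] = rng.uniform(1.0, 2.0, (25, 5))
        labels = nmf(V, k=2, seed=1).labels()
        assert len(np.unique(labels[:25])) == 1
        assert len(np.unique(labels[25:])) == 1
        assert labels[0] != labels[-1]

    def test_competitive_with_sklearn_mu_solver(self, rng):
        """Independent cross-check: same objective class as sklearn's MU NMF."""
        V = rng.uniform(0.1, 2.0, (60, 11))
        mine = nmf(V, k=3, seed=0, max_iter=2000, tol=1e-9)
        err_mine = np.linalg.norm(V - mine.W @ mine.H)
        sk = SklearnNMF(
            n_components=3, solver="mu", init="random", random_state=0,
            max_iter=2000, tol=1e-9,
        ).fit(V)
        err_sk = np.linalg.norm(V - sk.transform(V) @ sk.components_)
        assert err_mine <= err_sk * 1.02

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            nmf(np.array([[1.0, -0.1], [0.2, 0.3], [0.1, 0.1]]), k=1)
        with pytest.raises(ValueError, match="rank"):
            nmf(rng.uniform(0, 1, (5, 4)), k=0)


class TestConsensusCluster:
    def test_perfectly_stable_clustering(self, rng):
        # two blocks active on disjoint metabolites: every run repartitions
        # them identically
        V = np.full((40, 6), 1e-3)
        V[:20, :3] = rng.lognormal(0.0, 0.05, (20, 3))
        V[20:, 3:] = rng.lognormal(0.0, 0.05, (20, 3))
        cells = make_cells(V, [f"m{j}" for j in range(6)])
        res = consensus_cluster(cells, k_range=[2, 3], n_runs=10, seed=0)
        C2 = res.consensus[2]
        assert set(np.unique(np.round(C2, 12))) <= {0.0, 1.0}
        assert res.cophenetic[2] == pytest.approx(1.0)
        assert res.selected_rank == 2
        labels = res.cell_labels.to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_consensus_matrix_invariants(self, small_cohort):
        cells, _, _ = small_cohort
        sub = make_cells(
            cells.concentrations.to_numpy()[:60], cells.metabolite_names
        )
        res = consensus_cluster(sub, k_range=[2, 3], n_runs=5, seed=1)
        for C in res.consensus.values():
            assert np.allclose(C, C.T)
            assert np.allclose(np.diag(C), 1.0)
            assert C.min() >= 0.0 and C.max() <= 1.0 + 1e-12

    def test_planted_two_subgroups_select_rank_two(self):
        # separated regime: 4x shift on the fingerprint, 30% RSD, ~300 cells
        hits = 0
        for seed in range(3):
            cells, _, _ = generate_ctc_cohort(
                CohortSimConfig(n_patients=78, biological_rsd=0.30, seed=seed)
            )
            res = consensus_cluster(cells, seed=seed)
            hits += res.selected_rank == 2
        assert hits == 3

    def test_noise_less_coherent_than_structure(self, rng):
        structured, _, _ = generate_ctc_cohort(
            CohortSimConfig(n_patients=40, biological_rsd=0.30, seed=11)
        )
        res_s = consensus_cluster(structured, k_range=[2], n_runs=15, seed=11)
        n = structured.concentrations.shape[0]
        noise = make_cells(
            rng.uniform(0.5, 1.5, (n, 11)), structured.metabolite_names
        )
        res_n = consensus_cluster(noise, k_range=range(2, 7), n_runs=15, seed=11)
        assert max(res_n.cophenetic.values()) <= res_s.cophenetic[2]


class TestSelectFingerprint:
    def test_recovers_planted_fingerprint(self):
        model = published_risk_model()
        hits = 0
        for seed in range(10):
            cells, labels = simulate_from_risk_model(model, 2000, seed=seed)
            rng = np.random.default_rng(10_000 + seed)
            conc = cells.concentrations.copy()
            for extra in [m for m in DEFAULT_PANEL if m not in FINGERPRINT]:
                conc[extra] = rng.lognormal(0.0, 0.5, len(conc))
            full = SingleCellMatrix(
                concentrations=conc[list(DEFAULT_PANEL)], cells=cells.cells
            )
            # exact-set recovery needs multiplicity control: at plain alpha
            # each noise metabolite survives w.p. ~alpha, capping the exact
            # rate near (1-alpha)^7
            fp = select_fingerprint(full, labels, alpha=0.05 / len(DEFAULT_PANEL))
            hits += set(fp) == set(FINGERPRINT)
            # at the default alpha the planted four are always retained
            fp_default = select_fingerprint(full, labels)
            assert set(FINGERPRINT) <= set(fp_default)
        assert hits >= 9

    def test_null_labels_select_little(self, rng):
        empties, sizes = 0, []
        for seed in range(10):
            r = np.random.default_rng(seed)
            cells = make_cells(r.lognormal(0, 0.5, (400, 6)), [f"m{j}" for j in range(6)])
            labels = pd.Series(r.integers(1, 3, 400), index=cells.cell_ids)
            fp = select_fingerprint(cells, labels)
            empties += len(fp) == 0
            sizes.append(len(fp))
        assert empties >= 5          # majority of null runs keep nothing
        assert np.mean(sizes) < 1.0  # per-metabolite type-I rate ~ alpha

    def test_separating_metabolite_ranked_first(self, rng):
        n = 300
        X = rng.lognormal(0.0, 0.3, (n, 4))
        labels = pd.Series([1] * (n // 2) + [2] * (n // 2))
        X[labels.to_numpy() == 2, 1] += 10.0  # metabolite m1 separates perfectly
        cells = make_cells(X, [f"m{j}" for j in range(4)])
        labels.index = cells.cell_ids
        with pytest.warns(UserWarning):
            fp = select_fingerprint(cells, labels)
        assert fp[0] == "m1"


class TestRiskModel:
    def test_published_constants(self):
        m = published_risk_model()
        assert m.metabolite_names == (
            "glutamic acid", "malic acid", "aspartic acid", "lactic acid",
        )
        assert m.coefficients == (-0.932, 3.967, -0.166, -1.822)
        assert m.intercept == -3.694
        assert m.threshold == 0.420

    def test_score_at_zero_abundance(self):
        m = published_risk_model()
        s = risk_score(m, dict.fromkeys(m.metabolite_names, 0.0))
        assert abs(s - SCORE_AT_ZERO) < 1e-12

    def test_logit_zero_construction(self):
        # malic acid alone cancels the intercept: eta = 0 -> score 0.5
        m = published_risk_model()
        ab = dict.fromkeys(m.metabolite_names, 0.0)
        ab["malic acid"] = 3.694 / 3.967
        assert risk_score(m, ab) == pytest.approx(0.5, abs=1e-12)

    def test_keyed_by_name_not_position(self, rng):
        m = published_risk_model()
        df = pd.DataFrame(
            rng.lognormal(0, 0.4, (20, 4)), columns=list(m.metabolite_names)
        )
        shuffled = df[list(reversed(m.metabolite_names))]
        assert np.allclose(risk_score(m, df), risk_score(m, shuffled))

    def test_missing_metabolite_refused(self):
        m = published_risk_model()
        with pytest.raises(KeyError, match="missing"):
            risk_score(m, {"malic acid": 1.0})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 50.0), min_size=4, max_size=4))
    def test_score_strictly_inside_unit_interval(self, abundances):
        m = published_risk_model()
        s = risk_score(m, dict(zip(m.metabolite_names, abundances)))
        assert 0.0 < s < 1.0

    def test_monotone_in_signed_coefficients(self):
        m = published_risk_model()
        base = dict.fromkeys(m.metabolite_names, 1.0)
        s0 = risk_score(m, base)
        up_malic = dict(base, **{"malic acid": 1.5})
        up_lactic = dict(base, **{"lactic acid": 1.5})
        assert risk_score(m, up_malic) > s0      # positive coefficient
        assert risk_score(m, up_lactic) < s0     # negative coefficient

    def test_json_roundtrip(self, tmp_path):
        m = published_risk_model()
        m2 = RiskModel.from_json(m.to_json())
        assert m2 == m


class TestFitRiskModel:
    def test_sign_matches_separation_direction(self, rng):
        n = 200
        X = np.abs(rng.normal(1.0, 0.2, (n, 1)))
        X[n // 2:, 0] += 5.0
        cells = make_cells(X, ["malic acid"])
        labels = pd.Series([1] * (n // 2) + [2] * (n // 2), index=cells.cell_ids)
        with pytest.warns(UserWarning, match="penalized"):
            m = fit_risk_model(cells, labels, fingerprint=["malic acid"],
                               high_risk_label=2)
        assert m.coefficients[0] > 0

    def test_self_consistent_decision_boundary(self):
        model = published_risk_model()
        cells, labels = simulate_from_risk_model(model, 4000, seed=3)
        fitted = fit_risk_model(
            cells, labels, fingerprint=model.metabolite_names, high_risk_label="C2"
        )
        scores = risk_score(fitted, cells.concentrations)
        pred = pd.Series(
            np.where(scores >= fitted.threshold, "C2", "C1"), index=cells.cell_ids
        )
        refit = fit_risk_model(
            cells, pred, fingerprint=model.metabolite_names, high_risk_label="C2"
        )
        scores2 = risk_score(refit, cells.concentrations)
        side1 = scores >= fitted.threshold
        side2 = scores2 >= refit.threshold
        # asymptotic property; finite-n boundary cells may flip
        assert (side1 == side2).mean() >= 0.98

    def test_outcome_orientation(self, small_cohort):
        cells, patients, truth = small_cohort
        labels = truth.true_cell_subgroup_labels.map({"C1": 1, "C2": 2})
        m = fit_risk_model(cells, labels, outcomes=patients["outcome"])
        scores = risk_score(m, cells.concentrations)
        # C2-true cells must score higher on average than C1-true cells
        c2_scores = scores[(truth.true_cell_subgroup_labels == "C2").to_numpy()]
        c1_scores = scores[(truth.true_cell_subgroup_labels == "C1").to_numpy()]
        assert c2_scores.mean() > c1_scores.mean()


class TestYoudenCutoff:
    def test_perfect_separation(self):
        cut = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert cut == 0.8

    def test_three_point_enumeration(self):
        assert youden_cutoff([0.1, 0.5, 0.9], [0, 1, 1]) == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            s = rng.random(50).round(2)  # ties likely
            y = rng.integers(0, 2, 50)
            if y.sum() in (0, 50):
                continue
            best_j, best_c = -np.inf, None
            for c in np.unique(s):
                pred = s >= c
                tp = (pred & (y == 1)).sum()
                tn = (~pred & (y == 0)).sum()
                j = tp / y.sum() + tn / (50 - y.sum()) - 1
                if j > best_j:
                    best_j, best_c = j, c
            assert youden_cutoff(s, y) == best_c

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        cut = youden_cutoff(s, y)
        for f in (np.exp, lambda x: 2 * x + 1, lambda x: x**3):
            assert youden_cutoff(f(s), y) == pytest.approx(f(cut))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([0.5, 0.5], [0, 1])
        with pytest.raises(ValueError):
            youden_cutoff([0.1, 0.2], [1, 1])


class TestAssignSubgroups:
    def test_published_boundary_is_closed(self):
        assert assign_subgroups([0.420])[0] == "C2"
        assert assign_subgroups([0.419])[0] == "C1"

    def test_all_low_scores(self):
        labels = assign_subgroups([0.1, 0.2, 0.3])
        assert (labels == "C1").all()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            assign_subgroups([0.5], threshold=1.5)


class TestEndToEndRecovery:
    def test_planted_subgroups_recovered_through_full_chain(self):
        """consensus -> fingerprint -> risk model recovers planted membership."""
        agreements = []
        for seed in range(6):
            cells, patients, truth = generate_ctc_cohort(
                CohortSimConfig(n_patients=60, seed=seed)
            )
            res = consensus_cluster(cells, seed=seed)
            labels = res.cell_labels
            fp = select_fingerprint(cells, labels)
            if not fp:
                fp = list(FINGERPRINT)
            m = fit_risk_model(cells, labels, fingerprint=fp,
                               outcomes=patients["outcome"])
            pred = assign_subgroups(risk_score(m, cells.concentrations), m.threshold)
            tl = truth.true_cell_subgroup_labels.to_numpy()
            agreements.append(max((pred == tl).mean(), (pred != tl).mean()))
        assert np.mean(agreements) >= 0.9
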