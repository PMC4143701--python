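"""Nearest-completer imputation: worked example, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from longgwas.cohort import CohortConfig, simulate_cohort
from longgwas.imputation import (
    DistanceRecord,
    HotDeckImputer,
    ImputationWeights,
    average_exam_years,
    compute_normalization,
    compute_weights,
    distance,
    distance_matrix,
    extract_completers,
    impute_ages,
    mean_impute_sbp,
    nearest_completer,
    select_nearest,
    transfer_values,
)
from longgwas.phenotypes import EXAM_VARS, PhenotypeTable, exam_cols

from conftest import (
    CANDIDATE_DISTANCES,
    DONOR_DISTANCE,
    DONOR_ID,
    make_pheno,
)


# --------------------------------------------------------------------------
# independent brute-force oracle for the distance
# --------------------------------------------------------------------------

def brute_force_distance(nrow, crow, weights, constants):
    """Term-by-term re-implementation of the weighted distance."""
    total = 0.0
    wmap = {"AGE": weights.w_age, "SBP": 1.0, "MED": weights.w_med, "SMK": weights.w_smk}
    for var in EXAM_VARS:
        for i in range(4):
            vn, vc = nrow[f"{var}{i}"], crow[f"{var}{i}"]
            if var != "AGE" and pd.isna(vn):
                continue  # indicator gates the term off
            mu, sd = constants.mu[var][i], constants.sigma[var][i]
            if sd == 0 or wmap[var] == 0:
                continue
            zn, zc = (vn - mu) / sd, (vc - mu) / sd
            total += wmap[var] * (zn - zc) ** 2
    return total


# --------------------------------------------------------------------------
# steps 1-3
# --------------------------------------------------------------------------

class TestSteps:
    def test_completer_partition(self, worked_completers, worked_noncompleter_row):
        rows = [worked_noncompleter_row.to_dict()] + [
            r.to_dict() for _, r in worked_completers.df.iterrows()
        ]
        pheno = make_pheno(rows)
        comp, nonc = extract_completers(pheno)
        assert comp.sum() == 5 and nonc.sum() == 1 and not nonc[1]

    def test_missing_single_value_is_noncompleter(self, worked_donor_row):
        row = worked_donor_row.to_dict()
        row["SMK2"] = np.nan
        pheno = make_pheno([row, worked_donor_row.to_dict() | {"ID": "other"}])
        comp, _ = extract_completers(pheno)
        assert list(comp) == [False, True]

    def test_no_completers_hard_error(self, worked_noncompleter_row):
        with pytest.raises(ValueError, match="no completers"):
            extract_completers(make_pheno([worked_noncompleter_row.to_dict()]))

    def test_average_exam_years_arithmetic(self):
        rows = [
            {"ID": "A", "SEX": 0, "BIRTH_YEAR": 1952, "AGE0": 40.0, "SBP0": 120.0},
            {"ID": "B", "SEX": 0, "BIRTH_YEAR": 1950, "AGE0": 44.0, "SBP0": 121.0},
        ]
        pheno = make_pheno(rows)
        with pytest.raises(ValueError, match="attended by nobody"):
            average_exam_years(pheno)
        for i, yr in enumerate((1998, 2003, 2009), start=1):
            for r in rows:
                r[f"AGE{i}"] = float(yr - r["BIRTH_YEAR"])
        assert average_exam_years(make_pheno(rows)) == (1993, 1998, 2003, 2009)

    def test_average_years_match_mean_round_oracle(self):
        cohort = simulate_cohort(
            CohortConfig(n_individuals=100, n_snps=0, dropout_mode="mcar", seed=30)
        )
        pheno = cohort.phenotypes_observed
        got = average_exam_years(pheno)
        ages = pheno.values("AGE")
        by = pheno.df["BIRTH_YEAR"].to_numpy(float)
        for i in range(4):
            obs = ~np.isnan(ages[:, i])
            assert got[i] == int(round(np.mean(by[obs] + ages[obs, i])))

    def test_impute_ages_subtraction(self):
        pheno = make_pheno(
            [{"ID": "A", "SEX": 0, "BIRTH_YEAR": 1960, "SBP1": 130.0}]
        )
        out = impute_ages(pheno, (1993, 1998, 2003, 2009))
        assert list(out.values("AGE")[0]) == [33, 38, 43, 49]

    def test_impute_ages_keeps_observed(self):
        pheno = make_pheno(
            [{"ID": "A", "SEX": 0, "BIRTH_YEAR": 1960, "AGE1": 39.0, "SBP0": 120.0}]
        )
        out = impute_ages(pheno, (1993, 1998, 2003, 2009))
        assert out.values("AGE")[0, 1] == 39.0

    def test_masked_ages_recovered_exactly(self):
        cohort = simulate_cohort(
            CohortConfig(n_individuals=150, n_snps=0, dropout_mode="mar_age", seed=31)
        )
        obs = cohort.phenotypes_observed
        out = impute_ages(obs, average_exam_years(obs))
        assert np.array_equal(out.values("AGE"), cohort.phenotypes_complete.values("AGE"))

    def test_perfect_correlation_beta_one(self):
        rng = np.random.default_rng(2)
        rows = []
        for k in range(10):
            sbp0 = float(rng.uniform(100, 150))
            sbp3 = 3 * sbp0  # ΔSBP = 2·SBP0 exactly
            rows.append(
                {"ID": f"C{k}", "SEX": 0, "BIRTH_YEAR": 1950,
                 "AGE0": 40.0, "AGE1": 45.0, "AGE2": 50.0, "AGE3": 56.0,
                 "SBP0": sbp0, "SBP1": sbp0, "SBP2": sbp0, "SBP3": sbp3,
                 **{f"MED{i}": float(rng.integers(0, 2)) for i in range(4)},
                 **{f"SMK{i}": float(rng.integers(0, 2)) for i in range(4)}}
            )
        w = compute_weights(make_pheno(rows))
        assert w.beta == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_med_gives_zero_weight_with_warning(self):
        rng = np.random.default_rng(3)
        rows = []
        for k in range(10):
            rows.append(
                {"ID": f"C{k}", "SEX": 0, "BIRTH_YEAR": 1950,
                 **{f"AGE{i}": float(40 + 5 * i + k) for i in range(4)},
                 **{f"SBP{i}": float(rng.uniform(100, 160)) for i in range(4)},
                 **{f"MED{i}": 0.0 for i in range(4)},
                 **{f"SMK{i}": float(rng.integers(0, 2)) for i in range(4)}}
            )
        with pytest.warns(UserWarning, match="zero-variance"):
            w = compute_weights(make_pheno(rows))
        assert w.alpha_2 == 0.0 and w.w_med == 0.0

    def test_weights_match_direct_correlation_oracle(self):
        rng = np.random.default_rng(4)
        rows = []
        for k in range(5):
            rows.append(
                {"ID": f"C{k}", "SEX": 0, "BIRTH_YEAR": 1950,
                 **{f"AGE{i}": float(40 + 5 * i + rng.integers(0, 5)) for i in range(4)},
                 **{f"SBP{i}": float(rng.uniform(100, 160)) for i in range(4)},
                 **{f"MED{i}": float(rng.integers(0, 2)) for i in range(4)},
                 **{f"SMK{i}": float(rng.integers(0, 2)) for i in range(4)}}
            )
        pheno = make_pheno(rows)
        w = compute_weights(pheno)

        def corr(a, b):
            a, b = np.asarray(a, float), np.asarray(b, float)
            am, bm = a - a.mean(), b - b.mean()
            return (am @ bm) / np.sqrt((am @ am) * (bm @ bm))

        sbp = pheno.values("SBP")
        dsbp = sbp[:, 3] - sbp[:, 0]
        assert w.alpha_1 == pytest.approx(corr(dsbp, pheno.values("AGE")[:, 0]), abs=1e-12)
        assert w.alpha_2 == pytest.approx(corr(dsbp, pheno.values("MED")[:, 0]), abs=1e-12)
        assert w.alpha_3 == pytest.approx(corr(dsbp, pheno.values("SMK")[:, 0]), abs=1e-12)
        assert w.beta == pytest.approx(corr(dsbp, sbp[:, 0]), abs=1e-12)


class TestNormalization:
    def test_z_score_identities(self, small_complete_pheno):
        constants = compute_normalization(small_complete_pheno)
        mu, sd = constants.mu["SBP"][0], constants.sigma["SBP"][0]
        z = constants.normalize("SBP", np.array([[mu, 0, 0, 0], [mu + sd, 0, 0, 0]]))
        assert z[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert z[1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_mean_sd_oracle(self, small_complete_pheno):
        constants = compute_normalization(small_complete_pheno)
        vals = small_complete_pheno.values("SBP")
        for i in range(4):
            assert constants.mu["SBP"][i] == pytest.approx(vals[:, i].mean(), abs=1e-12)
            assert constants.sigma["SBP"][i] == pytest.approx(
                np.sqrt((vals[:, i] ** 2).mean() - vals[:, i].mean() ** 2), rel=1e-10
            )


class TestDistance:
    def _weights(self):
        return ImputationWeights(alpha_1=0.3, alpha_2=-0.2, alpha_3=0.1, beta=0.5)

    def test_identical_values_give_zero(self, small_complete_pheno):
        constants = compute_normalization(small_complete_pheno)
        row = small_complete_pheno.df.iloc[0]
        assert distance(row, row, self._weights(), constants) == pytest.approx(0.0, abs=1e-12)

    def test_single_sbp_term_unit_difference(self, small_complete_pheno):
        constants = compute_normalization(small_complete_pheno)
        w = self._weights()
        crow = small_complete_pheno.df.iloc[0].copy()
        nrow = crow.copy()
        nrow["ID"] = "N"
        for var in ("SBP", "MED", "SMK"):
            for i in range(4):
                nrow[f"{var}{i}"] = np.nan
        # only SBP_0 observed, exactly one normalized unit away from the donor
        nrow["SBP0"] = crow["SBP0"] + constants.sigma["SBP"][0]
        assert distance(nrow, crow, w, constants) == pytest.approx(1.0, abs=1e-12)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(5)
        for rep in range(30):
            n = int(rng.integers(6, 15))
            rows = []
            for k in range(n):
                row = {"ID": f"I{k:02d}", "SEX": 0, "BIRTH_YEAR": 1950,
                       **{f"AGE{i}": float(40 + 5 * i + rng.integers(-3, 4)) for i in range(4)},
                       **{f"SBP{i}": float(rng.uniform(100, 170)) for i in range(4)},
                       **{f"MED{i}": float(rng.integers(0, 2)) for i in range(4)},
                       **{f"SMK{i}": float(rng.integers(0, 2)) for i in range(4)}}
                if k == 0:  # the non-completer loses random SBP/MED/SMK slots
                    for var in ("SBP", "MED", "SMK"):
                        for i in range(4):
                            if rng.uniform() < 0.4:
                                row[f"{var}{i}"] = np.nan
                rows.append(row)
            pheno = make_pheno(rows)
            constants = compute_normalization(pheno)
            w = ImputationWeights(*rng.uniform(-0.9, 0.9, 3), beta=float(rng.uniform(0.2, 0.9)))
            nrow, crow = pheno.df.iloc[0], pheno.df.iloc[1]
            got = distance(nrow, crow, w, constants)
            want = brute_force_distance(nrow, crow, w, constants)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_nearest_equals_brute_force_argmin(self, small_complete_pheno):
        constants = compute_normalization(small_complete_pheno)
        w = self._weights()
        nrow = small_complete_pheno.df.iloc[0].copy()
        nrow["ID"] = "N"
        nrow["SBP3"] = np.nan
        donors = PhenotypeTable(small_complete_pheno.df.iloc[1:])
        got_id, got_d = nearest_completer(nrow, donors, w, constants)
        dists = {
            row["ID"]: brute_force_distance(nrow, row, w, constants)
            for _, row in donors.df.iterrows()
        }
        want_id = min(sorted(dists), key=lambda i: dists[i])
        assert got_id == want_id and got_d == pytest.approx(dists[want_id], rel=1e-12)


class TestDonorSelection:
    def test_worked_example_candidate_distances_select_donor(self):
        records = [
            DistanceRecord("T2DG2501049", cid, d)
            for cid, d in CANDIDATE_DISTANCES.items()
        ]
        best = select_nearest(records)
        assert best.completer_id == DONOR_ID and best.d == DONOR_DISTANCE

    def test_single_completer_always_wins(self):
        best = select_nearest([DistanceRecord("N", "onlyone", 99.9)])
        assert best.completer_id == "onlyone"

    def test_tie_breaks_to_smaller_id(self):
        records = [
            DistanceRecord("N", "zzz", 0.5),
            DistanceRecord("N", "aaa", 0.5),
            DistanceRecord("N", "mmm", 0.7),
        ]
        assert select_nearest(records).completer_id == "aaa"


class TestTransfer:
    def test_worked_example_value_transfer(self, worked_noncompleter_row, worked_donor_row):
        out, filled = transfer_values(worked_noncompleter_row, worked_donor_row)
        assert out["SBP3"] == 149.0  # the donated final SBP
        assert out["SBP0"] == 110.0
        assert out["MED3"] == 1.0 and out["MED0"] == 0.0
        assert out["SMK0"] == 0.0 and out["SMK3"] == 0.0
        assert set(filled) == {"SBP0", "SBP3", "MED0", "MED3", "SMK0", "SMK3"}
        # observed slots untouched
        assert out["SBP1"] == 125.0 and out["SBP2"] == 139.0

    def test_nothing_missing_is_identity(self, worked_donor_row):
        out, filled = transfer_values(worked_donor_row, worked_donor_row)
        assert filled == [] and out.equals(worked_donor_row)

    def test_donor_missing_slot_is_hard_error(self, worked_noncompleter_row):
        bad_donor = worked_noncompleter_row.copy()
        with pytest.raises(ValueError, match="completer invariant"):
            transfer_values(worked_noncompleter_row, bad_donor)


class TestImputeCohort:
    def test_complete_table_is_identity(self, small_complete_pheno):
        res = HotDeckImputer(small_complete_pheno).fit()
        pd.testing.assert_frame_equal(res.completed.df, small_complete_pheno.df)
        assert len(res.audit) == 0

    def test_output_complete_and_observed_preserved(self):
        cohort = simulate_cohort(
            CohortConfig(n_individuals=200, n_snps=0, dropout_mode="mar_age", seed=33)
        )
        obs = cohort.phenotypes_observed
        res = HotDeckImputer(obs).fit()
        for var in EXAM_VARS:
            assert res.completed.presence(var).all()
            m = obs.presence(var)
            assert np.array_equal(res.completed.values(var)[m], obs.values(var)[m])

    def test_donor_consistency_from_audit(self):
        cohort = simulate_cohort(
            CohortConfig(n_individuals=150, n_snps=0, dropout_mode="mcar", seed=34)
        )
        res = HotDeckImputer(cohort.phenotypes_observed).fit()
        comp = res.completed.df.set_index("ID")
        for _, row in res.audit.iterrows():
            if not row["imputed_slots"]:
                continue
            donor = comp.loc[row["donor_id"]]
            target = comp.loc[row["noncompleter_id"]]
            for slot in row["imputed_slots"].split(";"):
                assert target[slot] == donor[slot]

    def test_beats_mean_imputation_and_preserves_exam_means(self):
        cohort = simulate_cohort(
            CohortConfig(n_individuals=400, n_snps=0, dropout_mode="mar_age", seed=35)
        )
        obs, truth = cohort.phenotypes_observed, cohort.phenotypes_complete
        res = HotDeckImputer(obs).fit()
        baseline = mean_impute_sbp(obs)
        mask = ~obs.presence("SBP")

        def rmse(t):
            d = (t.values("SBP") - truth.values("SBP"))[mask]
            return np.sqrt(np.mean(d**2))

        assert rmse(res.completed) <= rmse(baseline)
        true_sbp = truth.values("SBP")
        for i in range(4):
            shift = abs(res.completed.values("SBP")[:, i].mean() - true_sbp[:, i].mean())
            assert shift < 0.15 * true_sbp[:, i].std()

    def test_determinism(self):
        cohort = simulate_cohort(
            CohortConfig(n_individuals=120, n_snps=0, dropout_mode="mcar", seed=36)
        )
        a = HotDeckImputer(cohort.phenotypes_observed).fit()
        b = HotDeckImputer(cohort.phenotypes_observed).fit()
        pd.testing.assert_frame_equal(a.completed.df, b.completed.df)
        pd.testing.assert_frame_equal(a.audit, b.audit)

    def test_same_sex_donor_restriction(self):
        cohort = simulate_cohort(
            CohortConfig(n_individuals=200, n_snps=0, dropout_mode="mcar", seed=37)
        )
        obs = cohort.phenotypes_observed
        res = HotDeckImputer(obs, same_sex_donors=True).fit()
        sex = obs.df.set_index("ID")["SEX"]
        for _, row in res.audit.iterrows():
            assert sex[row["noncompleter_id"]] == sex[row["donor_id"]]
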