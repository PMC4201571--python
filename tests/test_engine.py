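"""Scoring, homeometric collapsing, permutation p-values, histograms."""

import numpy as np
import pandas as pd
import pytest

from pepperm.config import RunConfig
from pepperm.decoys import CandidateSet, build_combined_database
from pepperm.engine import (
    MatchRecord,
    collapse_homeometric,
    find_target_record,
    permutation_pvalue,
    run_experiment,
    score_spectrum,
    significance_histogram,
    spectrum_pvalues,
    t_level,
)
from pepperm.indicators import MatchIndicators
from pepperm.mass_model import Peptide, peptide_neutral_mass
from pepperm.spectra import generate_synthetic_database, simulate_ideal_spectrum

from oracles import brute_force_clusters, brute_force_mass_filter, brute_force_pvalue


def make_record(mass, source="decoy", seq="ACDEFGHK", sid="s", **scores):
    vals = dict(
        n_matched=0, convolution=0.0, hyperscore=0.0, sp=0.0, xcorr=0.0,
        delta_cn=1.0, lam=1.0, poisson_p=1.0, e_value=1.0,
    )
    vals.update(scores)
    p = Peptide(seq, source=source, peptide_id=f"{source}_{mass:.3f}_{id(scores)}")
    return MatchRecord(sid, p, mass, MatchIndicators(**vals))


def random_records(rng, n=30):
    """Records with deliberately coarse score sets so ties occur."""
    recs = []
    for i in range(n):
        nm = int(rng.integers(0, 3))
        recs.append(
            make_record(
                float(rng.uniform(500, 506)),
                source="decoy" if i else "target",
                n_matched=nm,
                convolution=float(rng.choice([0.0, 10.0, 20.0])),
                hyperscore=float(rng.choice([0.0, 10.0, 40.0])),
                sp=float(rng.choice([0.0, 5.0])),
                xcorr=float(rng.choice([0.0, 0.01, 0.02])),
                delta_cn=float(rng.choice([0.0, 0.5])),
                lam=1.0,
                poisson_p=float(rng.choice([0.1, 0.5, 1.0])),
                e_value=float(rng.choice([1.0, 5.0])),
            )
        )
    return recs


class TestScoreSpectrum:
    def _setup(self, rng, k=20):
        db = generate_synthetic_database(12, rng, length_dist=8)
        cs = CandidateSet(list(db.entries), 12.0, db.neutral_masses())
        combined = build_combined_database(cs, db, k=k, seed=2)
        return db, combined

    def test_self_match_is_maximal(self, rng, config):
        db, combined = self._setup(rng)
        p = db.entries[0]
        spec = simulate_ideal_spectrum(p)
        records = score_spectrum(spec, combined, config)
        target = find_target_record(records, p.sequence)
        assert target is not None
        best = max(r.indicators.n_matched for r in records)
        assert target.indicators.n_matched == best == spec.n_peaks

    def test_scored_set_equals_brute_force_mass_filter(self, rng, config):
        db, combined = self._setup(rng)
        spec = simulate_ideal_spectrum(db.entries[3])
        records = score_spectrum(spec, combined, config)
        all_masses = list(combined.decoy_masses()) + [
            peptide_neutral_mass(p) for p in db
        ]
        expect = brute_force_mass_filter(all_masses, spec.neutral_mass(), 1.5)
        assert len(records) == len(expect)
        for r in records:
            assert abs(r.neutral_mass - spec.neutral_mass()) <= 1.5

    def test_precursor_boundary_closed(self, config):
        target = Peptide("ACDEFGHK", peptide_id="t")
        from pepperm.spectra import ExperimentalSpectrum
        from pepperm.mass_model import PROTON

        m = peptide_neutral_mass(target)
        spec = ExperimentalSpectrum("s", m + 1.5 + PROTON, 1, [100.0, 200.0], [1.0, 1.0])
        records = score_spectrum(spec, [target], config)
        assert len(records) == 1

    def test_no_candidates_warns_and_returns_empty(self, config):
        from pepperm.spectra import ExperimentalSpectrum

        spec = ExperimentalSpectrum("s", 5000.0, 1, [100.0, 200.0], [1.0, 1.0])
        with pytest.warns(UserWarning, match="no candidates"):
            records = score_spectrum(spec, [Peptide("AG", peptide_id="t")], config)
        assert records == []

    def test_modification_variants_expand_search(self, config):
        # precursor set at the amidated mass: only the amidated variant fits
        # a tight tolerance
        from pepperm.spectra import ExperimentalSpectrum
        from pepperm.mass_model import PROTON, STANDARD_MODS

        target = Peptide("ACDEFGHK", peptide_id="t")
        m = peptide_neutral_mass(target) - 0.984016
        spec = ExperimentalSpectrum("s", m + PROTON, 1, [100.0, 200.0], [1.0, 1.0])
        cfg = config.replace(mods=("amidation",), prec_tol_da=0.1)
        records = score_spectrum(spec, [target], cfg)
        assert len(records) == 1
        assert records[0].peptide.mods[0][1].name == "amidation"


class TestCollapse:
    def test_identical_tuples_near_masses_merge(self):
        a = make_record(500.0, n_matched=2)
        b = make_record(500.9, n_matched=2)
        clusters = collapse_homeometric([a, b])
        assert len(clusters) == 1

    def test_identical_tuples_far_masses_stay_apart(self):
        a = make_record(500.0, n_matched=2)
        b = make_record(502.0, n_matched=2)
        assert len(collapse_homeometric([a, b])) == 2

    def test_single_linkage_chains_through_intermediate(self):
        recs = [make_record(m, n_matched=2) for m in (500.0, 501.2, 502.4)]
        assert len(collapse_homeometric(recs)) == 1

    def test_target_represents_its_cluster(self):
        d = make_record(500.0, n_matched=2)
        t = make_record(500.5, source="target", n_matched=2)
        (cluster,) = collapse_homeometric([d, t])
        assert cluster.representative.peptide.source == "target"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_partition(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_records(rng, 30)
        ours = collapse_homeometric(recs)
        ours_parts = sorted(
            sorted(recs.index(m) for m in c.members) for c in ours
        )
        assert ours_parts == brute_force_clusters(recs)


class TestPermutationPvalue:
    def test_target_best_among_999(self):
        target = make_record(500.0, source="target", n_matched=50)
        decoys = [
            make_record(500.0 + 0.001 * i, n_matched=int(i % 7)) for i in range(999)
        ]
        # distinct hyperscores keep every decoy in its own cluster
        decoys = [
            MatchRecord(r.spectrum_id, r.peptide, r.neutral_mass,
                        MatchIndicators(*(r.indicators.as_tuple()[:2]
                                          + (float(i),) + r.indicators.as_tuple()[3:])))
            for i, r in enumerate(decoys)
        ]
        clusters = collapse_homeometric(decoys + [target])
        assert len(clusters) == 1000
        res = permutation_pvalue(clusters, target, "n_matched")
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.n_equal_or_better == 1

    def test_worked_example_two_of_nine(self):
        # 10 decoys: 3 homeometric-better collapsing to 1, 7 worse
        target = make_record(500.0, source="target", n_matched=5)
        better = [make_record(600.0 + 0.1 * i, n_matched=9) for i in range(3)]
        worse = [make_record(400.0 + 3.0 * i, n_matched=int(i % 3)) for i in range(7)]
        records = better + worse + [target]
        clusters = collapse_homeometric(records)
        res = permutation_pvalue(clusters, target, "n_matched")
        assert res.n_candidates_collapsed == 9
        assert res.n_equal_or_better == 2
        assert res.p_value == pytest.approx(2 / 9)

    @pytest.mark.parametrize("indicator", ["n_matched", "hyperscore", "e_value", "xcorr"])
    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_naive_recount(self, indicator, seed):
        rng = np.random.default_rng(seed)
        recs = random_records(rng, 40)
        target = recs[0]
        clusters = collapse_homeometric(recs)
        res = permutation_pvalue(clusters, target, indicator)
        expect_p, expect_n = brute_force_pvalue(recs, target, indicator)
        assert res.n_candidates_collapsed == expect_n
        assert res.p_value == pytest.approx(expect_p)

    def test_missing_delta_cn_flagged_not_one(self):
        target = make_record(500.0, source="target", delta_cn=float("nan"))
        decoys = [make_record(500.0, n_matched=i + 1) for i in range(3)]
        clusters = collapse_homeometric(decoys + [target])
        res = permutation_pvalue(clusters, target, "delta_cn")
        assert res.missing and np.isnan(res.p_value)

    def test_no_pvalue_is_zero(self, rng):
        for seed in range(3):
            recs = random_records(np.random.default_rng(seed), 25)
            clusters = collapse_homeometric(recs)
            for name in ("n_matched", "hyperscore", "e_value"):
                res = permutation_pvalue(clusters, recs[0], name)
                assert res.p_value > 0


class TestTLevelAndHistogram:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, 0), (0.1, 0), (0.099, 1), (1e-3, 2), (9.9e-4, 3), (1e-7, 6)],
    )
    def test_t_level_convention(self, p, expected):
        # t is the largest threshold passed: significant at p < 1e-t
        assert t_level(p) == expected

    def test_histogram_conserves_and_accumulates(self):
        df = pd.DataFrame(
            {
                "k": [100] * 4,
                "indicator": ["n_matched"] * 4,
                "p_value": [0.5, 5e-3, 1e-3, 2e-5],
                "t_level": [t_level(p) for p in [0.5, 5e-3, 1e-3, 2e-5]],
            }
        )
        hist = significance_histogram(df, "n_matched")
        row = hist.iloc[0]
        assert row["total"] == 4
        assert row[["t0", "t1", "t2", "t3", "t4", "t5", "t6plus"]].sum() == 4
        assert row["t2"] == 2  # 5e-3 and the exact 1e-3 boundary
        assert row["t4"] == 1
        assert row["cum_1e-2"] == 3
        assert row["cum_1e-4"] == 1


class TestRunExperiment:
    def _inputs(self, seed=5, n=16, length=9):
        rng = np.random.default_rng(seed)
        db = generate_synthetic_database(n, rng, length_dist=length)
        truths = db.entries[:3]
        spectra = [simulate_ideal_spectrum(p) for p in truths]
        truth = {s.spectrum_id: p.sequence for s, p in zip(spectra, truths)}
        cs = CandidateSet(list(db.entries), 12.0, db.neutral_masses())
        return db, spectra, truth, cs

    def test_ideal_spectra_all_significant(self):
        db, spectra, truth, cs = self._inputs()
        df = run_experiment(
            spectra, db, [300], seed=5, truth=truth, candidate_set=cs,
            indicators=("n_matched", "hyperscore"),
        )
        assert len(df) == len(spectra) * 2
        # ideal self-matches are strictly best: p is exactly one over the
        # collapsed candidate count
        assert (df["n_equal_or_better"] == 1).all()
        assert (df["p_value"] > 0).all()
        assert (df["p_value"] == 1.0 / df["n_candidates_collapsed"]).all()

    def test_granularity_bound_at_k_one(self):
        db, spectra, truth, cs = self._inputs()
        df = run_experiment(
            spectra, db, [1], seed=5, truth=truth, candidate_set=cs,
            indicators=("n_matched",),
        )
        for _, row in df.iterrows():
            assert row["p_value"] >= 1.0 / (row["n_candidates_collapsed"])
            assert row["n_candidates_collapsed"] <= len(db) + len(db)

    def test_same_seed_identical_output_bytes(self):
        db, spectra, truth, cs = self._inputs()
        kw = dict(truth=truth, candidate_set=cs, indicators=("n_matched", "e_value"))
        a = run_experiment(spectra, db, [50], seed=9, **kw).to_csv(sep="\t")
        b = run_experiment(spectra, db, [50], seed=9, **kw).to_csv(sep="\t")
        assert a == b

    def test_spectrum_pvalues_missing_indicator_flagged(self, rng, config):
        db = generate_synthetic_database(6, rng, length_dist=8)
        spec = simulate_ideal_spectrum(db.entries[0])
        records = score_spectrum(spec, db, config)
        target = find_target_record(records, db.entries[0].sequence)
        results = spectrum_pvalues(records, target, config)
        assert {r.indicator for r in results} == {
            "n_matched", "convolution", "hyperscore", "sp", "xcorr",
            "delta_cn", "lambda", "poisson_p", "e_value",
        }
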