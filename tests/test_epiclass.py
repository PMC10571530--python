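import itertools

import numpy as np
import pandas as pd
import pytest

from methmark import epiclass as ec
from methmark import simulate as sim
from methmark.io import MethylRead


def summary(sample_id, densities, region="R"):
    return ec.SampleRegionSummary(sample_id, region, np.array(densities))


def brute_force_search(cases, controls, objective):
    """Double-loop enumeration over every achievable (MD, EF) pair."""
    all_d = sorted({0.0} | {d for s in cases + controls for d in s.densities})
    best_key = None
    for md in all_d:
        efs = sorted(
            {0.0}
            | {ec.epiallele_fraction(s, md) for s in cases + controls}
        )
        for ef in efs:
            thr = ec.EpiclassThresholds(md, ef, objective, "R")
            sens = np.mean([ec.classify_sample(s, thr) for s in cases])
            spec = np.mean([not ec.classify_sample(s, thr) for s in controls])
            if objective == "max_specificity_then_sensitivity":
                key = (round(spec, 12), round(sens, 12))
            elif objective == "max_sensitivity_then_specificity":
                key = (round(sens, 12), round(spec, 12))
            else:
                key = (round(sens + spec, 12),)
            if best_key is None or key > best_key:
                best_key = key
    return best_key


class TestDensityAndFraction:
    def test_density_counting(self):
        read = MethylRead("r", "R", (1, 2, 3, 4), (1, 1, 0, 1))
        assert ec.methylation_density(read) == 0.75
        assert ec.methylation_density(MethylRead("r", "R", (1,), (0,))) == 0.0
        assert ec.methylation_density(MethylRead("r", "R", (1, 2), (1, 1))) == 1.0

    def test_region_clipping_counts_only_in_region_cpgs(self, regions, tmp_path):
        """A read spanning the window edge keeps only in-window CpGs."""
        from methmark import io as mio

        g = regions.get("GALR1")
        path = tmp_path / "reads.tsv"
        path.write_text(
            "sample_id\tlabel\tregion\tread_id\tcpg_positions\tcalls\n"
            f"s\tcase\tGALR1\tr\t{g.start + 1},{g.end + 9},{g.start + 2}\t110\n"
        )
        (rs,) = mio.read_reads(path, regions)
        (read,) = rs.reads["GALR1"]
        assert ec.methylation_density(read) == 0.5  # 1 of 2 in-region CpGs

    def test_epiallele_fraction_inclusive(self):
        s = summary("x", [1.0, 0.8, 0.5, 0.2, 0.0])
        assert ec.epiallele_fraction(s, 0.5) == 0.6  # "at or above"
        assert ec.epiallele_fraction(s, 0.0) == 1.0
        assert ec.epiallele_fraction(s, 1.0) == 0.2
        assert ec.epiallele_fraction(summary("y", [0.9]), 1.0) == 0.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ec.epiallele_fraction(summary("x", []), 0.5)

    def test_fraction_monotone_in_md(self):
        rng = np.random.default_rng(0)
        s = summary("x", rng.random(50))
        mds = np.linspace(0, 1, 21)
        efs = [ec.epiallele_fraction(s, m) for m in mds]
        assert all(a >= b for a, b in zip(efs, efs[1:]))


class TestClassifySample:
    def test_boundary_inclusion(self):
        s = summary("x", [0.9, 0.9, 0.1, 0.1])
        assert ec.classify_sample(s, ec.EpiclassThresholds(0.5, 0.5, "max_youden", "R"))

    def test_zero_ef_always_positive(self):
        s = summary("x", [0.0])
        assert ec.classify_sample(s, ec.EpiclassThresholds(1.0, 0.0, "max_youden", "R"))

    def test_fully_methylated_requirement(self):
        s = summary("x", [1.0, 0.99])
        thr = ec.EpiclassThresholds(1.0, 1.0, "max_youden", "R")
        assert not ec.classify_sample(s, thr)

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(1)
        s = summary("x", rng.random(30))
        grid = np.linspace(0, 1, 6)
        for md1, md2 in itertools.combinations(grid, 2):
            for ef1, ef2 in itertools.combinations(grid, 2):
                t_loose = ec.EpiclassThresholds(md1, ef1, "max_youden", "R")
                t_tight = ec.EpiclassThresholds(md2, ef2, "max_youden", "R")
                if ec.classify_sample(s, t_tight):
                    assert ec.classify_sample(s, t_loose)


class TestTrainThresholds:
    def test_separable_cohorts_reach_perfection(self):
        cases = [summary(f"c{i}", [0.9, 0.95, 1.0]) for i in range(4)]
        controls = [summary(f"h{i}", [0.0, 0.05, 0.1]) for i in range(4)]
        for objective in ec.OBJECTIVES:
            thr, surface = ec.train_thresholds(cases, controls, "R", objective)
            sens = np.mean([ec.classify_sample(s, thr) for s in cases])
            spec = np.mean([not ec.classify_sample(s, thr) for s in controls])
            assert sens == 1.0 and spec == 1.0
            assert {"md_min", "ef_min", "sensitivity", "specificity"} <= set(surface)

    @pytest.mark.parametrize("objective", ec.OBJECTIVES)
    @pytest.mark.parametrize("trial", range(12))
    def test_matches_brute_force_on_random_instances(self, objective, trial):
        """Exhaustive oracle equivalence on small random instances."""
        rng = np.random.default_rng(1000 + trial)
        n_cpg = int(rng.integers(2, 6))
        cases = [
            summary(f"c{i}", rng.integers(0, n_cpg + 1, rng.integers(3, 20)) / n_cpg)
            for i in range(rng.integers(2, 10))
        ]
        controls = [
            summary(f"h{i}", rng.integers(0, n_cpg + 1, rng.integers(3, 20)) / n_cpg)
            for i in range(rng.integers(2, 10))
        ]
        thr, _ = ec.train_thresholds(cases, controls, "R", objective)
        sens = np.mean([ec.classify_sample(s, thr) for s in cases])
        spec = np.mean([not ec.classify_sample(s, thr) for s in controls])
        if objective == "max_specificity_then_sensitivity":
            key = (round(spec, 12), round(sens, 12))
        elif objective == "max_sensitivity_then_specificity":
            key = (round(sens, 12), round(spec, 12))
        else:
            key = (round(sens + spec, 12),)
        assert key == brute_force_search(cases, controls, objective)

    def test_specificity_first_objective_uses_sensitivity_for_ties(self):
        # no pair reaches specificity 1: control c2 dominates every case read
        cases = [summary("c1", [0.6, 0.6]), summary("c2", [0.5, 0.5])]
        controls = [summary("h1", [0.1, 0.1]), summary("h2", [1.0, 1.0])]
        thr, surface = ec.train_thresholds(
            cases, controls, "R", "max_specificity_then_sensitivity"
        )
        sens = np.mean([ec.classify_sample(s, thr) for s in cases])
        spec = np.mean([not ec.classify_sample(s, thr) for s in controls])
        best_spec = surface.specificity.max()
        at_best = surface[surface.specificity == best_spec]
        assert spec == best_spec
        assert sens == at_best.sensitivity.max()

    def test_tie_break_prefers_lowest_md_then_highest_ef(self):
        cases = [summary("c", [1.0, 1.0])]
        controls = [summary("h", [0.0, 0.0])]
        thr, surface = ec.train_thresholds(cases, controls, "R", "max_youden")
        perfect = surface[(surface.sensitivity == 1.0) & (surface.specificity == 1.0)]
        assert thr.md_min == perfect.md_min.min()
        at_md = perfect[perfect.md_min == thr.md_min]
        assert thr.ef_min == at_md.ef_min.max()

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            ec.train_thresholds([], [summary("h", [0.1])], "R")


class TestSplitCv:
    def test_determinism_and_summary(self, plasma_readsets):
        cases = [r for r in plasma_readsets if r.label == "case"]
        controls = [r for r in plasma_readsets if r.label == "control"]
        a = ec.evaluate_split_cv(cases, controls, ["ZNF154", "TLX1"], n_iter=3, seed=5)
        b = ec.evaluate_split_cv(cases, controls, ["ZNF154", "TLX1"], n_iter=3, seed=5)
        pd.testing.assert_frame_equal(a, b)
        summ = ec.summarize_cv(a)
        assert len(summ) == 4  # 2 markers + any-one + any-two

    def test_signal_cohort_separates_held_out(self, plasma_readsets):
        cases = [r for r in plasma_readsets if r.label == "case"]
        controls = [r for r in plasma_readsets if r.label == "control"]
        df = ec.evaluate_split_cv(
            cases, controls, ["ZNF154"], n_iter=5, objective="max_youden", seed=2
        )
        sub = df[df.assay == "ZNF154"]
        assert sub.ef_auc.mean() > 0.9

    def test_any_two_nests_in_any_one(self, plasma_readsets):
        cases = [r for r in plasma_readsets if r.label == "case"]
        controls = [r for r in plasma_readsets if r.label == "control"]
        df = ec.evaluate_split_cv(
            cases, controls, ["ZNF154", "TLX1", "GALR1"], n_iter=3,
            objective="max_youden", seed=7,
        )
        for it in df.iteration.unique():
            rows = df[df.iteration == it].set_index("assay")
            any1 = rows.loc["any-one:ZNF154+TLX1+GALR1"]
            any2 = rows.loc["any-two:ZNF154+TLX1+GALR1"]
            assert any2.sensitivity <= any1.sensitivity + 1e-12
            assert any2.specificity >= any1.specificity - 1e-12

    def test_null_rho_sensitivity_tracks_one_minus_specificity(self, regions):
        gaps = []
        for seed in range(6):
            cfg = sim.ReadSimConfig(
                n_case=12, n_control=12, reads_per_sample=60, cpgs_per_region=10,
                tumor_read_fraction=0.0, seed=seed,
            )
            readsets = sim.gen_plasma_readsets(cfg, regions)
            cases = [r for r in readsets if r.label == "case"]
            controls = [r for r in readsets if r.label == "control"]
            df = ec.evaluate_split_cv(
                cases, controls, ["ZNF154"], n_iter=2, objective="max_youden", seed=seed
            )
            sub = df[df.assay == "ZNF154"]
            gaps.append(sub.sensitivity.mean() - (1 - sub.specificity.mean()))
        assert abs(np.mean(gaps)) < 0.3

    def test_too_few_samples_error(self, plasma_readsets):
        with pytest.raises(ValueError):
            ec.evaluate_split_cv(plasma_readsets[:1], plasma_readsets[10:], ["ZNF154"])


class TestTrainOnly:
    def test_separable_cohort_flagged_training_only(self, plasma_readsets):
        cases = [r for r in plasma_readsets if r.label == "case"]
        controls = [r for r in plasma_readsets if r.label == "control"]
        perf, trained = ec.train_only_evaluation(
            cases, controls, ["ZNF154", "TLX1", "GALR1"], "max_specificity_then_sensitivity"
        )
        assert perf.training_only.all()
        assert set(trained) == {"ZNF154", "TLX1", "GALR1"}
        # max-specificity objective: training specificity is maximal (here 1.0)
        singles = perf[perf.assay.isin(["ZNF154", "TLX1", "GALR1"])]
        assert (singles.specificity == 1.0).all()

    def test_any_one_sensitivity_at_least_each_member(self, plasma_readsets):
        cases = [r for r in plasma_readsets if r.label == "case"]
        controls = [r for r in plasma_readsets if r.label == "control"]
        perf, _ = ec.train_only_evaluation(
            cases, controls, ["ZNF154", "TLX1", "GALR1"], "max_youden"
        )
        perf = perf.set_index("assay")
        any1 = perf.loc["any-one:ZNF154+TLX1+GALR1"].sensitivity
        for marker in ("ZNF154", "TLX1", "GALR1"):
            assert any1 >= perf.loc[marker].sensitivity - 1e-12

    def test_flag_survives_serialization(self, plasma_readsets, tmp_path):
        cases = [r for r in plasma_readsets if r.label == "case"]
        controls = [r for r in plasma_readsets if r.label == "control"]
        perf, _ = ec.train_only_evaluation(cases, controls, ["ZNF154"])
        path = tmp_path / "perf.tsv"
        perf.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        assert back.training_only.all()
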