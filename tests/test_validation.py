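import numpy as np
import pytest

from gsalloc import (
    CVConfig,
    PhenotypeVector,
    SelectionSchedule,
    SimConfig,
    holdout_split,
    kfold_partition,
    results_frame,
    run_cv,
    run_external,
    run_grid,
    run_strategy_comparison,
    run_ts_size_sweep,
    simulate_panel,
    simulate_phenotype,
    simulate_population,
)
from gsalloc.markers import schedule_sizes
from gsalloc.rrblup import fit_rrblup
from gsalloc.validation import fixed_partition_evaluator


class TestPartitions:
    def test_fold_sizes_137_by_10(self):
        folds = kfold_partition(137, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [13] * 3 + [14] * 7
        all_idx = np.concatenate(folds)
        assert len(np.unique(all_idx)) == 137

    def test_singleton_folds(self):
        folds = kfold_partition(10, 10, seed=1)
        assert all(len(f) == 1 for f in folds)

    def test_seeds_give_different_partitions(self):
        parts = [tuple(map(tuple, kfold_partition(30, 3, seed=s))) for s in range(5)]
        assert len(set(parts)) > 1

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            kfold_partition(5, 10)

    @pytest.mark.parametrize(
        "n,k,expect",
        [(227, 3, (151, 76)), (1107, 5, (886, 221)), (100, 4, (75, 25))],
    )
    def test_holdout_split_sizes(self, n, k, expect):
        assert holdout_split(n, k) == expect


class TestRunCV:
    def test_null_trait_gives_near_zero_r(self):
        cfg = SimConfig(
            archetype="GERMPLASM", n_genotypes=300, n_markers=100, n_qtl=10,
            h2=0.0, seed=23,
        )
        G = simulate_panel(cfg)
        y, _ = simulate_phenotype(G, cfg)
        r_mean, r_min, r_max, rs = run_cv(G, y, None, CVConfig(k=10, n_repetitions=20, seed=1))
        assert abs(r_mean) < 0.1
        assert len(rs) == 200
        assert r_min <= r_mean <= r_max

    def test_noise_free_oligogenic_recovery(self):
        cfg = SimConfig(
            archetype="GERMPLASM", n_genotypes=300, n_markers=50, n_qtl=5,
            h2=1.0, seed=29,
        )
        G = simulate_panel(cfg)
        y, _ = simulate_phenotype(G, cfg)
        r_mean, *_ = run_cv(G, y, None, CVConfig(k=10, n_repetitions=2, seed=2))
        assert r_mean > 0.9

    def test_determinism(self, germplasm_pop, fast_cv):
        G, y, _ = germplasm_pop
        a = run_cv(G, y, None, fast_cv)
        b = run_cv(G, y, None, fast_cv)
        assert a[0] == b[0] and a[3] == b[3]

    def test_small_population_reduces_folds(self, germplasm_pop):
        G, y, _ = germplasm_pop
        ids = y.genotype_ids[:12]
        y12 = y.subset(ids)
        with pytest.warns(UserWarning, match="reducing folds"):
            r_mean, *_ = run_cv(G.subset_genotypes(ids), y12, None,
                                CVConfig(k=10, n_repetitions=1, seed=0))
        assert -1.0 <= r_mean <= 1.0


class TestRunExternal:
    def test_overlap_rejected(self, germplasm_pop):
        G, y, _ = germplasm_pop
        with pytest.raises(ValueError, match="overlap"):
            run_external(G, y, G, y)

    def test_cloned_validation_matches_training_r(self):
        from gsalloc import GenotypeMatrix, prediction_ability, predict_gebv

        cfg = SimConfig(
            archetype="GERMPLASM", n_genotypes=100, n_markers=80, n_qtl=8,
            h2=1.0, seed=37,
        )
        G = simulate_panel(cfg)
        y, _ = simulate_phenotype(G, cfg)
        # external set = exact genetic clones of 20 training genotypes
        clone_ids = G.genotype_ids[:20]
        Gc = G.subset_genotypes(clone_ids)
        G_val = GenotypeMatrix(
            [f"clone_{g}" for g in clone_ids], list(G.marker_ids), Gc.dosage.copy(),
        )
        y_val = PhenotypeVector([f"clone_{g}" for g in clone_ids],
                                y.subset(clone_ids).values)
        r_ev = run_external(G, y, G_val, y_val)
        fit = fit_rrblup(G, y)
        r_train = prediction_ability(
            y.subset(clone_ids).values, predict_gebv(fit, Gc)
        )
        assert r_ev == pytest.approx(r_train, abs=1e-10)

    def test_degenerate_training_raises(self, germplasm_pop):
        G, y, _ = germplasm_pop
        flat = PhenotypeVector(y.genotype_ids[:100], np.zeros(100))
        G_val = G.subset_genotypes(y.genotype_ids[100:130])
        y_val = y.subset(y.genotype_ids[100:130])
        with pytest.raises(ValueError, match="variance"):
            run_external(G, flat, G_val, y_val)


@pytest.fixture(scope="module")
def split_pop():
    """Training population of 120 plus 30 external genotypes."""
    cfg = SimConfig(
        archetype="GERMPLASM", n_genotypes=150, n_markers=120, n_qtl=12,
        h2=0.7, seed=41,
    )
    G, y, _ = simulate_population(cfg)
    ids = np.array(G.genotype_ids)
    return (
        G.subset_genotypes(list(ids[:120])), y.subset(list(ids[:120])),
        G.subset_genotypes(list(ids[120:])), y.subset(list(ids[120:])),
    )


class TestStrategyComparison:
    def test_structure_and_cell_reproducibility(self, split_pop, fast_cv):
        G, y, G_val, y_val = split_pop
        sched = SelectionSchedule([30, 12])
        res = run_strategy_comparison(
            G, y, G_val, y_val, ("NRE_MB", "NRE_R"), sched, fast_cv,
            n_random_reps=5, seed=3,
        )
        frame = results_frame(res)
        assert (frame.strategy == "ALL").sum() == 1
        nre_r = frame[frame.strategy == "NRE_R"]
        assert set(nre_r.subset_size) == {30, 12}
        assert (nre_r.r_cv_min <= nre_r.r_cv_mean).all()
        assert (nre_r.r_cv_mean <= nre_r.r_cv_max).all()
        assert frame.r_cv_mean.between(-1, 1).all()
        # any single NRE_MB cell reproduces from its components exactly
        from gsalloc.markers import select_nre_mb

        subs = select_nre_mb(fit_rrblup(G, y), sched)
        expect, *_ = run_cv(G, y, subs[0].marker_ids, fast_cv)
        cell = frame[(frame.strategy == "NRE_MB") & (frame.subset_size == 30)]
        assert cell.r_cv_mean.iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_min_strictly_below_max_for_replicated_random(self, split_pop, fast_cv):
        G, y, G_val, y_val = split_pop
        res = run_strategy_comparison(
            G, y, G_val, y_val, ("NRE_R",), SelectionSchedule([20]), fast_cv,
            n_random_reps=4, seed=5,
        )
        row = results_frame(res).query("strategy == 'NRE_R'").iloc[0]
        assert row.r_cv_min < row.r_cv_max


class TestTsSweep:
    def test_fraction_one_coincides_with_baseline(self, split_pop, fast_cv):
        G, y, G_val, y_val = split_pop
        res = run_ts_size_sweep(
            G, y, G_val, y_val, fractions=(1.0,), methods=("AN", "RANDOM"),
            n_random_reps=2, cfg=fast_cv, seed=7,
        )
        base, *_ = run_cv(G, y, None, fast_cv)
        frame = results_frame(res)
        assert np.allclose(frame.r_cv_mean, base, atol=1e-12)

    def test_core_sizes_match_contract(self, split_pop, fast_cv):
        from gsalloc import core_size

        G, y, G_val, y_val = split_pop
        res = run_ts_size_sweep(
            G, y, G_val, y_val, fractions=(0.5, 0.2), methods=("EN", "AN"),
            cfg=fast_cv, n_restarts=2, seed=9,
        )
        for r in res:
            assert r.n_models >= 1
            # the CV within a core of c genotypes ran on exactly that core
            c = core_size(r.ts_fraction, len(y))
            assert c >= 6

    def test_random_training_ability_rises_with_size(self):
        # random-sampling mean r_cv at 75% >= at 5%, mirroring rising
        # training-size curves (averaged over seeds)
        lo, hi = [], []
        for seed in range(6):
            cfg = SimConfig(
                archetype="MULTIFAM", n_genotypes=120, n_markers=150, n_qtl=15,
                h2=0.6, seed=60 + seed,
            )
            G, y, _ = simulate_population(cfg)
            res = run_ts_size_sweep(
                G, y, None, None, fractions=(0.75, 0.1), methods=("RANDOM",),
                n_random_reps=3, cfg=CVConfig(k=3, n_repetitions=1, seed=seed),
                seed=seed,
            )
            frame = results_frame(res)
            hi.append(frame[frame.ts_fraction == 0.75].r_cv_mean.iloc[0])
            lo.append(frame[frame.ts_fraction == 0.1].r_cv_mean.iloc[0])
        assert np.mean(hi) > np.mean(lo)


class TestGrid:
    def test_grid_dimensions_and_baseline_cell(self, split_pop, fast_cv):
        G, y, G_val, y_val = split_pop
        sched = SelectionSchedule([30, 12])
        res = run_grid(
            G, y, G_val, y_val, sched, fractions=(0.5,), cfg=fast_cv,
            re_mob_reps=3, n_restarts=2, seed=13,
        )
        frame = results_frame(res)
        assert len(frame) == (len(sched) + 1) * 2  # (sizes + all) x (0.5, 1.0)
        base, *_ = run_cv(G, y, None, fast_cv)
        cell = frame[(frame.strategy == "ALL") & (frame.ts_fraction == 1.0)]
        assert cell.r_cv_mean.iloc[0] == pytest.approx(base, abs=1e-12)

    def test_determinism(self, split_pop, fast_cv):
        G, y, G_val, y_val = split_pop
        sched = SelectionSchedule([20])
        a = results_frame(run_grid(G, y, G_val, y_val, sched, fractions=(0.5,),
                                   cfg=fast_cv, re_mob_reps=2, n_restarts=1, seed=3))
        b = results_frame(run_grid(G, y, G_val, y_val, sched, fractions=(0.5,),
                                   cfg=fast_cv, re_mob_reps=2, n_restarts=1, seed=3))
        assert a.equals(b)


class TestHeritabilityTrend:
    def test_cv_ability_rises_with_h2(self):
        from scipy.stats import spearmanr

        h2s = (0.1, 0.3, 0.5, 0.8)
        means = []
        for h2 in h2s:
            vals = []
            for seed in range(6):
                cfg = SimConfig(
                    archetype="GERMPLASM", n_genotypes=120, n_markers=150,
                    n_qtl=15, h2=h2, seed=80 + seed,
                )
                G, y, _ = simulate_population(cfg)
                r_mean, *_ = run_cv(G, y, None, CVConfig(k=3, n_repetitions=1, seed=seed))
                vals.append(r_mean)
            means.append(np.mean(vals))
        rho, _ = spearmanr(h2s, means)
        assert rho > 0


def test_fixed_partition_evaluator_is_stable(germplasm_pop):
    G, y, _ = germplasm_pop
    ev = fixed_partition_evaluator(G, y, CVConfig(k=5, n_repetitions=1, seed=2))
    ids = G.marker_ids[:40]
    assert ev(ids) == ev(list(ids))
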