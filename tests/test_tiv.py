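import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tivscan.noise import NoiseModel, fit_noise
from tivscan.signal_qc import presence_mask
from tivscan.synthetic import SimulationSpec, simulate_arrays
from tivscan.pipeline import run_pipeline
from tivscan.tiv import (
    TIVEvent,
    call_de_genes,
    call_tiv,
    deviation_stats,
    fold_changes,
    gene_fc,
    switch_like_filter,
)

from test_signal_qc import make_matrix, make_sheet

FLAT = NoiseModel(np.array([5.0]), np.array([0.2]))


def _ann(ps_to_gene):
    return pd.DataFrame(
        {
            "ps_id": list(ps_to_gene),
            "gene_id": list(ps_to_gene.values()),
            "chrom": "chr1",
            "start": 0,
            "end": 25,
            "strand": "+",
            "tier": "full",
            "label": "putative_exon",
        }
    )


class TestFoldChanges:
    def test_unit_shift(self):
        sheet = make_sheet(times=(0, 60), reps=3)
        vals = np.array([[5.0, 5.0, 5.0, 6.0, 6.0, 6.0]])
        m = make_matrix(vals, np.full((1, 6), 0.01), sheet)
        fc = fold_changes(m, sheet, presence_mask(m, sheet), FLAT)
        assert fc.fc.loc["PS0", 60] == pytest.approx(1.0)

    def test_t0_column_identically_zero(self):
        rng = np.random.default_rng(0)
        sheet = make_sheet(times=(0, 20, 60), reps=3)
        vals = rng.normal(7, 1, size=(50, 9))
        m = make_matrix(vals, np.full((50, 9), 0.01), sheet)
        fc = fold_changes(m, sheet, presence_mask(m, sheet), FLAT)
        assert (fc.fc[0] == 0).all()

    def test_matches_brute_mean_difference(self):
        rng = np.random.default_rng(1)
        sheet = make_sheet(times=(0, 20, 60), reps=3)
        vals = rng.normal(7, 1, size=(100, 9))
        m = make_matrix(vals, np.full((100, 9), 0.01), sheet)
        fc = fold_changes(m, sheet, presence_mask(m, sheet), FLAT)
        for i in range(100):
            base = vals[i, :3].mean()
            for j, t in enumerate((0, 20, 60)):
                expected = vals[i, 3 * j : 3 * j + 3].mean() - base
                assert fc.fc.iloc[i][t] == pytest.approx(expected)

    def test_absent_at_t0_masks_row(self, caplog):
        sheet = make_sheet(times=(0, 60), reps=3)
        vals = np.full((1, 6), 7.0)
        detp = np.array([[0.9, 0.9, 0.9, 0.01, 0.01, 0.01]])
        m = make_matrix(vals, detp, sheet)
        with caplog.at_level("INFO"):
            fc = fold_changes(m, sheet, presence_mask(m, sheet), FLAT)
        assert fc.fc.loc["PS0"].isna().all()
        assert "fully masked" in caplog.text


class TestGeneFC:
    def _fc_table(self, fcs, genes):
        sheet = make_sheet(times=(0, 60), reps=3)
        vals = np.zeros((len(fcs), 6))
        vals[:, 3:] = np.asarray(fcs)[:, None]
        m = make_matrix(vals + 7.0, np.full((len(fcs), 6), 0.01), sheet)
        return fold_changes(m, sheet, presence_mask(m, sheet), FLAT), _ann(genes)

    def test_median_examples(self):
        fc_table, ann = self._fc_table([0.5, 0.5, 2.0], {f"PS{i}": "g" for i in range(3)})
        g = gene_fc(fc_table, ann, ann["ps_id"])
        assert g.fc.loc["g", 60] == pytest.approx(0.5)

    def test_even_count_median_convention(self):
        fc_table, ann = self._fc_table(
            [0.0, 1.0, 0.0, 1.0], {f"PS{i}": "g" for i in range(4)}
        )
        g = gene_fc(fc_table, ann, ann["ps_id"])
        assert g.fc.loc["g", 60] == pytest.approx(0.5)

    def test_fewer_than_three_ps_masked(self):
        fc_table, ann = self._fc_table([0.5, 0.7], {"PS0": "g", "PS1": "g"})
        g = gene_fc(fc_table, ann, ann["ps_id"])
        assert np.isnan(g.fc.loc["g", 60])

    def test_matches_sort_based_median(self):
        rng = np.random.default_rng(5)
        n_genes, ps_per = 200, 5
        genes = {f"PS{i}": f"g{i // ps_per}" for i in range(n_genes * ps_per)}
        fcs = rng.normal(size=n_genes * ps_per)
        fc_table, ann = self._fc_table(fcs, genes)
        g = gene_fc(fc_table, ann, ann["ps_id"])
        for k in range(n_genes):
            vals = sorted(fcs[k * ps_per : (k + 1) * ps_per])
            mid = len(vals) // 2
            expected = vals[mid] if len(vals) % 2 else (vals[mid - 1] + vals[mid]) / 2
            assert g.fc.loc[f"g{k}", 60] == pytest.approx(expected)


class TestCallDE:
    def test_strong_injection_called_up(self):
        spec = SimulationSpec(seed=0, n_genes=100, de_fraction=0.2, de_log2fc=1.0)
        models, ps, matrix, sheet, truth = simulate_arrays(spec)
        res = run_pipeline(models, ps, matrix, sheet, classify=False)
        de_truth = truth.genes[truth.genes["de"]]
        up_truth = set(de_truth.index[de_truth["de_sign"] > 0])
        called_up = {
            c.gene_id
            for c in res.de_calls
            if "up" in c.directions.values()
        }
        assert up_truth and up_truth <= called_up

    def test_fc_min_rule_blocks_small_fc(self):
        # linear FC 1.3 with tiny sigma: significant but below threshold
        sheet = make_sheet(times=(0, 60), reps=3)
        n = 300
        rng = np.random.default_rng(1)
        genes = {f"PS{i}": f"g{i // 6}" for i in range(n)}
        vals = np.full((n, 6), 7.0)
        vals[:, 3:] += np.log2(1.3)
        vals += rng.normal(0, 0.01, size=vals.shape)
        m = make_matrix(vals, np.full((n, 6), 0.001), sheet)
        noise = fit_noise(m, sheet, n_bins=5)
        fc_table = fold_changes(m, sheet, presence_mask(m, sheet), noise)
        g = gene_fc(fc_table, _ann(genes), list(genes))
        calls, table = call_de_genes(g, fc_min=1.5, alpha=0.05)
        assert (table["q"] < 0.05).any()  # significance is there
        assert calls == []  # but the FC cut-off dominates

    def test_null_false_call_rate(self):
        rates = []
        for seed in range(3):
            spec = SimulationSpec(seed=seed, n_genes=500)
            models, ps, matrix, sheet, _ = simulate_arrays(spec)
            res = run_pipeline(models, ps, matrix, sheet, classify=False)
            rates.append(len(res.de_genes) / 500)
        assert np.mean(rates) <= 0.075


class TestDeviationStats:
    def _setup(self, ps_fcs, genes):
        sheet = make_sheet(times=(0, 60, 120), reps=3)
        vals = np.full((len(ps_fcs), 9), 7.0)
        vals[:, 3:6] += np.asarray(ps_fcs)[:, None]
        vals[:, 6:] += np.asarray(ps_fcs)[:, None]
        m = make_matrix(vals, np.full((len(ps_fcs), 9), 0.01), sheet)
        fc_table = fold_changes(m, sheet, presence_mask(m, sheet), FLAT)
        ann = _ann(genes)
        return fc_table, gene_fc(fc_table, ann, ann["ps_id"])

    def test_zero_deviation_p_is_one(self):
        fc_table, g = self._setup([1.0] * 4, {f"PS{i}": "g" for i in range(4)})
        dev = deviation_stats(fc_table, g)
        assert dev.delta.loc["PS0", 60] == pytest.approx(0.0)
        assert dev.p.loc["PS0", 60] == pytest.approx(1.0)

    def test_z_and_p_from_normal_cdf(self):
        delta, sd = 1.0, 0.25
        z = delta / sd
        p = 2 * stats.norm.sf(abs(z))
        assert z == pytest.approx(4.0)
        assert p == pytest.approx(6.33e-5, rel=1e-2)

    def test_ps_permutation_invariance(self, small_sim):
        _spec, models, ps, matrix, sheet, _t = small_sim
        res = run_pipeline(models, ps, matrix, sheet, classify=False)
        dev = res.dev_stats
        perm = dev.delta.sample(frac=1.0, random_state=0).index
        assert np.allclose(
            dev.delta.loc[perm].to_numpy(),
            dev.delta.reindex(perm).to_numpy(),
            equal_nan=True,
        )


def _mk_dev(p_by_time, delta_by_time, times=(20, 40, 60, 120, 240, 480)):
    """Single-PS DeviationStats-like structure for call_tiv unit tests."""
    from tivscan.tiv import DeviationStats

    idx = ["PS0"]
    p = pd.DataFrame([p_by_time], index=idx, columns=list(times))
    delta = pd.DataFrame([delta_by_time], index=idx, columns=list(times))
    z = delta.copy()
    gene_of_ps = pd.Series({"PS0": "g"})
    return DeviationStats(delta=delta, z=z, p=p, gene_of_ps=gene_of_ps,
                          times=list(times))


class TestCallTIV:
    def test_two_adjacent_flags_one_event(self):
        dev = _mk_dev(
            [1, 1, 1e-9, 1e-9, 1, 1], [0, 0, 1.0, 1.0, 0, 0]
        )
        events, _ = call_tiv(dev, alpha=0.05, min_adjacent=2)
        assert len(events) == 1
        assert events[0].times == (60, 120)

    def test_non_adjacent_flags_no_event(self):
        dev = _mk_dev([1e-9, 1, 1, 1, 1e-9, 1], [1.0, 0, 0, 0, 1.0, 0])
        events, _ = call_tiv(dev, alpha=0.05, min_adjacent=2)
        assert events == []

    def test_last_time_point_alone_cannot_seed(self):
        dev = _mk_dev([1, 1, 1, 1, 1, 1e-9], [0, 0, 0, 0, 0, 1.0])
        events, _ = call_tiv(dev, alpha=0.05, min_adjacent=2)
        assert events == []

    def test_sign_flip_breaks_run(self):
        dev = _mk_dev([1e-9, 1e-9, 1, 1, 1, 1], [1.0, -1.0, 0, 0, 0, 0])
        events, _ = call_tiv(dev, alpha=0.05, min_adjacent=2)
        assert events == []

    def test_gene_order_invariance(self, small_sim):
        _spec, models, ps, matrix, sheet, _t = small_sim
        res = run_pipeline(models, ps, matrix, sheet, classify=False)
        dev = res.dev_stats
        from tivscan.tiv import DeviationStats

        perm = dev.delta.sample(frac=1.0, random_state=1).index
        dev2 = DeviationStats(
            delta=dev.delta.loc[perm],
            z=dev.z.loc[perm],
            p=dev.p.loc[perm],
            gene_of_ps=dev.gene_of_ps.loc[perm],
            times=dev.times,
        )
        ev1, _ = call_tiv(dev)
        ev2, _ = call_tiv(dev2)
        key = lambda e: (e.gene_id, e.sign, e.run_start, e.run_end, e.ps_ids)
        assert sorted(map(key, ev1)) == sorted(map(key, ev2))

    def test_translation_invariance(self):
        # shifting all PS of a gene at one time moves gene FC, not deltas
        sheet = make_sheet(times=(0, 60, 120), reps=3)
        rng = np.random.default_rng(3)
        n = 8
        genes = {f"PS{i}": "g" for i in range(n)}
        vals = np.full((n, 9), 7.0) + rng.normal(0, 0.2, size=(n, 9))
        m1 = make_matrix(vals, np.full((n, 9), 0.01), sheet)
        vals2 = vals.copy()
        vals2[:, 3:6] += 2.0  # every PS of the gene shifted at t = 60
        m2 = make_matrix(vals2, np.full((n, 9), 0.01), sheet)
        ann = _ann(genes)
        fc1 = fold_changes(m1, sheet, presence_mask(m1, sheet), FLAT)
        fc2 = fold_changes(m2, sheet, presence_mask(m2, sheet), FLAT)
        g1 = gene_fc(fc1, ann, ann["ps_id"])
        g2 = gene_fc(fc2, ann, ann["ps_id"])
        assert g2.fc.loc["g", 60] - g1.fc.loc["g", 60] == pytest.approx(2.0)
        d1 = deviation_stats(fc1, g1)
        d2 = deviation_stats(fc2, g2)
        assert np.allclose(d1.delta.to_numpy(), d2.delta.to_numpy())


class TestSwitchLikeFilter:
    def _event(self, run_len):
        return TIVEvent(
            gene_id="g",
            ps_ids=("p",),
            run_start=1,
            run_end=run_len,
            times=tuple(range(run_len)),
            sign=1,
            q_min=0.01,
            max_abs_delta=1.0,
            switch_like=run_len >= 3,
        )

    def test_run_length_two_excluded(self):
        assert switch_like_filter([self._event(2)]) == []

    def test_run_length_three_retained(self):
        events = [self._event(3)]
        assert switch_like_filter(events) == events

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(9)
        events = [self._event(int(k)) for k in rng.integers(1, 7, size=50)]
        got = switch_like_filter(events, min_adjacent=3)
        expected = [e for e in events if (e.run_end - e.run_start + 1) >= 3]
        assert got == expected
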