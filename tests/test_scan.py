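"""Counts I/O, Storey q-values, and the end-to-end locus scan."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from wfhmm import (
    Scenario,
    TimeSeries,
    default_nes_grid,
    qvalues,
    read_counts,
    scan,
    simulate_dataset,
    write_counts,
)

COARSE = default_nes_grid(121)


def _series(locus, counts, sizes=None, dates=(0, 1, 2, 3, 4, 5)):
    sizes = sizes if sizes is not None else [30] * len(dates)
    return TimeSeries(locus, list(dates), sizes, counts)


class TestCountsIO:
    def test_round_trip(self, tmp_path):
        per_line = {
            "A": [_series("l1", [3, 5, 8, 12, 20, 25]),
                  _series("l2", [15, 14, 16, 15, 15, 17])],
            "B": [_series("l3", [20, 12, 8, 4, 1, 0])],
        }
        path = tmp_path / "counts.tsv"
        write_counts(path, per_line)
        back = read_counts(path)
        assert set(back) == {"A", "B"}
        for line in per_line:
            for a, b in zip(per_line[line], back[line]):
                assert a.locus_id == b.locus_id
                np.testing.assert_array_equal(a.dates, b.dates)
                np.testing.assert_array_equal(a.sizes, b.sizes)
                np.testing.assert_array_equal(a.counts, b.counts)

    def test_six_generation_design_with_varying_sizes(self, tmp_path):
        # the per-date sizes of a real selection experiment (divergent
        # chicken lines genotyped every generation) must carry through
        sizes = [102, 28, 42, 56, 54, 60]
        counts = [51, 20, 30, 40, 40, 50]
        path = tmp_path / "c.tsv"
        write_counts(path, {"pHu+": [_series("snp1", counts, sizes)]})
        back = read_counts(path)["pHu+"][0]
        np.testing.assert_array_equal(back.sizes, sizes)
        np.testing.assert_array_equal(back.dates, [0, 1, 2, 3, 4, 5])

    def test_count_exceeding_size_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("locus\tn_0\ty_0\tn_5\ty_5\nl1\t30\t31\t30\t2\n")
        with pytest.raises(ValueError, match="rows: 2"):
            read_counts(path)


class TestQvalues:
    def test_all_ones(self):
        np.testing.assert_array_equal(qvalues(np.ones(10)), np.ones(10))

    def test_empty(self):
        assert qvalues([]).size == 0

    def test_matches_bh_with_pi0_one(self, rng):
        p = rng.uniform(size=500) ** 2
        q = qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=300)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_pi0_estimated_below_one_with_signal(self, rng):
        p = np.concatenate([rng.uniform(size=900), np.full(300, 1e-6)])
        q = qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(q <= bh + 1e-12)


def _simulated_line(Ne, s, reps, seed, T=45):
    sc = Scenario(Ne=Ne, s=s, x0=0.5, T=T, reps=reps, seed=seed)
    _, counts = simulate_dataset(sc, np.random.default_rng(seed))
    dates = sc.dates
    sizes = np.full(len(dates), 30)
    return [TimeSeries(f"s{seed}_{i}", dates, sizes, counts[i])
            for i in range(reps)]


class TestScan:
    def test_null_dataset_rarely_calls(self):
        series = _simulated_line(100, 0.0, 250, seed=50)
        df = scan({"A": series}, {"A": 100}, nes_grid=COARSE)
        assert df.significant.sum() <= 2  # FDR control under the global null

    def test_mixture_recovers_selected_loci(self):
        null = _simulated_line(100, 0.0, 120, seed=51)
        sel = _simulated_line(100, 0.4, 15, seed=52)
        df = scan({"A": null + sel}, {"A": 100}, nes_grid=COARSE)
        calls = df[df.significant]
        assert len(calls) >= 5
        truth = calls.locus_id.str.startswith("s52_")
        assert truth.mean() > 0.8  # calls are dominated by true positives

    def test_divergent_lines_give_opposite_signs(self):
        dates = list(range(0, 46, 5))
        up = np.round(np.linspace(0.3, 0.95, 10) * 30).astype(int)
        down = np.round(np.linspace(0.7, 0.05, 10) * 30).astype(int)
        per_line = {"plus": [_series("snp", up.tolist(), dates=dates)],
                    "minus": [_series("snp", down.tolist(), dates=dates)]}
        df = scan(per_line, {"plus": 157, "minus": 123}, nes_grid=COARSE)
        s = df.set_index("line").s_hat
        assert s["plus"] > 0 and s["minus"] < 0

    def test_exclusions_flagged(self):
        series = [_series("fix", [12, 0, 0, 0, 0, 0]),
                  _series("mono", [0, 0, 0, 0, 0, 0]),
                  _series("ok", [10, 12, 15, 14, 18, 20])]
        df = scan({"A": series}, {"A": 100}, nes_grid=COARSE)
        flags = df.set_index("locus_id").excluded
        assert flags["fix"] == "one_step_fixation"
        assert flags["mono"] == "monomorphic"
        assert flags["ok"] == ""
        assert df.set_index("locus_id").pvalue.notna().to_dict() == {
            "fix": False, "mono": False, "ok": True}

    def test_missing_ne_raises(self):
        with pytest.raises(ValueError, match="no Ne"):
            scan({"A": [_series("l", [1, 2, 3, 4, 5, 6])]}, {})

    def test_deterministic(self):
        series = _simulated_line(100, 0.1, 10, seed=53)
        a = scan({"A": series}, {"A": 100}, nes_grid=COARSE)
        b = scan({"A": series}, {"A": 100}, nes_grid=COARSE)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_wf_and_bws_call_the_same_loci(self):
        null = _simulated_line(120, 0.0, 50, seed=54)
        sel = _simulated_line(120, 0.4, 10, seed=57)
        per_line = {"A": null + sel}
        sig = {}
        for model in ("WF", "BwS"):
            df = scan(per_line, {"A": 120}, model=model, nes_grid=COARSE)
            sig[model] = set(df[df.significant].locus_id)
        assert sig["WF"] == sig["BwS"]
        assert len(sig["BwS"]) > 0
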