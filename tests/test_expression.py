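"""Per-probe Welch tests, cross-dataset convergence, multiplicity gates."""

import numpy as np
import pandas as pd
import pytest

from genoconverge.expression import (
    ConvergenceCall,
    ExpressionDataset,
    ProbeTestResult,
    adjust,
    converge,
    probe_tests,
)

from conftest import bh_oracle, welch_oracle


def make_dataset(values, n_case, dataset_id="ds1", probe_gene=None):
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    samples = [f"s{i}" for i in range(n_samples)]
    probes = [f"p{i}" for i in range(n_probes)]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * (n_samples - n_case), index=samples
    )
    if probe_gene is None:
        probe_gene = pd.Series({p: f"gene_{p}" for p in probes})
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=probes, columns=samples),
        groups=groups,
        probe_gene=probe_gene,
    )


class TestProbeTests:
    def test_identical_groups_give_null_result(self):
        ds = make_dataset([[1, 2, 3, 1, 2, 3]], n_case=3)
        (r,) = probe_tests(ds)
        assert r.p == pytest.approx(1.0) and r.direction == 0
        assert r.t == pytest.approx(0.0)

    def test_constant_equal_probe_is_degenerate_not_nan(self):
        ds = make_dataset([[5, 5, 5, 5, 5, 5]], n_case=3)
        (r,) = probe_tests(ds)
        assert r.t == 0.0 and r.p == 1.0 and r.direction == 0

    def test_matches_welch_formula_oracle(self, rng):
        values = rng.normal(size=(50, 17))
        ds = make_dataset(values, n_case=9)
        for i, r in enumerate(probe_tests(ds)):
            t, p = welch_oracle(values[i, :9], values[i, 9:])
            assert r.t == pytest.approx(t, abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-10)
            assert r.direction == np.sign(values[i, :9].mean() - values[i, 9:].mean())

    def test_label_swap_flips_direction_preserves_p(self, rng):
        values = rng.normal(size=(20, 12))
        ds = make_dataset(values, n_case=6)
        swapped = make_dataset(np.concatenate([values[:, 6:], values[:, :6]], axis=1),
                               n_case=6)
        for r1, r2 in zip(probe_tests(ds), probe_tests(swapped)):
            assert r1.p == pytest.approx(r2.p, rel=1e-12)
            assert r1.direction == -r2.direction

    def test_missing_value_names_probe(self, rng):
        values = rng.normal(size=(3, 8))
        values[1, 2] = np.nan
        ds = make_dataset(values, n_case=4)
        with pytest.raises(ValueError, match="p1"):
            probe_tests(ds)

    def test_too_few_samples_per_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            make_dataset(np.zeros((2, 4)), n_case=1)

    def test_null_rejection_rate_near_alpha(self, rng):
        values = rng.normal(size=(1000, 40))
        ds = make_dataset(values, n_case=20)
        rate = np.mean([r.p < 0.05 for r in probe_tests(ds)])
        # binomial 4-sigma band around 5% at n=1000
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 1000)


def _result(ds, gene, p, direction, probe="x"):
    return ProbeTestResult(ds, f"{gene}_{probe}", gene, 1.0, p, direction)


class TestConverge:
    def test_two_aligned_datasets_called(self):
        results = {
            "d1": [_result("d1", "G1", 0.01, +1)],
            "d2": [_result("d2", "G1", 0.02, +1)],
            "d3": [_result("d3", "G1", 0.50, -1)],
        }
        (call,) = converge(results, ["G1"])
        assert call.called and call.aligned
        assert call.n_datasets_significant == 2
        assert call.gene_p == 0.01

    def test_opposed_directions_not_called(self):
        results = {
            "d1": [_result("d1", "G1", 0.01, +1)],
            "d2": [_result("d2", "G1", 0.02, -1)],
        }
        (call,) = converge(results, ["G1"])
        assert not call.called and not call.aligned

    def test_single_dataset_significance_insufficient(self):
        results = {
            "d1": [_result("d1", "G1", 0.001, +1)],
            "d2": [_result("d2", "G1", 0.90, +1)],
        }
        (call,) = converge(results, ["G1"])
        assert not call.called and call.n_datasets_significant == 1

    def test_nonsignificant_probe_in_significant_dataset_breaks_alignment(self):
        # alignment covers ALL probes of the gene in significant datasets
        results = {
            "d1": [_result("d1", "G1", 0.01, +1, "a"),
                   _result("d1", "G1", 0.80, -1, "b")],
            "d2": [_result("d2", "G1", 0.02, +1, "a"),
                   _result("d2", "G1", 0.60, +1, "b")],
        }
        (call,) = converge(results, ["G1"])
        assert not call.aligned and not call.called

    def test_direction_zero_probes_are_neutral(self):
        results = {
            "d1": [_result("d1", "G1", 0.01, +1, "a"),
                   _result("d1", "G1", 1.00, 0, "b")],
            "d2": [_result("d2", "G1", 0.02, +1, "a"),
                   _result("d2", "G1", 1.00, 0, "b")],
        }
        (call,) = converge(results, ["G1"])
        assert call.aligned and call.called

    def test_gene_outside_reference_list_never_called(self):
        results = {
            "d1": [_result("d1", "G1", 0.01, +1)],
            "d2": [_result("d2", "G1", 0.02, +1)],
        }
        (call,) = converge(results, ["OTHER"])
        assert not call.called

    def test_empty_reference_rejected(self):
        results = {"d1": [], "d2": []}
        with pytest.raises(ValueError, match="reference"):
            converge(results, [])

    def test_matches_enumeration_oracle_on_toy(self, rng):
        """Random 3-dataset toy tables agree with direct rule enumeration."""
        for _ in range(50):
            results = {}
            per_gene = {}
            for d in ("d1", "d2", "d3"):
                rs = []
                for g in ("G1", "G2"):
                    for probe in ("a", "b"):
                        p = float(rng.random())
                        direction = int(rng.choice([-1, 1]))
                        rs.append(_result(d, g, p, direction, probe))
                        per_gene.setdefault(g, []).append((d, p, direction))
                results[d] = rs
            calls = {c.gene: c for c in converge(results, ["G1", "G2"])}
            for g, rows in per_gene.items():
                sig_ds = {d for d, p, _ in rows if p < 0.05}
                dirs = {s for d, _, s in rows if d in sig_ds}
                aligned = len(dirs - {0}) <= 1 and bool(sig_ds)
                expected = len(sig_ds) >= 2 and aligned
                assert calls[g].called == expected


class TestAdjust:
    def _call(self, gene, p, called=True):
        return ConvergenceCall(gene, 2, ("d1", "d2"), True, called, p)

    def test_single_gene_passes_both(self):
        (call,) = adjust([self._call("G1", 0.01)])
        assert call.fdr_pass and call.bonferroni_pass

    def test_uncalled_genes_keep_flags_false(self):
        calls = adjust([self._call("G1", 0.001), self._call("G2", 0.001, called=False)])
        assert calls[0].fdr_pass and not calls[1].fdr_pass

    def test_bh_matches_sort_and_scan_oracle(self, rng):
        pvals = rng.random(100) ** 2
        calls = [self._call(f"G{i}", float(p)) for i, p in enumerate(pvals)]
        flags = [c.fdr_pass for c in adjust(calls)]
        assert flags == list(bh_oracle(pvals, alpha=0.05))

    def test_bonferroni_subset_of_fdr(self, rng):
        for _ in range(20):
            pvals = rng.random(30)
            calls = adjust([self._call(f"G{i}", float(p)) for i, p in enumerate(pvals)])
            for c in calls:
                assert not c.bonferroni_pass or c.fdr_pass
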