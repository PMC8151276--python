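import numpy as np
import pandas as pd
import pytest

from gpcrtracer import concordance
from gpcrtracer.concordance import (
    overlap,
    table_from_counts,
    threshold_sweep,
)
from gpcrtracer.errors import SchemaError
from gpcrtracer.promiscuity import ProbabilityProfile


def _matrix(data, scaffolds=None, families=None):
    arr = np.asarray(data)
    scaffolds = scaffolds or [f"S{i}" for i in range(arr.shape[0])]
    families = families or [f"F{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=scaffolds, columns=families)


class TestOverlap:
    def test_identical_matrices(self, rng):
        m = _matrix(rng.integers(0, 2, size=(4, 5)))
        table = overlap(m, m)
        assert table.accuracy == 100.0
        assert table.fp == 0 and table.fn == 0

    def test_printed_counts_worked_example(self):
        table = table_from_counts(
            predicted_positive=82, confirmed_positive=56,
            predicted_negative=530, confirmed_negative=512,
        )
        assert (table.tp, table.fp, table.tn, table.fn) == (56, 26, 512, 18)
        assert table.accuracy == pytest.approx(92.8, abs=0.05)
        assert table.positive_confirmation_rate == pytest.approx(68.3, abs=0.05)

    def test_recount_oracle_random_matrices(self, rng):
        p = _matrix(rng.integers(0, 2, size=(5, 5)))
        c = _matrix(rng.integers(0, 2, size=(5, 5)))
        table = overlap(p, c)
        # brute-force cellwise recount
        tp = fp_ = fn = tn = 0
        for i in range(5):
            for j in range(5):
                pred, conf = p.iat[i, j], c.iat[i, j]
                if pred and conf:
                    tp += 1
                elif pred:
                    fp_ += 1
                elif conf:
                    fn += 1
                else:
                    tn += 1
        assert (table.tp, table.fp, table.fn, table.tn) == (tp, fp_, fn, tn)
        assert table.accuracy == pytest.approx(100 * (tp + tn) / 25)

    def test_conservation(self, rng):
        p = _matrix(rng.integers(0, 2, size=(6, 7)))
        c = _matrix(rng.integers(0, 2, size=(6, 7)))
        assert overlap(p, c).n_cells == 42

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(SchemaError):
            overlap(_matrix(np.zeros((2, 3))), _matrix(np.zeros((3, 2))))

    def test_label_mismatch_rejected(self):
        p = _matrix(np.zeros((2, 2)), families=["A", "B"])
        c = _matrix(np.zeros((2, 2)), families=["A", "C"])
        with pytest.raises(SchemaError):
            overlap(p, c)


class TestConsolidateScreen:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["scaffold", "construct", "fold_response"])

    def test_any_member_rule(self):
        results = self._results(
            [("S1", "R1", 1.0), ("S1", "R2", 2.0), ("S1", "R3", 1.1), ("S1", "R4", 0.9)]
        )
        fam_map = {f"R{i}": "FamA" for i in range(1, 5)}
        matrix = concordance.consolidate_screen(results, fam_map)
        assert matrix.at["S1", "FamA"] == 1

    def test_all_members_negative(self):
        results = self._results([("S1", "R1", 1.2), ("S1", "R2", 1.49)])
        matrix = concordance.consolidate_screen(results, {"R1": "FamA", "R2": "FamA"})
        assert matrix.at["S1", "FamA"] == 0

    def test_planted_truth_recovered(self, rng):
        # plant family-level truth, emit one >=1.5 fold per positive cell
        scaffolds = [f"S{i}" for i in range(4)]
        families = [f"Fam{j}" for j in range(3)]
        truth = _matrix(rng.integers(0, 2, size=(4, 3)), scaffolds, families)
        fam_map, rows = {}, []
        for j, fam in enumerate(families):
            fam_map[f"R{j}"] = fam
            for i, s in enumerate(scaffolds):
                fold = 2.0 if truth.at[s, fam] else 1.1
                rows.append((s, f"R{j}", fold))
        matrix = concordance.consolidate_screen(
            self._results(rows), fam_map, scaffolds=scaffolds, families=families
        )
        pd.testing.assert_frame_equal(matrix, truth)

    def test_unmapped_construct_warns_and_excludes(self):
        results = self._results([("S1", "R1", 2.0), ("S1", "RX", 2.0)])
        with pytest.warns(UserWarning, match="RX"):
            matrix = concordance.consolidate_screen(results, {"R1": "FamA"})
        assert list(matrix.columns) == ["FamA"]


class TestThresholdSweep:
    def _profiles(self, values, families):
        out = []
        for i, row in enumerate(values):
            row = np.asarray(row, dtype=float)
            row = row / row.sum() * 100.0
            probs = dict(zip(families, row))
            probs[families[-1]] += 100.0 - sum(probs.values())
            out.append(ProbabilityProfile(f"S{i}", probs))
        return out

    def test_zero_threshold_degenerate(self, rng):
        families = ["A", "B", "C"]
        profiles = self._profiles(rng.uniform(1, 10, size=(4, 3)), families)
        conf = _matrix(rng.integers(0, 2, size=(4, 3)), [p.compound_id for p in profiles], families)
        while conf.to_numpy().all() or not conf.to_numpy().any():
            conf = _matrix(rng.integers(0, 2, size=(4, 3)), [p.compound_id for p in profiles], families)
        results, _ = threshold_sweep(profiles, conf, [0.0])
        table = results[0.0]
        assert table.sensitivity == 100.0 and table.specificity == 0.0

    def test_above_max_threshold_all_negative(self, rng):
        families = ["A", "B"]
        profiles = self._profiles([[60, 40], [30, 70]], families)
        conf = _matrix([[1, 0], [0, 1]], ["S0", "S1"], families)
        results, _ = threshold_sweep(profiles, conf, [101.0])
        assert results[101.0].specificity == 100.0

    def test_planted_optimum_found(self):
        families = ["A", "B", "C", "D"]
        # probabilities above 10 mark the truly-confirmed cells exactly
        raw = [
            [70, 12, 11, 7],
            [60, 25, 8, 7],
            [55, 15, 22, 8],
        ]
        profiles = self._profiles(raw, families)
        conf_data = (np.asarray(raw, dtype=float) >= 10).astype(int)
        conf = _matrix(conf_data, [p.compound_id for p in profiles], families)
        _, best = threshold_sweep(profiles, conf, [2.0, 10.0, 30.0])
        assert best == 10.0

    def test_monotonicity_over_random_matrices(self, rng):
        families = [f"F{j}" for j in range(6)]
        profiles = self._profiles(rng.uniform(0.5, 10, size=(8, 6)), families)
        conf = _matrix(
            rng.integers(0, 2, size=(8, 6)),
            [p.compound_id for p in profiles], families,
        )
        thresholds = [0.0, 2.0, 5.0, 10.0, 30.0, 101.0]
        results, _ = threshold_sweep(profiles, conf, thresholds)
        sens = [results[t].sensitivity for t in thresholds]
        spec = [results[t].specificity for t in thresholds]
        assert all(a >= b - 1e-9 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(spec, spec[1:]))
        for t in thresholds:
            assert results[t].n_cells == 48

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([], pd.DataFrame(), [])


class TestOverrides:
    def test_curated_override_applied(self):
        conf = _matrix(np.zeros((2, 2), dtype=int), ["S0", "S1"], ["A", "B"])
        overrides = pd.DataFrame(
            [{"scaffold": "S0", "family": "B", "confirmed": 1}]
        )
        out = concordance.apply_overrides(conf, overrides)
        assert out.at["S0", "B"] == 1 and conf.at["S0", "B"] == 0

    def test_override_outside_matrix_rejected(self):
        conf = _matrix(np.zeros((1, 1), dtype=int), ["S0"], ["A"])
        overrides = pd.DataFrame([{"scaffold": "SX", "family": "A", "confirmed": 1}])
        with pytest.raises(SchemaError):
            concordance.apply_overrides(conf, overrides)
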