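"""QC filters against brute-force oracles; pattern classification rules."""

import numpy as np
import pandas as pd
import pytest

from chondrostage.datatypes import DYNAMIC_PATTERNS, PatternClass, TrajectoryMatrix
from chondrostage.synthetic_data import (
    PATTERN_TEMPLATES,
    TEMPLATE_AMPLITUDE,
    TEMPLATE_BASELINE,
    simulate_trajectory_matrix,
)
from chondrostage.trajectory_patterns import (
    QcConfig,
    apply_qc,
    classify_all,
    classify_pattern,
    filter_cells_min_genes,
    filter_genes_min_cells,
    qualify_cells_total_counts,
    rank_dynamic_genes,
)


def count_matrix(rng, n_genes=50, n_cells=30, zero_fraction=0.5):
    counts = rng.poisson(5.0, size=(n_genes, n_cells)).astype(float)
    counts[rng.random(counts.shape) < zero_fraction] = 0.0
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    cells = pd.Index([f"c{j}" for j in range(n_cells)])
    return TrajectoryMatrix(
        expression=pd.DataFrame(counts, index=genes, columns=cells),
        pseudotime=pd.Series(rng.uniform(0, 1, n_cells), index=cells),
    )


# --- brute-force oracles (straight loops, independent of the implementation)


def brute_filter_cells(m, min_genes):
    keep = [
        c for c in m.expression.columns
        if sum(1 for v in m.expression[c] if v > 0) >= min_genes
    ]
    return m.expression.loc[:, keep]


def brute_filter_genes(m, min_cells):
    keep = [
        g for g in m.expression.index
        if sum(1 for v in m.expression.loc[g] if v > 0) >= min_cells
    ]
    return m.expression.loc[keep]


def brute_qualify_totals(m, k):
    totals = [m.expression[c].sum() for c in m.expression.columns]
    mean = sum(totals) / len(totals)
    sd = (sum((x - mean) ** 2 for x in totals) / (len(totals) - 1)) ** 0.5
    keep = [
        c for c, tot in zip(m.expression.columns, totals)
        if mean - k * sd <= tot <= mean + k * sd
    ]
    return m.expression.loc[:, keep]


class TestQcFilters:
    def test_min_genes_boundary_inclusive(self):
        """A cell expressing exactly the threshold is kept; one fewer is not."""
        cfg = QcConfig(min_genes_per_cell=3)
        expr = pd.DataFrame(
            {"keep": [1.0, 1, 1, 0], "drop": [1.0, 1, 0, 0]},
            index=[f"g{i}" for i in range(4)],
        )
        m = TrajectoryMatrix(expr, pd.Series([0.1, 0.9], index=expr.columns))
        out = filter_cells_min_genes(m, cfg)
        assert list(out.expression.columns) == ["keep"]

    def test_min_cells_boundary_inclusive(self):
        cfg = QcConfig(min_cells_per_gene=2)
        expr = pd.DataFrame(
            [[1.0, 1, 0], [1.0, 0, 0], [0.0, 0, 0]],
            index=["keep", "drop", "zero"], columns=["a", "b", "c"],
        )
        m = TrajectoryMatrix(expr, pd.Series([0.1, 0.5, 0.9],
                                             index=expr.columns))
        out = filter_genes_min_cells(m, cfg)
        assert list(out.expression.index) == ["keep"]

    def test_total_count_outlier_removed(self):
        rng = np.random.default_rng(8)
        totals_base = rng.normal(1000, 100, 100)
        expr = pd.DataFrame(
            np.r_[totals_base, 10_000.0][None, :],
            index=["g0"], columns=[f"c{j}" for j in range(101)],
        )
        m = TrajectoryMatrix(expr, pd.Series(np.linspace(0, 1, 101),
                                             index=expr.columns))
        out = qualify_cells_total_counts(m, QcConfig())
        assert "c100" not in out.expression.columns
        assert out.n_cells == 100

    def test_all_equal_totals_all_retained(self):
        expr = pd.DataFrame(np.ones((3, 5)), index=list("abc"),
                            columns=[f"c{j}" for j in range(5)])
        m = TrajectoryMatrix(expr, pd.Series(np.linspace(0, 1, 5),
                                             index=expr.columns))
        out = qualify_cells_total_counts(m, QcConfig())
        assert out.n_cells == 5

    def test_single_cell_kept_with_warning(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["c"])
        m = TrajectoryMatrix(expr, pd.Series([0.0], index=["c"]))
        with pytest.warns(UserWarning, match="single cell"):
            out = qualify_cells_total_counts(m, QcConfig())
        assert out.n_cells == 1

    def test_emptying_filters_raise(self):
        expr = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["g1", "g2"],
                            columns=["a", "b"])
        m = TrajectoryMatrix(expr, pd.Series([0.1, 0.9], index=expr.columns))
        with pytest.raises(ValueError, match="cells"):
            filter_cells_min_genes(m, QcConfig(min_genes_per_cell=5))
        with pytest.raises(ValueError, match="genes"):
            filter_genes_min_cells(m, QcConfig(min_cells_per_gene=5))

    @pytest.mark.parametrize("seed", range(20))
    def test_filters_match_brute_force(self, seed):
        """Each QC filter equals an independent loop-based recount."""
        rng = np.random.default_rng(seed)
        m = count_matrix(rng)
        cfg = QcConfig(min_genes_per_cell=10, min_cells_per_gene=12)
        pd.testing.assert_frame_equal(
            filter_cells_min_genes(m, cfg).expression,
            brute_filter_cells(m, 10),
        )
        pd.testing.assert_frame_equal(
            filter_genes_min_cells(m, cfg).expression,
            brute_filter_genes(m, 12),
        )
        pd.testing.assert_frame_equal(
            qualify_cells_total_counts(m, cfg).expression,
            brute_qualify_totals(m, 2.0),
        )

    def test_filter_order_regression(self):
        """Cells -> genes -> totals is the fixed order; the frozen expected
        output differs from what genes-first would give."""
        expr = pd.DataFrame(
            [[1.0, 0, 0], [1.0, 1, 0], [0.0, 1, 1]],
            index=["g1", "g2", "g3"], columns=["c1", "c2", "c3"],
        )
        m = TrajectoryMatrix(expr, pd.Series([0.1, 0.5, 0.9],
                                             index=expr.columns))
        cfg = QcConfig(min_genes_per_cell=2, min_cells_per_gene=2,
                       total_count_sd=10)
        out = apply_qc(m, cfg)
        assert list(out.expression.index) == ["g2"]
        assert list(out.expression.columns) == ["c1", "c2"]
        # genes-first would instead keep {g2, g3} x {c2}
        genes_first = brute_filter_cells(
            TrajectoryMatrix(brute_filter_genes(m, 2),
                             m.pseudotime), 2
        )
        assert list(genes_first.index) != list(out.expression.index)


class TestRankDynamicGenes:
    @staticmethod
    def _matrix(genes: dict):
        cells = pd.Index([f"c{j}" for j in range(60)])
        t = np.linspace(0, 1, 60)
        expr = pd.DataFrame(
            {c: {g: f(t[j]) for g, f in genes.items()}
             for j, c in enumerate(cells)}
        )
        return TrajectoryMatrix(expr, pd.Series(t, index=cells))

    def test_constant_gene_not_selected_linear_gene_selected(self):
        m = self._matrix({
            "flat": lambda t: 3.0,
            "linear": lambda t: 1.0 + 5.0 * t,
        })
        ranked = rank_dynamic_genes(m, QcConfig())
        assert "linear" in ranked.index
        assert ranked.loc["linear", "q_value"] < 0.01
        assert "flat" not in ranked.index

    def test_too_few_pseudotime_values(self):
        expr = pd.DataFrame(np.ones((2, 12)),
                            columns=[f"c{j}" for j in range(12)])
        m = TrajectoryMatrix(
            expr, pd.Series([0.0] * 6 + [1.0] * 6, index=expr.columns)
        )
        with pytest.raises(ValueError, match="distinct pseudotime"):
            rank_dynamic_genes(m, QcConfig())

    def test_simulation_selection_precision(self):
        """>= 90% of selected genes are true dynamic genes."""
        m = simulate_trajectory_matrix(10, 950, 300, noise_sd=0.2, seed=5)
        ranked = rank_dynamic_genes(m, QcConfig())
        truth = m.labels.loc[ranked.index]
        assert len(ranked) > 0
        assert (truth != PatternClass.FLAT).mean() >= 0.90


class TestClassifyPattern:
    t = np.linspace(0, 1, 300)

    @pytest.mark.parametrize("cls", DYNAMIC_PATTERNS + (PatternClass.FLAT,))
    def test_canonical_templates_recovered(self, cls):
        v = TEMPLATE_BASELINE + TEMPLATE_AMPLITUDE * PATTERN_TEMPLATES[cls](self.t)
        assert classify_pattern(v, self.t) is cls

    def test_step_down_early_is_immediate(self):
        v = np.where(self.t < 0.15, 2.5, 0.5)
        assert classify_pattern(v, self.t) is PatternClass.IMMEDIATE_DOWN

    def test_linear_decreasing_is_gradual(self):
        assert classify_pattern(2.5 - 2 * self.t, self.t) is \
            PatternClass.GRADUAL_DOWN

    def test_late_step_up_is_delayed(self):
        v = np.where(self.t >= 0.85, 2.5, 0.5)
        assert classify_pattern(v, self.t) is PatternClass.DELAYED_UP

    def test_full_sine_is_tide_wave(self):
        v = 0.5 + 2 * (0.5 + 0.5 * np.sin(2 * np.pi * self.t))
        assert classify_pattern(v, self.t) is PatternClass.TIDE_WAVE

    @pytest.mark.parametrize("gain,offset", [(2.0, 0.0), (0.5, 1.0), (10.0, 5.0)])
    def test_positive_affine_invariance(self, gain, offset):
        """Scaling/shifting expression does not change the assigned class."""
        for cls in DYNAMIC_PATTERNS:
            v = TEMPLATE_BASELINE + TEMPLATE_AMPLITUDE * PATTERN_TEMPLATES[cls](
                self.t
            )
            assert classify_pattern(gain * v + offset, self.t) is cls

    def test_fewer_cells_than_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            classify_pattern(np.ones(5), np.linspace(0, 1, 5), QcConfig())


class TestClassifyAll:
    def test_five_templates_one_each(self):
        m = simulate_trajectory_matrix(1, 0, 300, noise_sd=0.0, seed=3)
        table = classify_all(m)
        assert sorted(table["pattern"]) == sorted(c.value for c in
                                                  DYNAMIC_PATTERNS)

    def test_all_flat_matrix(self):
        m = simulate_trajectory_matrix(0, 8, 50, noise_sd=0.0, seed=3)
        table = classify_all(m)
        assert (table["pattern"] == "FLAT").all()
        assert table.attrs["class_counts"] == {"FLAT": 8}

    def test_noisy_recovery(self):
        """>= 85% of dynamic-gene labels recovered at noise sd 0.2."""
        m = simulate_trajectory_matrix(10, 0, 300, noise_sd=0.2, seed=11)
        table = classify_all(m)
        truth = m.labels.map(lambda c: c.value)
        assert (table["pattern"] == truth).mean() >= 0.85
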