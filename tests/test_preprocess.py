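import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import tmtde

from conftest import make_design, make_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_filter(values, design, min_zeros_per_group, min_groups):
    """Enumerate groups and count unquantified cells per protein, cell by cell."""
    removed = []
    for pid in values.index:
        n_groups_hit = 0
        for g in design.groups:
            n_zero = 0
            for s in design.samples_in(g):
                v = values.loc[pid, s]
                if pd.isna(v) or v == 0:
                    n_zero += 1
            if n_zero >= min_zeros_per_group:
                n_groups_hit += 1
        if n_groups_hit >= min_groups:
            removed.append(pid)
    return set(removed)


def binned_median_trend(arr, n_bins=10):
    """Max |M(A)| trend over sample pairs via a quadratic through binned
    medians -- a smoother independent of both lowess and the package's
    trimmed-polyfit statistic."""
    n = arr.shape[1]
    worst = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
            if shared.sum() < 50:
                continue
            m = arr[shared, i] - arr[shared, j]
            a = (arr[shared, i] + arr[shared, j]) / 2.0
            edges = np.quantile(a, np.linspace(0, 1, n_bins + 1))
            idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, n_bins - 1)
            cx, cy = [], []
            for b in range(n_bins):
                sel = idx == b
                if sel.sum() >= 20:
                    cx.append(np.median(a[sel]))
                    cy.append(np.median(m[sel]))
            if len(cx) < 4:
                continue
            coef = np.polyfit(cx, cy, 2)
            grid = np.linspace(min(cx), max(cx), 50)
            worst = max(worst, float(np.max(np.abs(np.polyval(coef, grid)))))
    return worst


# ---------------------------------------------------------------------------
# replicate-zero filter
# ---------------------------------------------------------------------------

class TestFilterLowObservation:
    design = make_design(["g1", "g2", "g3", "g4"], 4)

    @staticmethod
    def _one_protein_table(zero_counts):
        row = []
        for n_zero in zero_counts:
            row += [0.0] * n_zero + [10.0] * (4 - n_zero)
        return make_table([row], samples=TestFilterLowObservation.design.samples)

    @pytest.mark.parametrize(
        "zero_counts,removed",
        [
            ((3, 3, 0, 0), True),   # two groups reach 3 unquantified
            ((3, 2, 2, 2), False),  # only one group reaches 3
            ((4, 0, 0, 0), False),  # only one group affected at all
            ((4, 4, 4, 4), True),
            ((2, 2, 2, 2), False),
        ],
    )
    def test_rule_on_known_zero_patterns(self, zero_counts, removed):
        q = self._one_protein_table(zero_counts)
        kept, report = tmtde.filter_low_observation(q, self.design)
        assert (kept.n_proteins == 0) == removed
        assert report.n_removed == int(removed)

    def test_missing_counts_like_zero(self):
        q = self._one_protein_table((0, 0, 0, 0))
        q.values.iloc[0, [0, 1, 2, 4, 5, 6]] = np.nan  # 3 in g1, 3 in g2
        kept, _ = tmtde.filter_low_observation(q, self.design)
        assert kept.n_proteins == 0

    def test_small_group_warns_not_errors(self):
        d = make_design(["a", "b"], 2)
        q = make_table([[1.0, 2.0, 3.0, 4.0]], samples=d.samples)
        kept, report = tmtde.filter_low_observation(q, d, min_zeros_per_group=3)
        assert kept.n_proteins == 1
        assert len(report.warnings) == 2

    def test_agrees_with_brute_force_on_random_matrices(self):
        """500 random matrices/designs against cell-by-cell enumeration."""
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n_groups = rng.integers(2, 5)
            reps = rng.integers(2, 6)
            n_prot = rng.integers(1, 30)
            d = make_design([f"g{i}" for i in range(n_groups)], int(reps))
            vals = rng.exponential(10, size=(n_prot, n_groups * reps))
            vals[rng.random(vals.shape) < 0.35] = 0.0
            vals[rng.random(vals.shape) < 0.1] = np.nan
            q = make_table(vals, samples=d.samples)
            mz = int(rng.integers(1, reps + 2))
            mg = int(rng.integers(1, n_groups + 1))
            kept, report = tmtde.filter_low_observation(
                q, d, min_zeros_per_group=mz, min_groups=mg)
            expected = brute_force_filter(q.values, d, mz, mg)
            assert set(report.removed_ids) == expected
            assert kept.n_proteins == n_prot - len(expected)
            assert report.n_input - report.n_removed == kept.n_proteins


# ---------------------------------------------------------------------------
# scale transforms
# ---------------------------------------------------------------------------

class TestScaleTransforms:
    def test_log2_values_zeros_and_all_zero_rows(self):
        q = make_table([[8.0, 0.0], [0.0, 0.0]])
        logt = tmtde.to_log2(q)
        assert logt.scale == "log2"
        assert logt.values.iloc[0, 0] == 3.0
        assert np.isnan(logt.values.iloc[0, 1])
        assert logt.values.iloc[1].isna().all()  # retained, all-missing
        assert logt.n_proteins == 2

    def test_back_to_linear_inverts(self):
        rng = np.random.default_rng(0)
        vals = rng.exponential(100, size=(50, 4))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        q = make_table(np.nan_to_num(vals, nan=0.0))
        back = tmtde.back_to_linear(tmtde.to_log2(q))
        observed = vals > 0
        np.testing.assert_allclose(
            back.values.to_numpy()[observed], vals[observed], rtol=0, atol=1e-10)
        # zeros became missing and stay missing
        assert np.isnan(back.values.to_numpy()[~observed]).all()

    def test_wrong_scale_rejected(self):
        q = make_table([[1.0]])
        with pytest.raises(ValueError):
            tmtde.back_to_linear(q)
        with pytest.raises(ValueError):
            tmtde.to_log2(tmtde.to_log2(q))


# ---------------------------------------------------------------------------
# cyclic LOESS
# ---------------------------------------------------------------------------

def biased_log2_table(seed=3, n=400, n_samples=6, amplitude=0.5):
    rng = np.random.default_rng(seed)
    base = rng.normal(20, 2, n)
    z = (base - 20) / 2
    vals = base[:, None] + rng.normal(0, 0.25, (n, n_samples))
    for s in range(n_samples):
        coef = rng.uniform(-1, 1, 3)
        curve = coef[0] + coef[1] * z + coef[2] * z**2
        vals[:, s] += curve * (amplitude / max(np.max(np.abs(curve)), 1e-9))
    return make_table(vals, scale="log2")


class TestCyclicLoess:
    def test_identical_samples_are_left_alone(self):
        rng = np.random.default_rng(1)
        col = rng.normal(20, 2, 200)
        q = make_table(np.tile(col[:, None], 4), scale="log2")
        out, _ = tmtde.cyclic_loess_normalize(q)
        np.testing.assert_allclose(
            out.values.to_numpy(), q.values.to_numpy(), atol=1e-8)

    def test_constant_offset_matches_median_centering(self):
        """Pure shift, no trend: result should agree with a median-centering
        oracle and leave |median(M)| < 0.05."""
        rng = np.random.default_rng(7)
        col = rng.normal(20, 2, 300)
        q = make_table(np.column_stack([col, col + 1.0]), scale="log2")
        out, _ = tmtde.cyclic_loess_normalize(q)
        m = out.values.iloc[:, 0] - out.values.iloc[:, 1]
        assert abs(np.median(m)) < 0.05
        oracle = tmtde.median_center(q)
        diff = np.abs(out.values.to_numpy() - oracle.values.to_numpy())
        assert np.median(diff) < 0.05

    def test_injected_bias_removed(self, default_pipeline_result):
        """>= 80% reduction of the intensity-dependent trend on default
        simulated data, measured by an independent binned-median smoother."""
        pre = binned_median_trend(default_pipeline_result["log2_pre"].values.to_numpy())
        post = binned_median_trend(default_pipeline_result["log2_post"].values.to_numpy())
        assert post <= 0.2 * pre

    def test_dimensions_and_missingness_preserved(self, default_pipeline_result):
        pre = default_pipeline_result["log2_pre"].values
        post = default_pipeline_result["log2_post"].values
        assert pre.shape == post.shape
        assert (pre.isna() == post.isna()).all().all()
        assert list(pre.index) == list(post.index)

    def test_permutation_of_samples_is_immaterial(self):
        q = biased_log2_table()
        out1, _ = tmtde.cyclic_loess_normalize(q)
        perm = [3, 0, 5, 1, 4, 2]
        qp = tmtde.QuantTable(q.values.iloc[:, perm], q.gene_symbols, "log2")
        out2, _ = tmtde.cyclic_loess_normalize(qp)
        np.testing.assert_allclose(
            out1.values.to_numpy(),
            out2.values[q.sample_ids].to_numpy(),
            atol=1e-6,
        )

    def test_medians_align_on_clean_complete_data(self):
        """Bias-free, complete, i.i.d. log-normal intensities: after
        normalization the samples' log2 levels agree to < 0.02 in the
        median, assessed pairwise (median of per-protein differences, the
        paired quantity the normalization controls)."""
        rng = np.random.default_rng(9)
        base = rng.normal(20, 2, 2000)
        vals = base[:, None] + rng.normal(0, 0.25, (2000, 8))
        q = make_table(vals, scale="log2")
        out, _ = tmtde.cyclic_loess_normalize(q)
        o = out.values.to_numpy()
        worst = max(
            abs(np.median(o[:, i] - o[:, j]))
            for i in range(8) for j in range(i + 1, 8)
        )
        assert worst < 0.02

    def test_parameter_validation(self):
        q = biased_log2_table(n=60)
        with pytest.raises(ValueError):
            tmtde.cyclic_loess_normalize(q, span=0.0)
        with pytest.raises(ValueError):
            tmtde.cyclic_loess_normalize(q, span=1.5)
        single = tmtde.QuantTable(q.values.iloc[:, :1], scale="log2")
        with pytest.raises(ValueError):
            tmtde.cyclic_loess_normalize(single)

    def test_sparse_pair_skipped_with_report(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(20, 2, (100, 3))
        vals[5:, 2] = np.nan  # sample c shares only 5 proteins with a and b
        q = make_table(vals, samples=["a", "b", "c"], scale="log2")
        out, report = tmtde.cyclic_loess_normalize(q)
        assert ("a", "c") in report.skipped_pairs
        assert ("b", "c") in report.skipped_pairs
        # the sparse sample is left untouched
        np.testing.assert_allclose(
            out.values["c"].dropna(), q.values["c"].dropna(), atol=1e-12)

    def test_agrees_with_limma_reference(self, tmp_path):
        """Cross-check against limma::normalizeCyclicLoess(method='pairs').

        The absolute level is not identified (any smooth component common to
        all samples survives normalization), so agreement is judged on what
        the method controls: both implementations must flatten the pairwise
        M(A) trend of the same biased matrix to a small fraction of its
        initial size.
        """
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        q = biased_log2_table(seed=11, n=500, n_samples=4)
        mat = tmp_path / "mat.tsv"
        out = tmp_path / "limma.tsv"
        np.savetxt(mat, q.values.to_numpy(), delimiter="\t")
        script = (
            f'x <- as.matrix(read.table("{mat}")); '
            "suppressMessages(library(limma)); "
            'y <- normalizeCyclicLoess(x, span=0.7, iterations=3, method="pairs"); '
            f'write.table(y, "{out}", sep="\\t", row.names=FALSE, col.names=FALSE)'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        limma_vals = np.loadtxt(out)
        ours, _ = tmtde.cyclic_loess_normalize(q)

        pre = binned_median_trend(q.values.to_numpy(), n_bins=8)
        t_ours = binned_median_trend(ours.values.to_numpy(), n_bins=8)
        t_limma = binned_median_trend(limma_vals, n_bins=8)
        assert t_ours <= 0.2 * pre
        assert t_limma <= 0.2 * pre
        # and the two normalized matrices tell the same pairwise story in the
        # well-populated intensity range
        a_all = q.values.to_numpy().mean(axis=1)
        interior = (a_all > np.quantile(a_all, 0.05)) & (a_all < np.quantile(a_all, 0.95))
        o = ours.values.to_numpy()
        for i in range(4):
            for j in range(i + 1, 4):
                diff = (o[interior, i] - o[interior, j]) - (
                    limma_vals[interior, i] - limma_vals[interior, j])
                assert np.mean(np.abs(diff)) < 0.05
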