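"""Probe- and gene-level signature pipeline stages and end-to-end runs."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cptsig import (
    ExpressionMatrix,
    ProbeAnnotation,
    ScreenParams,
    SyntheticConfig,
    aggregate_probes_to_genes,
    build_target_reference,
    robust_standardize_rows,
    run_exon_array_signature,
    run_gene_level_signature,
    screen_probes,
    select_coherent_target_probes,
    simulate_exon_dataset,
)


def _matrix(ids, values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix.from_arrays(ids, samples, values)


class TestCoherentTargetSelection:
    def test_duplicated_rows_all_retained(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = _matrix(["a", "b", "c"], [base, base, base])
        assert select_coherent_target_probes(m, ["a", "b", "c"]) == ["a", "b", "c"]

    def test_anticorrelated_probe_excluded(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(12)
        m = _matrix(["A", "B", "C"], [base, base + 0.05 * rng.standard_normal(12), -base])
        assert select_coherent_target_probes(m, ["A", "B", "C"]) == ["A", "B"]

    def test_matches_exhaustive_subset_oracle(self):
        rng = np.random.default_rng(42)
        n, k = 20, 6
        latent = rng.standard_normal(n)
        rows = [latent + 0.4 * rng.standard_normal(n) for _ in range(4)]
        rows += [rng.standard_normal(n), -latent]
        ids = [f"t{i}" for i in range(k)]
        m = _matrix(ids, rows)
        result = select_coherent_target_probes(m, ids, 0.5)

        # independent oracle: enumerate all subsets, same tie-break rules
        rmat = np.corrcoef(np.asarray(rows))
        best = None
        for size in range(k, 1, -1):
            for combo in itertools.combinations(range(k), size):
                prs = [rmat[i, j] for i, j in itertools.combinations(combo, 2)]
                if all(r > 0.5 for r in prs):
                    key = (size, np.mean(prs), tuple(-c for c in combo))
                    if best is None or key > best[0]:
                        best = (key, combo)
            if best:
                break
        assert result == [ids[i] for i in best[1]]

    def test_six_probe_driver_retains_five_coherent(self):
        m, ann, _ = simulate_exon_dataset(SyntheticConfig(seed=5))
        retained = select_coherent_target_probes(m, ann.probes_for("MYC"), 0.5)
        assert len(retained) == 5
        assert "MYC_p6" not in retained  # the decorrelated probe

    def test_absent_probes_error(self, small_matrix):
        with pytest.raises(KeyError):
            select_coherent_target_probes(small_matrix, ["nope"])


class TestScreenProbes:
    def test_targets_always_pass(self):
        rng = np.random.default_rng(1)
        m = _matrix([f"p{i}" for i in range(10)], rng.standard_normal((10, 20)))
        out = screen_probes(m, ["p3", "p7"], ScreenParams())
        assert {"p3", "p7"} <= set(out)

    def test_matches_bruteforce_pairwise_oracle(self):
        from cptsig.corr_stats import pearson

        rng = np.random.default_rng(7)
        latent = rng.standard_normal(30)
        ids, rows = [], []
        for i in range(15):
            ids.append(f"mod{i}")
            rows.append(latent + 0.6 * rng.standard_normal(30))
        for i in range(40):
            ids.append(f"bg{i}")
            rows.append(rng.standard_normal(30))
        m = _matrix(ids, rows)
        params = ScreenParams(p_max=0.01)
        out = set(screen_probes(m, ["mod0", "mod1"], params))

        expected = set()
        for fid in ids:
            for t in ("mod0", "mod1"):
                rec = pearson(m.row(fid), m.row(t))
                if abs(rec.r) >= params.r_min and rec.p < params.p_max:
                    expected.add(fid)
                    break
        assert out == expected

    def test_zero_variance_probe_silently_excluded(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(15)
        m = _matrix(["t", "flat"], [base, np.zeros(15)])
        assert screen_probes(m, ["t"], ScreenParams()) == ["t"]

    def test_empty_targets_error(self, small_matrix):
        with pytest.raises(ValueError):
            screen_probes(small_matrix, [], ScreenParams())


class TestRobustStandardize:
    def test_hand_example(self):
        m = _matrix(["r1"], [[1.0, 2.0, 3.0, 4.0, 5.0]])
        out = robust_standardize_rows(m)
        np.testing.assert_allclose(out.values[0], [-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_output_rows_have_median0_iqr1(self):
        rng = np.random.default_rng(3)
        m = _matrix([f"p{i}" for i in range(20)], rng.standard_normal((20, 11)) * 5 + 2)
        out = robust_standardize_rows(m)
        med = np.median(out.values, axis=1)
        q1, q3 = np.percentile(out.values, [25, 75], axis=1, method="linear")
        np.testing.assert_allclose(med, 0.0, atol=1e-12)
        np.testing.assert_allclose(q3 - q1, 1.0, atol=1e-12)

    def test_idempotent_on_standardized_rows(self):
        rng = np.random.default_rng(4)
        m = _matrix([f"p{i}" for i in range(5)], rng.standard_normal((5, 9)))
        once = robust_standardize_rows(m)
        twice = robust_standardize_rows(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_row_dropped(self):
        m = _matrix(["flat", "var"], [[2.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0]])
        out = robust_standardize_rows(m)
        assert out.feature_ids == ["var"]
        assert out.n_dropped_degenerate == 1

    def test_all_degenerate_is_error(self):
        m = _matrix(["f1", "f2"], [[1.0] * 4, [2.0] * 4])
        with pytest.raises(ValueError):
            robust_standardize_rows(m)


class TestAggregation:
    def test_single_probe_gene_passthrough(self, annotation):
        m = _matrix(["p3"], [[0.5, -0.5, 1.5]])
        out = aggregate_probes_to_genes(m, annotation)
        assert out.feature_ids == ["GENEB"]
        np.testing.assert_array_equal(out.values[0], m.values[0])

    def test_mean_of_two_probes(self, annotation):
        m = _matrix(["p1", "p2"], [[0.2, 1.0], [0.4, 3.0]])
        out = aggregate_probes_to_genes(m, annotation)
        np.testing.assert_allclose(out.row("GENEA"), [0.3, 2.0])

    def test_matches_per_gene_loop_oracle(self):
        rng = np.random.default_rng(11)
        probes = [f"p{i}" for i in range(30)]
        genes = {p: f"G{rng.integers(0, 8)}" for p in probes}
        m = _matrix(probes, rng.standard_normal((30, 7)))
        out = aggregate_probes_to_genes(m, ProbeAnnotation(genes))
        for g in out.feature_ids:
            members = [p for p in probes if genes[p] == g]
            expected = np.mean([m.row(p) for p in members], axis=0)
            np.testing.assert_allclose(out.row(g), expected, atol=1e-12)

    def test_unannotated_probes_dropped(self):
        ann = ProbeAnnotation({"p1": "GENEA"})
        m = _matrix(["p1", "orphan"], [[1.0, 2.0], [3.0, 4.0]])
        out = aggregate_probes_to_genes(m, ann)
        assert out.feature_ids == ["GENEA"]
        assert out.n_dropped_unannotated == 1

    def test_no_annotated_probe_is_error(self):
        ann = ProbeAnnotation({"px": "GENEX"})
        m = _matrix(["p1"], [[1.0, 2.0]])
        with pytest.raises(ValueError):
            aggregate_probes_to_genes(m, ann)


@pytest.fixture(scope="module")
def dataset():
    cfg = SyntheticConfig(
        n_samples=40, n_module_genes=40, n_background_genes=300, seed=123
    )
    return simulate_exon_dataset(cfg)


class TestEndToEnd:

    def test_planted_module_recovered(self, dataset):
        m, ann, truth = dataset
        result = run_exon_array_signature(m, ann, "MYC")
        assert len(result.retained_target_probes) == 5
        recovered = truth.module_genes & set(result.signature_genes)
        assert len(recovered) / len(truth.module_genes) >= 0.95

    def test_signature_thresholds_recomputable(self, dataset):
        m, ann, truth = dataset
        result = run_exon_array_signature(m, ann, "MYC")
        ref = result.reference_vector
        for gene in result.signature_genes:
            r, _ = stats.pearsonr(result.gene_matrix.row(gene), ref)
            assert abs(r) >= result.params.r_min

    def test_screened_superset_of_targets(self, dataset):
        m, ann, _ = dataset
        result = run_exon_array_signature(m, ann, "MYC")
        assert set(result.retained_target_probes) <= set(result.screened_probes)

    def test_sample_and_feature_order_invariance(self, dataset):
        m, ann, _ = dataset
        base = run_exon_array_signature(m, ann, "MYC")
        rng = np.random.default_rng(0)
        perm_s = rng.permutation(m.n_samples)
        perm_f = rng.permutation(m.n_features)
        shuffled = ExpressionMatrix(
            m.data.iloc[perm_f, perm_s], scale_tag=m.scale_tag
        )
        other = run_exon_array_signature(shuffled, ann, "MYC")
        assert other.counts == base.counts
        assert set(other.signature_genes) == set(base.signature_genes)

    def test_threshold_monotonicity(self, dataset):
        """Raising r_min or lowering p_max never grows the signature."""
        m, ann, _ = dataset
        sizes = {}
        for r_min in (0.4, 0.5, 0.6):
            for p_max in (0.05, 0.01, 0.001):
                res = run_exon_array_signature(
                    m, ann, "MYC", ScreenParams(r_min=r_min, p_max=p_max)
                )
                sizes[(r_min, p_max)] = set(res.signature_genes)
        for r1 in (0.4, 0.5):
            for p in (0.05, 0.01, 0.001):
                assert sizes[(r1 + 0.1, p)] <= sizes[(r1, p)]
        for r in (0.4, 0.5, 0.6):
            assert sizes[(r, 0.001)] <= sizes[(r, 0.01)] <= sizes[(r, 0.05)]

    def test_target_exclusion_flag(self, dataset):
        m, ann, _ = dataset
        excl = run_exon_array_signature(m, ann, "MYC", exclude_target=True)
        incl = run_exon_array_signature(m, ann, "MYC", exclude_target=False)
        assert "MYC" not in excl.signature_genes
        assert "MYC" in incl.signature_genes
        assert excl.target_record is not None
        assert excl.target_record.r == pytest.approx(1.0)

    def test_per_probe_reference_mode_runs(self, dataset):
        m, ann, truth = dataset
        res = run_exon_array_signature(m, ann, "MYC", reference_mode="per_probe")
        recovered = truth.module_genes & set(res.signature_genes)
        assert len(recovered) / len(truth.module_genes) >= 0.95


class TestGeneLevelPath:
    def test_target_row_r1_and_excluded(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal(20)
        m = _matrix(
            ["Myc", "g1", "g2"],
            [latent, latent + 0.3 * rng.standard_normal(20), rng.standard_normal(20)],
        )
        res = run_gene_level_signature(m, "Myc", ScreenParams(p_max=0.05))
        assert "Myc" not in res.signature_genes
        assert res.target_record.r == pytest.approx(1.0)
        assert "g1" in res.signature_genes

    def test_n6_p_criterion_binds(self):
        """With 6 samples, p < 0.05 implies |r| > ~0.811, so r in (0.5, 0.811) fails."""
        rng = np.random.default_rng(5)
        ref = rng.standard_normal(6)
        z = rng.standard_normal(6)
        refc = (ref - ref.mean()) / np.linalg.norm(ref - ref.mean())
        zc = z - z.mean() - ((z - z.mean()) @ refc) * refc
        zc /= np.linalg.norm(zc)

        def gene_with_r(r):
            return r * refc + np.sqrt(1 - r * r) * zc

        m = _matrix(
            ["Myc", "mid", "high"],
            [ref, gene_with_r(0.7), gene_with_r(0.95)],
            samples=[f"s{j}" for j in range(6)],
        )
        res = run_gene_level_signature(m, "Myc", ScreenParams(p_max=0.05))
        assert "mid" not in res.signature_genes  # 0.5 < r < 0.811 rejected
        assert "high" in res.signature_genes

    def test_absent_target_errors(self):
        m = _matrix(["g1"], [[1.0, 2.0, 3.0]])
        with pytest.raises(KeyError):
            run_gene_level_signature(m, "Myc")
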