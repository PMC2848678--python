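import numpy as np
import pytest

from hgtbench import composition as comp
from hgtbench.composition import CompositionVector, Criterion
from hgtbench.detector import (
    METHOD_NAMES,
    Direction,
    GeneScores,
    MethodConfig,
    Reference,
    ScanMode,
    WindowScores,
    gene_vector,
    genome_reference,
    method_registry,
    project_to_genes,
    robust_host_signature,
    scan_windows,
    score_genes,
    score_windows,
)
from hgtbench.genome_io import AnnotatedGenome, Gene, SequenceRecord
from hgtbench.metrics import MetricName


class TestRegistry:
    # every cell of the published method table: (criterion, mode,
    # window, step, metric, direction)
    EXPECTED = {
        "GC.windows": (Criterion.GC, ScanMode.WINDOW, 20000, 5000,
                       MetricName.MANHATTAN, Direction.UPPER),
        "GCtotal": (Criterion.GC, ScanMode.GENE, None, None,
                    MetricName.NONE, Direction.TWO_SIDED),
        "GC1-GC3": (Criterion.GC1GC3, ScanMode.GENE, None, None,
                    MetricName.NONE, Direction.TWO_SIDED),
        "dint5": (Criterion.DINUC_NORM, ScanMode.WINDOW, 5000, 5000,
                  MetricName.DELTA_STAR, Direction.UPPER),
        "dint.di31T2": (Criterion.DINUC31, ScanMode.GENE, None, None,
                        MetricName.MAHALANOBIS, Direction.UPPER),
        "CU.chi2": (Criterion.CODON, ScanMode.GENE, None, None,
                    MetricName.CHI2, Direction.UPPER),
        "CU.karlin": (Criterion.CODON, ScanMode.GENE, None, None,
                      MetricName.DELTA_STAR, Direction.UPPER),
        "CU.karlin.aa": (Criterion.AA, ScanMode.GENE, None, None,
                         MetricName.DELTA_STAR, Direction.UPPER),
        "CU.KL": (Criterion.CODON, ScanMode.GENE, None, None,
                  MetricName.KL, Direction.UPPER),
        "CU.mahalanobis": (Criterion.CODON, ScanMode.GENE, None, None,
                           MetricName.MAHALANOBIS, Direction.UPPER),
        "oli.Pearson": (Criterion.TETRA_NORM, ScanMode.WINDOW, 5000, 1000,
                        MetricName.PEARSON, Direction.LOWER),
        "oli.covariance": (Criterion.TETRA_NORM, ScanMode.WINDOW, 5000, 1000,
                           MetricName.COVARIANCE, Direction.LOWER),
        "oli.chi2": (Criterion.TETRA_NORM, ScanMode.WINDOW, 5000, 1000,
                     MetricName.CHI2, Direction.UPPER),
        "oli.mahalanobis": (Criterion.TETRA_NORM, ScanMode.WINDOW, 5000, 1000,
                            MetricName.MAHALANOBIS, Direction.UPPER),
        "oli.KL": (Criterion.TETRA_NORM, ScanMode.WINDOW, 5000, 1000,
                   MetricName.KL, Direction.UPPER),
        "signature": (Criterion.TETRA, ScanMode.WINDOW, 5000, 500,
                      MetricName.EUCLIDEAN, Direction.UPPER),
    }

    def test_exactly_sixteen_methods(self):
        assert set(METHOD_NAMES) == set(self.EXPECTED)

    @pytest.mark.parametrize("name", sorted(EXPECTED))
    def test_every_registry_cell(self, name):
        cfg = method_registry(name)
        crit, mode, w, s, metric, direction = self.EXPECTED[name]
        assert cfg.criterion is crit
        assert cfg.mode is mode
        assert cfg.window_bp == w
        assert cfg.step_bp == s
        assert cfg.metric is metric
        assert cfg.direction is direction

    def test_signature_uses_robust_reference(self):
        assert method_registry("signature").reference is Reference.ROBUST_SIGNATURE

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(KeyError, match="oli.chi2"):
            method_registry("no-such-method")


class TestScanWindows:
    def test_exact_tiling(self):
        assert scan_windows(20000, 5000, 5000) == [
            (0, 5000), (5000, 10000), (10000, 15000), (15000, 20000)
        ]

    def test_no_extra_window_when_last_reaches_end(self):
        ws = scan_windows(12000, 5000, 1000)
        assert len(ws) == 8
        assert ws[0] == (0, 5000) and ws[-1] == (7000, 12000)

    def test_end_anchored_final_window(self):
        assert scan_windows(5500, 5000, 5000) == [(0, 5000), (500, 5500)]

    def test_window_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            scan_windows(4000, 5000, 1000)


def _vec(values):
    return CompositionVector(Criterion.TETRA, np.asarray(values, float), 100)


class TestRobustHostSignature:
    def test_homogeneous_windows_give_plain_mean(self):
        vs = [_vec(np.full(256, 1 / 256)) for _ in range(10)]
        out = robust_host_signature(vs)
        assert out.values == pytest.approx(np.full(256, 1 / 256))

    def test_minority_cluster_excluded(self):
        u = np.full(256, 1 / 256)
        v = u.copy()
        v[:8] += 0.05  # strongly shifted minority
        v /= v.sum()
        vs = [_vec(u)] * 90 + [_vec(v)] * 10
        out = robust_host_signature(vs)
        assert out.values == pytest.approx(u, abs=1e-12)

    def test_order_invariance(self, rng):
        u = np.full(256, 1 / 256)
        v = u + rng.normal(0, 0.002, 256)
        v = np.abs(v) / np.abs(v).sum()
        vs = [_vec(u)] * 20 + [_vec(v)] * 4
        a = robust_host_signature(vs)
        perm = list(np.array(vs, dtype=object)[rng.permutation(len(vs))])
        b = robust_host_signature(perm)
        assert a.values == pytest.approx(b.values, abs=1e-12)

    def test_few_windows_fall_back_with_warning(self):
        vs = [_vec(np.full(256, 1 / 256))] * 3
        with pytest.warns(UserWarning):
            out = robust_host_signature(vs)
        assert out.values == pytest.approx(np.full(256, 1 / 256))


class TestProjectToGenes:
    def test_gene_inside_single_window(self):
        ws = WindowScores("m", [(0, 5000, 2.0), (5000, 10000, 7.0)])
        gs = project_to_genes(ws, [Gene("a", 100, 900)])
        assert gs.scores["a"] == 2.0

    def test_weighted_mean_across_two_windows(self):
        # 300 bp in a window scoring 2, 100 bp in a window scoring 4
        ws = WindowScores("m", [(0, 1000, 2.0), (1000, 2000, 4.0)])
        gs = project_to_genes(ws, [Gene("a", 700, 1100)])
        assert gs.scores["a"] == pytest.approx((2 * 300 + 4 * 100) / 400)

    def test_matches_brute_force_on_random_fixtures(self, rng):
        """Barycenter projection equals an independent O(genes x windows)
        overlap scan, exactly."""
        for _ in range(100):
            length = int(rng.integers(4000, 20000))
            w = int(rng.integers(500, 3000))
            s = int(rng.integers(100, w + 1))
            windows = scan_windows(length, w, s)
            scores = rng.normal(size=len(windows))
            ws = WindowScores("m", [(a, b, sc) for (a, b), sc in zip(windows, scores)])
            genes = []
            pos = 0
            gi = 0
            while pos < length - 100:
                glen = int(rng.integers(60, 900))
                end = min(pos + glen, length)
                genes.append(Gene(f"g{gi}", pos, end))
                pos = end + int(rng.integers(10, 200))
                gi += 1
            got = project_to_genes(ws, genes)
            for g in genes:
                num = den = 0.0
                for (a, b, sc) in ws.windows:
                    ov = min(b, g.end) - max(a, g.start)
                    if ov > 0:
                        num += sc * ov
                        den += ov
                assert got.scores[g.id] == pytest.approx(num / den, abs=1e-12)

    def test_projection_stays_within_contributing_range(self, rng):
        windows = scan_windows(10000, 2000, 500)
        scores = rng.normal(size=len(windows))
        ws = WindowScores("m", [(a, b, s) for (a, b), s in zip(windows, scores)])
        genes = [Gene("a", 1234, 4321), Gene("b", 8000, 9999)]
        gs = project_to_genes(ws, genes)
        for g in genes:
            contrib = [
                s for (a, b, s) in ws.windows
                if min(b, g.end) - max(a, g.start) > 0
            ]
            assert min(contrib) - 1e-12 <= gs.scores[g.id] <= max(contrib) + 1e-12


def _toy_genome(seq_parts, gene_spans):
    seq = "".join(seq_parts)
    genes = [Gene(f"g{i}", a, b) for i, (a, b) in enumerate(gene_spans)]
    return AnnotatedGenome(SequenceRecord("toy", seq), genes)


class TestScoreGenes:
    def test_gctotal_zero_for_gene_at_reference(self):
        # two identical genes -> reference GC equals each gene's GC
        gene = "ATGGCATTC"
        genome = _toy_genome(
            [gene, "A" * 20, gene], [(0, 9), (29, 38)]
        )
        gs = score_genes(genome, "GCtotal")
        assert gs.scores["g0"] == pytest.approx(0.0, abs=1e-12)
        assert gs.scores["g1"] == pytest.approx(0.0, abs=1e-12)

    def test_cu_kl_zero_when_usage_matches_reference(self):
        gene = "ATGGCATTC"
        genome = _toy_genome([gene, "A" * 20, gene], [(0, 9), (29, 38)])
        gs = score_genes(genome, "CU.KL")
        assert gs.scores["g0"] == pytest.approx(0.0, abs=1e-12)

    def test_gc1gc3_has_two_components(self):
        gene = "ATGGCATTC"
        genome = _toy_genome([gene, "A" * 20, gene], [(0, 9), (29, 38)])
        gs = score_genes(genome, "GC1-GC3")
        assert gs.scores2 is not None
        assert set(gs.scores) == set(gs.scores2) == {"g0", "g1"}

    def test_gene_mean_reference_of_two_genes(self):
        # genes with GC 0 and 1 -> reference 0.5
        genome = _toy_genome(
            ["ATATAT", "A" * 20, "GCGCGC"], [(0, 6), (26, 32)]
        )
        cfg = method_registry("GCtotal")
        ref = genome_reference(genome, cfg)
        assert ref.values[0] == pytest.approx(0.5)

    def test_whole_genome_gc_reference(self):
        genome = _toy_genome(["GGCCATAT"], [(0, 8)])
        cfg = MethodConfig(
            "GC.windows", Criterion.GC, ScanMode.WINDOW,
            MetricName.MANHATTAN, Direction.UPPER, Reference.WHOLE_GENOME,
            8, 8,
        )
        ref = genome_reference(genome, cfg)
        assert ref.values[0] == pytest.approx(0.5)


class TestWindowScoring:
    def _uniformish(self, rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_homogeneous_genome_scores_near_zero(self, rng):
        seq = self._uniformish(rng, 12000)
        genome = _toy_genome([seq], [(0, 1200)])
        cfg = MethodConfig(
            "sig-test", Criterion.TETRA, ScanMode.WINDOW,
            MetricName.EUCLIDEAN, Direction.UPPER, Reference.WHOLE_GENOME,
            4000, 2000,
        )
        ws = score_windows(genome, cfg)
        assert len(ws.windows) == len(scan_windows(12000, 4000, 2000))
        scores = [s for _, _, s in ws.windows]
        # sampling noise only: all scores small and similar
        assert max(scores) < 0.1

    def test_divergent_block_scores_higher(self, rng):
        """Windows overlapping a compositionally divergent block must
        outscore windows that do not, for a distance metric."""
        host = self._uniformish(rng, 20000)
        block = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=5000))
        seq = host[:10000] + block + host[10000:]
        genome = _toy_genome([seq], [(0, 600)])
        cfg = MethodConfig(
            "sig-test", Criterion.TETRA, ScanMode.WINDOW,
            MetricName.EUCLIDEAN, Direction.UPPER, Reference.WHOLE_GENOME,
            5000, 1000,
        )
        ws = score_windows(genome, cfg)
        inside = [s for a, b, s in ws.windows if min(b, 15000) - max(a, 10000) >= 2500]
        outside = [s for a, b, s in ws.windows if min(b, 15000) - max(a, 10000) <= 0]
        assert min(inside) > max(outside)

    def test_oli_chi2_gene_scores_match_end_to_end_brute_force(self, rng):
        """oli.chi2 on a small genome equals independent window counting,
        chi2 arithmetic and barycenter projection."""
        from hgtbench.composition import normalized_tetranucleotides

        seq = self._uniformish(rng, 9000)
        genes = [(100, 1300), (2000, 3500), (5000, 8200)]
        genome = _toy_genome([seq], genes)
        cfg = MethodConfig(
            "oli.chi2", Criterion.TETRA_NORM, ScanMode.WINDOW,
            MetricName.CHI2, Direction.UPPER, Reference.WHOLE_GENOME,
            3000, 1000,
        )
        got = score_genes(genome, cfg)

        ref = normalized_tetranucleotides(seq)
        windows = []
        for a in range(0, 9000 - 3000 + 1, 1000):
            w = normalized_tetranucleotides(seq[a : a + 3000])
            o = w.values * w.support
            e = ref.values * w.support
            m = e > 0
            windows.append((a, a + 3000, float(((o[m] - e[m]) ** 2 / e[m]).sum())))
        for i, (a, b) in enumerate(genes):
            num = den = 0.0
            for wa, wb, sc in windows:
                ov = min(wb, b) - max(wa, a)
                if ov > 0:
                    num += sc * ov
                    den += ov
            assert got.scores[f"g{i}"] == pytest.approx(num / den, rel=1e-9)


class TestInsertedBlockSeparation:
    def test_distance_methods_rank_inserted_genes_higher(self, small_family):
        """Planting a strongly divergent multi-gene block raises the mean
        score of inserted genes above native genes for every
        distance-metric method that can run at this genome size."""
        from hgtbench.simulator import (
            ModelGenomeRecipe, insert_hts, synthesize_genome,
        )

        host, donors = small_family
        base = synthesize_genome(host, 80, seed=5)
        recipe = ModelGenomeRecipe(0.10, (6, 8), (("d2", 1.0),), seed=5)
        genome = insert_hts(base, donors, recipe, seed=9)
        assert any(v != "native" for v in genome.truth.values())
        for name in ("dint5", "oli.chi2", "oli.KL", "signature", "CU.KL"):
            gs = score_genes(genome, name)
            ht = [s for gid, s in gs.scores.items() if genome.truth[gid] != "native"]
            nat = [s for gid, s in gs.scores.items() if genome.truth[gid] == "native"]
            assert np.mean(ht) > np.mean(nat), name
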