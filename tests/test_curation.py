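"""Curation screen: differential-region arithmetic (with a per-base
brute-force oracle), RD/REL criteria, convergent-pair geometry and the
full curation funnel on a cohort with planted miscalls."""

import math

import numpy as np
import pytest

from ctsai import (
    CoverageTrack,
    GeneModel,
    IsoformStats,
    TranscriptModel,
    apply_filter_cascade,
    census,
    curate,
    detect_convergent_pairs,
    differential_regions,
    filter_expressed_genes,
    read_density_check,
    relative_support_score,
    run_detection,
    simulate_dataset,
    SimulationParams,
)
from ctsai.models import ConsistencyError
from ctsai.simulate import CONV_GONIDIA, CONV_SOMA


def _tx(tid, exons, gene="g1", chrom="chr1", strand="+"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons))


def _bases(intervals):
    return {b for s, e in intervals for b in range(s, e)}


class TestDifferentialRegions:
    def test_subset_isoform(self):
        r = differential_regions(
            _tx("t1", [(0, 100)]), _tx("t2", [(0, 100), (200, 300)])
        )
        assert r.unique_to_iso1 == ()
        assert r.unique_to_iso2 == ((200, 300),)
        assert r.shared == ((0, 100),)

    def test_identical_isoforms(self):
        r = differential_regions(
            _tx("t1", [(0, 50), (80, 120)]), _tx("t2", [(0, 50), (80, 120)])
        )
        assert r.unique_to_iso1 == () and r.unique_to_iso2 == ()
        assert r.shared == ((0, 50), (80, 120))

    def test_staggered_overlap(self):
        r = differential_regions(_tx("t1", [(0, 50)]), _tx("t2", [(25, 75)]))
        assert r.unique_to_iso1 == ((0, 25),)
        assert r.unique_to_iso2 == ((50, 75),)
        assert r.shared == ((25, 50),)

    def test_different_chrom_rejected(self):
        with pytest.raises(ConsistencyError):
            differential_regions(
                _tx("t1", [(0, 50)]), _tx("t2", [(0, 50)], chrom="chr2")
            )

    def test_matches_per_base_brute_force(self):
        """Interval arithmetic equals per-base set arithmetic on 100
        random isoform pairs."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            def random_exons():
                n = rng.integers(1, 5)
                points = np.sort(rng.choice(400, size=2 * n, replace=False))
                return [
                    (int(points[2 * i]), int(points[2 * i + 1]))
                    for i in range(n)
                    if points[2 * i] < points[2 * i + 1]
                ] or [(0, 10)]
            t1 = _tx("t1", random_exons())
            t2 = _tx("t2", random_exons())
            r = differential_regions(t1, t2)
            b1, b2 = _bases(t1.exons), _bases(t2.exons)
            assert _bases(r.unique_to_iso1) == b1 - b2
            assert _bases(r.unique_to_iso2) == b2 - b1
            assert _bases(r.shared) == b1 & b2
            # partition of the exonic union
            assert (
                _bases(r.unique_to_iso1) | _bases(r.unique_to_iso2)
                | _bases(r.shared)
            ) == b1 | b2


def _track(soma, gonidia, chrom="chr1"):
    return CoverageTrack(
        {"soma": {chrom: np.asarray(soma, float)},
         "gonidia": {chrom: np.asarray(gonidia, float)}}
    )


class TestReadDensity:
    regions = differential_regions(
        _tx("t1", [(0, 100), (100, 200)]), _tx("t2", [(100, 200), (200, 300)])
    )
    claimed = {"iso1": "soma", "iso2": "gonidia"}

    def test_uniform_dense_coverage_passes(self):
        cov = _track([20] * 300, [20] * 300)
        assert read_density_check(cov, self.regions, self.claimed).rd_pass

    def test_uncovered_unique_region_fails(self):
        soma = [20] * 300
        gon = [20] * 200 + [0] * 100  # iso2's unique region empty in gonidia
        res = read_density_check(_track(soma, gon), self.regions, self.claimed)
        assert res.iso1_pass and not res.iso2_pass and not res.rd_pass

    def test_threshold_is_inclusive(self):
        cov = _track([5.0] * 300, [5.0] * 300)
        assert read_density_check(cov, self.regions, self.claimed,
                                  min_mean_depth=5.0).rd_pass

    def test_isoform_without_unique_region_fails(self):
        regions = differential_regions(
            _tx("t1", [(0, 100)]), _tx("t2", [(0, 100), (200, 300)])
        )
        cov = _track([50] * 300, [50] * 300)
        res = read_density_check(cov, regions, self.claimed)
        assert not res.iso1_pass and not res.rd_pass


class TestRelativeSupport:
    # unique1 = [0,100), shared = [100,200), unique2 = [200,300)
    regions = differential_regions(
        _tx("t1", [(0, 100), (100, 200)]), _tx("t2", [(100, 200), (200, 300)])
    )

    def test_switching_signal_passes(self):
        """u1 = (soma 40, gon 4), u2 = (4, 40), shared = (40, 40):
        score = log2(10) - log2(1/10) ~ 6.64 with opposite-sign terms."""
        soma = [40] * 100 + [40] * 100 + [4] * 100
        gon = [4] * 100 + [40] * 100 + [40] * 100
        score, ok = relative_support_score(
            _track(soma, gon), self.regions, pseudodepth=0.0
        )
        assert score == pytest.approx(2 * math.log2(10))
        assert ok

    def test_flat_signal_fails(self):
        cov = _track([30] * 300, [30] * 300)
        score, ok = relative_support_score(cov, self.regions, pseudodepth=0.0)
        assert score == 0.0 and not ok

    def test_pure_expression_difference_cancels(self):
        """10x higher depth everywhere in soma is exactly the artifact REL
        rejects: normalization cancels it to score 0."""
        base = [40] * 100 + [20] * 100 + [40] * 100
        cov = _track([10 * d for d in base], base)
        score, ok = relative_support_score(cov, self.regions, pseudodepth=0.0)
        assert score == pytest.approx(0.0)
        assert not ok

    def test_scaling_one_cell_type_leaves_score_unchanged(self):
        """Whole-track scaling invariance (pseudodepth 0)."""
        soma = [40] * 100 + [25] * 100 + [4] * 100
        gon = [5] * 100 + [30] * 100 + [45] * 100
        cov = _track(soma, gon)
        s0, _ = relative_support_score(cov, self.regions, pseudodepth=0.0)
        s1, _ = relative_support_score(
            cov.scaled("soma", 7.5), self.regions, pseudodepth=0.0
        )
        assert s1 == pytest.approx(s0)

    def test_empty_shared_region_is_undefined(self):
        regions = differential_regions(
            _tx("t1", [(0, 100)]), _tx("t2", [(200, 300)])
        )
        cov = _track([10] * 300, [10] * 300)
        score, ok = relative_support_score(cov, regions)
        assert score is None and not ok


class TestConvergentPairs:
    def test_planted_pairs_detected_with_bias(self):
        params = SimulationParams(
            n_genes=30, n_ctsai=0, n_convergent_pairs=3,
            replicate_cv=0.0, seed=5,
        )
        models, truth, table, _ = simulate_dataset(params)
        gene_er = {}
        for g in models:
            sums = table.gene_sums()
            soma = sums.loc[g.gene_id, list(table.design.samples_of("soma"))].mean()
            gon = sums.loc[g.gene_id, list(table.design.samples_of("gonidia"))].mean()
            gene_er[g.gene_id] = soma / gon
        pairs = detect_convergent_pairs(models, gene_er)
        assert len(pairs) == 3
        soma_side = truth.genes_with(CONV_SOMA)
        gon_side = truth.genes_with(CONV_GONIDIA)
        for a, b, ov, opposite in pairs:
            assert ov == params.convergent_overlap
            assert opposite
            assert {a, b} & soma_side and {a, b} & gon_side

    def test_same_strand_overlap_not_reported(self):
        a = GeneModel("a", "c", "+", (_tx("a.t1", [(0, 100), (150, 300)], "a", "c"),))
        b = GeneModel("b", "c", "+", (_tx("b.t1", [(250, 400)], "b", "c"),))
        assert detect_convergent_pairs([a, b]) == []

    def test_divergent_5prime_overlap_not_reported(self):
        # '-' gene then '+' gene: overlap touches both 5' ends only
        a = GeneModel("a", "c", "-", (_tx("a.t1", [(0, 100), (150, 300)], "a", "c", "-"),))
        b = GeneModel("b", "c", "+", (_tx("b.t1", [(250, 350), (400, 500)], "b", "c"),))
        assert detect_convergent_pairs([a, b]) == []

    def test_translation_and_order_invariance(self):
        def pair(shift):
            a = GeneModel("a", "c", "+",
                          (_tx("a.t1", [(0 + shift, 100 + shift),
                                        (200 + shift, 300 + shift)], "a", "c"),))
            b = GeneModel("b", "c", "-",
                          (_tx("b.t1", [(260 + shift, 360 + shift),
                                        (500 + shift, 600 + shift)],
                               "b", "c", "-"),))
            return a, b
        a, b = pair(0)
        p0 = detect_convergent_pairs([a, b])
        assert p0 == detect_convergent_pairs([b, a])
        a2, b2 = pair(10_000)
        p1 = detect_convergent_pairs([a2, b2])
        assert [(x, y, ov) for x, y, ov, _ in p0] == [
            (x, y, ov) for x, y, ov, _ in p1
        ]


def _fused_miscall(ga: GeneModel, gb: GeneModel, gene_id: str) -> GeneModel:
    """A convergent pair mis-assembled as one two-'isoform' gene."""
    t1 = ga.transcripts[0]
    t2 = gb.transcripts[0]
    mk = lambda t, n: TranscriptModel(
        f"{gene_id}.t{n}", gene_id, t.chrom, "+", t.exons
    )
    return GeneModel(gene_id, ga.chrom, "+", (mk(t1, 1), mk(t2, 2)))


class TestCurate:
    def test_funnel_on_planted_cohort(self):
        """True switch genes are retained; fused convergent miscalls are
        excluded as CT; every candidate gets exactly one final status."""
        params = SimulationParams(
            n_genes=40, n_ctsai=6, n_convergent_pairs=3,
            replicate_cv=0.0, seed=13,
        )
        models, truth, table, coverage = simulate_dataset(params)
        by_gene = {g.gene_id: g for g in models}

        # candidates: the 6 true switch genes ...
        c = census(models, filter_expressed_genes(table))
        records, _ = run_detection(table, models, c)
        candidates = [r for r in records if r.verdict == "candidate"]
        assert {r.gene_id for r in candidates} == truth.ctsai_genes

        # ... plus 3 convergent pairs misdeclared as isoform pairs
        call_models = list(models)
        soma_side = sorted(truth.genes_with(CONV_SOMA))
        gon_side = sorted(truth.genes_with(CONV_GONIDIA))
        from ctsai import isoform_cell_type_stats
        for i, (a_id, b_id) in enumerate(zip(soma_side, gon_side), 1):
            fused_id = f"fused{i}"
            fused = _fused_miscall(by_gene[a_id], by_gene[b_id], fused_id)
            call_models.append(fused)
            stats = [
                isoform_cell_type_stats(table, f"{gid}.t1")
                for gid in (a_id, b_id)
            ]
            stats = [
                IsoformStats(f"{fused_id}.t{j+1}", s.mean_soma, s.mean_gonidia,
                             s.ER, s.log2ER, s.p_value)
                for j, s in enumerate(stats)
            ]
            candidates.append(apply_filter_cascade(fused_id, stats))

        results, counts = curate(
            candidates, call_models, coverage, reference_models=models
        )
        by_id = {r.gene_id: r for r in results}
        for gid in truth.ctsai_genes:
            assert by_id[gid].final == "retained"
        for i in range(1, 4):
            assert by_id[f"fused{i}"].final == "excluded_CT"
            assert by_id[f"fused{i}"].convergent_flag
        assert counts["input"] == len(candidates)
        assert sum(
            counts[k] for k in
            ("retained", "excluded_RD", "excluded_REL", "excluded_CT")
        ) == counts["input"]

    def test_empty_candidate_list(self, noisefree_cohort):
        _, models, _, _, coverage = noisefree_cohort
        results, counts = curate([], models, coverage)
        assert results == [] and counts["input"] == 0
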