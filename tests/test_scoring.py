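import itertools

import numpy as np
import pandas as pd
import pytest

from offscan import (
    GuideRNA,
    build_feature_matrix,
    cctop_score,
    cfd_score,
    cropit_score,
    feature_columns,
    ingest_external_scores,
    mit_score,
    random_guide,
)
from offscan.scoring import ConfigError, LOCUS_COLS, ScoreTables

from .conftest import make_site

SCORERS = {"CFD": cfd_score, "MIT": mit_score, "CCTop": cctop_score,
           "CROP-IT": cropit_score}


class TestPerfectMatch:
    @pytest.mark.parametrize("name", ["CFD", "MIT", "CROP-IT"])
    def test_unity_at_zero_mismatches(self, guide, tables, name):
        assert SCORERS[name](guide, make_site(guide), tables) == pytest.approx(1.0)

    def test_cctop_zero_is_maximum(self, guide, tables):
        assert cctop_score(guide, make_site(guide), tables) == 0.0


class TestCfd:
    def test_single_mismatch_is_table_factor(self, guide, tables):
        site = make_site(guide, positions=[7])
        g, d = guide.protospacer[6], site.site_seq[6]
        expected = tables.cfd_mm[(7, g, d)] * tables.cfd_pam[site.pam_seq[1:]]
        assert cfd_score(guide, site, tables) == pytest.approx(expected)

    def test_product_of_independent_lookups(self, guide, tables):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(1, 7))
            pos = sorted(rng.choice(np.arange(1, 21), k, replace=False).tolist())
            site = make_site(guide, positions=pos)
            expected = tables.cfd_pam[site.pam_seq[1:]]
            for p in pos:
                expected *= tables.cfd_mm[
                    (p, guide.protospacer[p - 1], site.site_seq[p - 1])
                ]
            assert cfd_score(guide, site, tables) == pytest.approx(expected)

    def test_missing_key_is_config_error(self, guide, tables):
        broken = ScoreTables(
            cfd_mm=dict(tables.cfd_mm),
            cfd_pam=dict(tables.cfd_pam),
            mit_w=tables.mit_w,
            cctop_base=tables.cctop_base,
            cropit_segments=tables.cropit_segments,
        )
        site = make_site(guide, positions=[5])
        key = (5, guide.protospacer[4], site.site_seq[4])
        broken.cfd_mm.pop(key)
        with pytest.raises(ConfigError):
            cfd_score(guide, site, broken)


class TestMit:
    def test_single_mismatch(self, guide, tables):
        site = make_site(guide, positions=[14])
        # distance factor is 1 by convention for n = 1, and 1/n^2 = 1
        assert mit_score(guide, site, tables) == pytest.approx(1 - tables.mit_w[13])

    def test_clustering_penalized_more_than_spread(self, guide, tables):
        # brute force over all position pairs: adjacent pairs never beat the
        # maximally spread pair once the position-weight product is factored out
        def distance_count_part(pos):
            site = make_site(guide, positions=pos)
            s = mit_score(guide, site, tables)
            w = np.prod([1 - tables.mit_w[p - 1] for p in pos])
            return s / w if w > 0 else np.nan

        spread = distance_count_part([1, 20])
        for p in range(1, 20):
            adjacent = distance_count_part([p, p + 1])
            if not np.isnan(adjacent):
                assert adjacent <= spread + 1e-12


class TestCctop:
    def test_pam_proximal_penalized_more(self, guide, tables):
        s20 = cctop_score(guide, make_site(guide, positions=[20]), tables)
        s1 = cctop_score(guide, make_site(guide, positions=[1]), tables)
        assert s20 < s1 < 0

    def test_direct_evaluation(self, guide, tables):
        site = make_site(guide, positions=[3, 17])
        assert cctop_score(guide, site, tables) == pytest.approx(
            -(1.2**3 + 1.2**17)
        )

    def test_strictly_decreasing_per_added_mismatch(self, guide, tables):
        prev = cctop_score(guide, make_site(guide), tables)
        for k in range(1, 7):
            cur = cctop_score(guide, make_site(guide, positions=list(range(1, k + 1))), tables)
            assert cur < prev
            prev = cur


class TestCropit:
    def test_all_mismatched_is_zero(self, guide, tables):
        site = make_site(guide, positions=list(range(1, 21)))
        assert cropit_score(guide, site, tables) == pytest.approx(0.0)

    def test_heavier_segment_costs_more(self, guide, tables):
        lightest = min(tables.cropit_segments, key=lambda s: s[2])
        heaviest = max(tables.cropit_segments, key=lambda s: s[2])
        s_light = cropit_score(guide, make_site(guide, positions=[lightest[0]]), tables)
        s_heavy = cropit_score(guide, make_site(guide, positions=[heaviest[0]]), tables)
        assert s_heavy < s_light

    def test_segment_gap_is_config_error(self, tables):
        with pytest.raises(ConfigError):
            ScoreTables(
                cfd_mm=tables.cfd_mm,
                cfd_pam=tables.cfd_pam,
                mit_w=tables.mit_w,
                cctop_base=tables.cctop_base,
                cropit_segments=((1, 10, 1.0), (12, 20, 2.0)),
            )


class TestInvariants:
    """Shared structural properties of the four native scores."""

    @pytest.mark.parametrize("seed", range(5))
    def test_cfd_mit_non_increasing_under_inclusion(self, tables, seed):
        # brute force over all mismatch sets of size <= 3 (every size-<=2 set
        # extended by every further position)
        guide = random_guide(seed, f"g{seed}")
        rng = np.random.default_rng(seed)
        mutated = {
            p: rng.choice([b for b in "ACGT" if b != guide.protospacer[p - 1]])
            for p in range(1, 21)
        }

        def score_set(name, positions):
            site = make_site(guide, positions=sorted(positions),
                             bases=[mutated[p] for p in sorted(positions)])
            return SCORERS[name](guide, site, tables)

        subsets = [()]
        subsets += [(p,) for p in range(1, 21)]
        subsets += list(itertools.combinations(range(1, 21), 2))
        for name in ("CFD", "MIT"):
            for s in subsets:
                base = score_set(name, s)
                for p in range(1, 21):
                    if p not in s:
                        assert score_set(name, s + (p,)) <= base + 1e-12

    def test_enumeration_order_invariance(self, guide, tables):
        site = make_site(guide, positions=[4, 9, 16])
        shuffled = make_site(guide, positions=[4, 9, 16])
        shuffled.mismatch_positions = (16, 4, 9)  # reorder enumeration only
        for fn in SCORERS.values():
            assert fn(guide, shuffled, tables) == pytest.approx(
                fn(guide, site, tables)
            )

    def test_position_independence(self, guide, tables):
        a = make_site(guide, positions=[5], start=100)
        b = make_site(guide, positions=[5], start=5000)
        for fn in SCORERS.values():
            assert fn(guide, a, tables) == fn(guide, b, tables)


class TestExternalIngestion:
    def _cands(self, guide, tables, n=4):
        sites = [make_site(guide, positions=[i + 1], start=100 * i)
                 for i in range(n)]
        for s in sites:
            s.label = 0
        return build_feature_matrix(sites, [guide], tables)

    def test_full_coverage(self, guide, tables):
        df = self._cands(guide, tables)
        ext = df[LOCUS_COLS].copy()
        ext["score"] = np.arange(len(ext), dtype=float)
        scores, flag, cov = ingest_external_scores(ext, df, "toolX")
        assert cov == 1.0
        assert (flag == 0).all()
        assert list(scores) == list(ext["score"])

    def test_empty_table_fully_imputed(self, guide, tables):
        df = self._cands(guide, tables)
        ext = df[LOCUS_COLS].iloc[:0].copy()
        ext["toolX"] = []
        scores, flag, cov = ingest_external_scores(ext, df, "toolX")
        assert cov == 0.0
        assert (flag == 1).all()

    def test_partial_coverage_min_imputed(self, guide, tables):
        df = self._cands(guide, tables)
        ext = df[LOCUS_COLS].iloc[:2].copy()
        ext["toolX"] = [5.0, 3.0]
        scores, flag, cov = ingest_external_scores(ext, df, "toolX")
        assert cov == pytest.approx(0.5)
        assert (scores.iloc[2:] == 3.0).all()

    def test_row_order_invariance(self, guide, tables):
        df = self._cands(guide, tables)
        ext = df[LOCUS_COLS].copy()
        ext["toolX"] = np.arange(len(ext), dtype=float)
        a, _, _ = ingest_external_scores(ext, df, "toolX")
        b, _, _ = ingest_external_scores(ext.iloc[::-1].reset_index(drop=True),
                                         df, "toolX")
        assert list(a) == list(b)

    def test_duplicate_keys_rejected(self, guide, tables):
        df = self._cands(guide, tables)
        ext = pd.concat([df[LOCUS_COLS]] * 2, ignore_index=True)
        ext["toolX"] = 1.0
        with pytest.raises(ValueError, match="duplicate"):
            ingest_external_scores(ext, df, "toolX")


class TestFeatureMatrix:
    def test_values_equal_individual_calls(self, guide, tables):
        sites = [make_site(guide, positions=[p], start=100 * p) for p in (1, 5, 20)]
        for s in sites:
            s.label = 0
        df = build_feature_matrix(sites, [guide], tables)
        ordered = sorted(sites, key=lambda c: (c.chrom, c.start, c.strand))
        for name, fn in SCORERS.items():
            assert list(df[name]) == [fn(guide, s, tables) for s in ordered]

    def test_adding_external_preserves_native_columns(self, guide, tables):
        sites = [make_site(guide, positions=[p], start=100 * p) for p in (1, 5)]
        for s in sites:
            s.label = 0
        base = build_feature_matrix(sites, [guide], tables)
        ext = base[LOCUS_COLS].copy()
        ext["toolX"] = [0.5, 0.25]
        with_ext = build_feature_matrix(sites, [guide], tables,
                                        external={"toolX": ext})
        for name in SCORERS:
            assert (with_ext[name] == base[name]).all()
        assert "toolX" in feature_columns(with_ext)

    def test_unlabeled_rejected_by_default(self, guide, tables):
        sites = [make_site(guide, positions=[1])]
        with pytest.raises(ValueError, match="label"):
            build_feature_matrix(sites, [guide], tables)

    def test_planted_positives_score_higher_cfd(self, tables):
        # planted positives carry fewer mismatches, hence higher CFD by design
        from offscan import PlantSpec, enumerate_candidates, label_candidates, make_genome, plant_sites
        from offscan.curation import CuratedDataset, OtsRecord

        g = random_guide(31, "pg")
        genome, truth = plant_sites(
            make_genome(30_000, seed=32),
            PlantSpec(guide=g, sites=[(0, "+", "GG"), (1, "-", "GG")], seed=33),
        )
        cands = enumerate_candidates(genome, g, 6)
        validated = CuratedDataset(
            guides=[g],
            records=[OtsRecord(t.guide_name, t.chrom, t.start, t.end, t.strand,
                               t.site_seq, "assay", None) for t in truth],
        )
        labeled = label_candidates(cands, validated).candidates
        df = build_feature_matrix(labeled, [g], tables)
        pos = df[df.label == 1]["CFD"]
        neg = df[df.label == 0]["CFD"]
        if len(neg):
            assert pos.mean() > neg.mean()
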