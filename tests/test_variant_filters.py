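"""Filter-cascade behavior: privacy subtraction on normalized alleles,
context filters with their exact boundary decisions, proximity joining,
and order-independence of the cascade."""

import itertools

import pytest

from otscreen.core_io import GenomeAssembly, MaskSet, VariantRecord, normalize_indel
from otscreen.synthetic_data import generate_genome
from otscreen.target_search import PredictedSite
from otscreen.variant_filters import (
    FILTER_ORDER,
    FilterParams,
    annotate_proximity,
    filter_gc,
    filter_homopolymer,
    filter_repeat,
    nearest_site,
    run_filter_cascade,
    select_private_indels,
)

from oracles import all_pairs_min_distance


def make_site(chrom="chr1", start=1000, strand="+", seed_mm=0, nonseed_mm=0):
    return PredictedSite(
        chrom=chrom, start=start, end=start + 20, strand=strand,
        matched_seq="A" * 20, pam_observed="AGG", pam_class="NGG",
        seed_mm=seed_mm, nonseed_mm=nonseed_mm,
    )


class TestPrivacy:
    def test_empty_controls_everything_survives(self):
        v = VariantRecord("chr1", 100, "AT", "A")
        assert select_private_indels([v], [], []) == [v]

    def test_exact_match_in_db_removed(self):
        v = VariantRecord("chr1", 100, "AT", "A")
        dup = VariantRecord("chr1", 100, "AT", "A", samples=frozenset({"db"}))
        assert select_private_indels([v], [], [dup]) == []

    def test_equivalent_encodings_collapse_after_normalization(self):
        # CA>C at 99 and AA>A at 100 describe the same deletion in a run
        g = GenomeAssembly({"chr1": "T" * 98 + "CAAAAT" + "G" * 10})
        mut = normalize_indel(VariantRecord("chr1", 99, "CA", "C"), g)
        ctrl = normalize_indel(VariantRecord("chr1", 100, "AA", "A"), g)
        assert select_private_indels([mut], [[ctrl]], [], genome=g) == []

    def test_unnormalized_input_detected(self):
        g = GenomeAssembly({"chr1": "T" * 98 + "CAAAAT" + "G" * 10})
        raw = VariantRecord("chr1", 100, "AA", "A")
        with pytest.raises(ValueError, match="un-normalized"):
            select_private_indels([raw], [], [], genome=g)

    def test_position_only_mode_is_looser(self):
        mut = VariantRecord("chr1", 100, "AT", "A")
        other_allele = VariantRecord("chr1", 100, "ATT", "A")
        assert select_private_indels([mut], [[other_allele]], []) == [mut]
        assert select_private_indels(
            [mut], [[other_allele]], [], position_only=True
        ) == []


class TestRepeatFilter:
    mask = MaskSet({"chr1": [(100, 200)]}, label="repeat")

    def test_inside_mask_fails(self):
        (t,) = filter_repeat([VariantRecord("chr1", 151, "A", "AT")], self.mask)
        assert not t.flags["repeat"]

    def test_half_open_boundary_passes(self):
        # REF interval [200, 201) does not intersect [100, 200)
        (t,) = filter_repeat([VariantRecord("chr1", 201, "A", "AT")], self.mask)
        assert t.flags["repeat"]
        # but [199, 200) does
        (t,) = filter_repeat([VariantRecord("chr1", 200, "A", "AT")], self.mask)
        assert not t.flags["repeat"]

    def test_unmasked_chromosome_passes(self):
        (t,) = filter_repeat([VariantRecord("chr2", 150, "A", "AT")], self.mask)
        assert t.flags["repeat"]

    def test_matches_linear_scan_oracle(self, rng):
        ivs = sorted(
            (int(s), int(s) + int(rng.integers(1, 50)))
            for s in rng.integers(0, 5000, size=40)
        )
        mask = MaskSet({"chr1": ivs})
        variants = [
            VariantRecord("chr1", int(p), "AAA", "A")
            for p in rng.integers(1, 5000, size=200)
        ]
        traces = filter_repeat(variants, mask)
        for v, t in zip(variants, traces):
            s, e = v.interval
            naive = any(s < ie and iv < e for iv, ie in ivs)
            assert t.flags["repeat"] == (not naive)


class TestHomopolymerFilter:
    def _genome(self, up, down, ref="GT"):
        # variant at fixed position 51 with controlled flanks
        seq = "ACGTC" * 9 + up + ref + down + "ACGTC" * 9
        return GenomeAssembly({"chr1": seq}), VariantRecord(
            "chr1", 45 + len(up) + 1, ref, ref[0]
        )

    def test_k_run_upstream_fails(self):
        g, v = self._genome("A" * 10, "CGTAGCTAGC")
        (t,) = filter_homopolymer([v], g, k=10)
        assert not t.flags["homopolymer"]
        assert "upstream" in t.fail_reason["homopolymer"]

    def test_k_minus_one_run_passes(self):
        g, v = self._genome("C" + "A" * 9, "CGTAGCTAGC")
        (t,) = filter_homopolymer([v], g, k=10)
        assert t.flags["homopolymer"]

    def test_downstream_run_also_fails(self):
        g, v = self._genome("ACGTACGTAC", "T" * 10)
        (t,) = filter_homopolymer([v], g, k=10)
        assert not t.flags["homopolymer"]

    def test_truncated_flank_passes_with_warning(self, caplog):
        g = GenomeAssembly({"chr1": "AAAAA" + "CGTAGCTAGCCGTAGCTAGCCGTAGCTAGCCGTAGCTAGCCGTAGCTAGC"})
        v = VariantRecord("chr1", 6, "C", "CT")
        with caplog.at_level("WARNING"):
            (t,) = filter_homopolymer([v], g, k=10)
        assert t.flags["homopolymer"]
        assert "truncated" in caplog.text


class TestGcFilter:
    def _case(self, n_gc_left, n_gc_right):
        left = ("G" * n_gc_left + "A" * 50)[:50]
        right = ("C" * n_gc_right + "T" * 50)[:50]
        seq = "ACGTC" * 20 + left + "AT" + right + "ACGTC" * 20
        g = GenomeAssembly({"chr1": seq})
        return g, VariantRecord("chr1", 151, "AT", "A")

    def test_all_gc_flanks_fail_high(self):
        g, v = self._case(50, 50)
        (t,) = filter_gc([v], g)
        assert not t.flags["gc"]
        assert ">" in t.fail_reason["gc"]

    def test_half_gc_passes(self):
        g, v = self._case(50, 0)
        (t,) = filter_gc([v], g)
        assert t.flags["gc"]

    def test_exact_bounds_pass_strict_inequality(self):
        g, v = self._case(40, 20)        # exactly 0.60
        (t,) = filter_gc([v], g)
        assert t.flags["gc"]
        g, v = self._case(20, 0)         # exactly 0.20
        (t,) = filter_gc([v], g)
        assert t.flags["gc"]
        g, v = self._case(41, 20)        # 0.61 fails
        (t,) = filter_gc([v], g)
        assert not t.flags["gc"]
        g, v = self._case(19, 0)         # 0.19 fails
        (t,) = filter_gc([v], g)
        assert not t.flags["gc"]

    def test_n_bases_excluded_from_both_sides_of_ratio(self):
        # 25 G + 25 N upstream, 50 A downstream -> 25/(100-25) = 1/3
        seq = "ACGTC" * 20 + "G" * 25 + "N" * 25 + "AT" + "A" * 50 + "ACGTC" * 20
        g = GenomeAssembly({"chr1": seq})
        (t,) = filter_gc([VariantRecord("chr1", 151, "AT", "A")], g)
        assert t.flags["gc"]


class TestProximity:
    def test_variant_inside_site_distance_zero(self):
        site = make_site(start=1000)
        v = VariantRecord("chr1", 1010, "AAA", "A")
        kept = annotate_proximity([v], [site])
        assert kept == [(v, site, 0)]

    def test_500_kept_501_dropped(self):
        site = make_site(start=1000)
        at_500 = VariantRecord("chr1", 499, "AT", "A")   # interval [498,500)
        at_501 = VariantRecord("chr1", 498, "AT", "A")   # interval [497,499)
        kept = annotate_proximity([at_500, at_501], [site], proximity_bp=500)
        assert [(v.pos, d) for v, _, d in kept] == [(499, 500)]

    def test_no_site_on_chromosome_dropped(self):
        v = VariantRecord("chr2", 100, "AT", "A")
        assert annotate_proximity([v], [make_site()]) == []

    def test_tie_broken_to_smaller_coordinate(self):
        near = make_site(start=1000)
        far = make_site(start=1040)
        v = VariantRecord("chr1", 1030, "AT", "A")   # 9 bp from both edges
        (_, site, d) = annotate_proximity([v], [far, near])[0]
        assert d == 9 and site.start == 1000

    def test_cutsite_anchor_configurable(self):
        site = make_site(start=1000, strand="+")     # cut at 1017
        v = VariantRecord("chr1", 1118, "AT", "A")   # interval [1117,1119)
        _, d_proto = nearest_site(v, [site], anchor="protospacer")
        _, d_cut = nearest_site(v, [site], anchor="cutsite")
        assert (d_proto, d_cut) == (97, 100)

    def test_matches_all_pairs_oracle(self, rng):
        sites = [make_site(start=int(s)) for s in rng.integers(0, 20000, 30)]
        for p in rng.integers(1, 20000, size=100):
            v = VariantRecord("chr1", int(p), "AAAA", "A")
            _, d = nearest_site(v, sites)
            assert d == all_pairs_min_distance(
                v.interval, [(s.start, s.end) for s in sites]
            )


class TestCascade:
    def _setup(self):
        genome = generate_genome({"chr1": 30_000}, seed=31)
        sites = [make_site(start=10_000)]
        mask = MaskSet({"chr1": [(20_000, 20_500)]}, label="repeat")
        g = genome.sequences["chr1"]

        def indel_at(pos0):
            ref = g[pos0] + g[pos0 + 1]
            return normalize_indel(
                VariantRecord("chr1", pos0 + 1, ref, ref[0]), genome
            )

        clean = indel_at(10_100)          # near site, clean context
        shared = indel_at(10_200)
        far = indel_at(25_000)
        # SNV beside the clean indel so every context filter passes for it
        snv = VariantRecord("chr1", 10_111, g[10_110],
                            "A" if g[10_110] != "A" else "C")
        mutant = [clean, shared, far, snv]
        controls = [[VariantRecord(*shared.key)]]
        return mutant, controls, [], mask, genome, sites

    def test_survivors_and_traces(self):
        mutant, controls, db, mask, genome, sites = self._setup()
        survivors, traces = run_filter_cascade(
            mutant, controls, db, mask, genome, sites
        )
        assert [v.pos for v, _, _ in survivors] == [mutant[0].pos]
        assert len(traces) == len(mutant)
        by_pos = {t.variant.pos: t for t in traces}
        assert by_pos[mutant[1].pos].failed_filters == ("privacy",)
        assert by_pos[mutant[2].pos].failed_filters == ("proximity",)
        assert by_pos[mutant[3].pos].failed_filters == ("vtype",)

    def test_trace_conservation(self):
        mutant, controls, db, mask, genome, sites = self._setup()
        survivors, traces = run_filter_cascade(
            mutant, controls, db, mask, genome, sites
        )
        n_failed = sum(1 for t in traces if t.failed_filters)
        assert len(survivors) + n_failed == len(mutant)

    def test_survivor_set_order_independent(self):
        """The cascade is an intersection of pure predicates: applying the
        five filters in any order yields the same survivor set."""
        mutant, controls, db, mask, genome, sites = self._setup()
        params = FilterParams()
        _, traces = run_filter_cascade(
            mutant, controls, db, mask, genome, sites, params
        )
        reference = {
            t.variant.key for t in traces
            if all(t.flags[f] for f in FILTER_ORDER) and t.flags["vtype"]
        }
        for order in itertools.permutations(FILTER_ORDER):
            pool = [v for v in mutant if v.is_indel]
            for stage in order:
                keep = []
                for v in pool:
                    t = next(x for x in traces if x.variant.key == v.key)
                    if t.flags[stage]:
                        keep.append(v)
                pool = keep
            assert {v.key for v in pool} == reference

    def test_privacy_soundness_post_hoc(self):
        mutant, controls, db, mask, genome, sites = self._setup()
        survivors, _ = run_filter_cascade(
            mutant, controls, db, mask, genome, sites
        )
        control_keys = {v.key for cs in controls for v in cs} | {
            v.key for v in db
        }
        assert all(v.key not in control_keys for v, _, _ in survivors)
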