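"""Normalized frequency, abundance, species presence, phosphosite
containment, sequence identity and conservation tiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrekit import enrichment as en
from nrekit import motif as mo
from nrekit.model import NRESegment, PhosphoSite, SegmentKind
from nrekit.motif import MotifMatch


def _seg(seq, pid="P", cls="c", species="sp1", start=1, domain=False):
    return NRESegment(protein_id=pid, start=start, end=start + len(seq) - 1,
                      sequence=seq, kind=SegmentKind.NKE, class_label=cls,
                      species=species, has_internal_domain=domain)


def _match(pid, start, width, motif_id="m"):
    return MotifMatch(motif_id=motif_id, protein_id=pid, start=start,
                      end=start + width - 1, score=10.0, p_value=1e-4)


# Published per-class occurrence counts with their printed normalized
# frequencies (corpus of 457,685 domain-free NRE segments).
TABLE_ROWS = [
    ("LRR-VI-2", 3532, 5265, 3532, 58.3),
    ("LRR-Xb-1", 3183, 7026, 4333, 21.7),
    ("PERK-2", 2075, 4546, 2082, 45.8),
    ("PERK-2", 2719, 4546, 2729, 60.0),
    ("PERK-2", 3134, 4546, 3144, 69.2),
    ("LRR-IV", 1220, 2096, 1221, 127.0),
    ("RLCK-XII-2", 1210, 1678, 1579, 150.7),
]
NTOTAL_PUBLISHED = 457_685


class TestNormalizedFrequency:
    @pytest.mark.parametrize("cls,nm,nc,p,expected", TABLE_ROWS)
    def test_published_rows_reproduce_to_printed_decimal(self, cls, nm, nc, p, expected):
        f = en.normalized_frequency(nm, p, nc, NTOTAL_PUBLISHED)
        assert round(f, 1) == expected

    def test_identity_case(self):
        assert en.normalized_frequency(1, 1, 1, 1) == pytest.approx(1.0)

    def test_zero_total_occurrences_signaled(self):
        with pytest.raises(ValueError):
            en.normalized_frequency(0, 0, 10, 100)

    @given(
        nm=st.integers(0, 1000),
        extra=st.integers(0, 1000),
        nc=st.integers(1, 5000),
        headroom=st.integers(0, 5000),
    )
    @settings(max_examples=300, derandomize=True)
    def test_product_and_factored_forms_agree(self, nm, extra, nc, headroom):
        p = nm + extra
        if p == 0:
            return
        ntotal = nc + headroom
        f = (nm * nm * ntotal) / (p * nc * nc)
        ac = nc / ntotal
        f_factored = (nm / (p * ac)) * (nm / nc)
        assert f == pytest.approx(f_factored, abs=1e-9, rel=1e-9)
        assert en.normalized_frequency(nm, p, nc, ntotal) == pytest.approx(f)

    @given(nm=st.integers(1, 99), nc=st.integers(1, 500), headroom=st.integers(0, 500))
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_in_nm(self, nm, nc, headroom):
        p, ntotal = 100, nc + headroom
        f1 = en.normalized_frequency(nm, p, nc, ntotal)
        f2 = en.normalized_frequency(nm + 1, p, nc, ntotal)
        assert f2 > f1


class TestClassCounts:
    def test_abundance_scores(self):
        segs = (
            [_seg("A" * 30, f"a{i}", "c1") for i in range(2)]
            + [_seg("A" * 30, f"b{i}", "c2") for i in range(3)]
            + [_seg("A" * 30, f"c{i}", "c3") for i in range(5)]
        )
        counts = en.count_classes(segs)
        assert [c.Nc for c in counts] == [2, 3, 5]
        assert all(c.Ntotal == 10 for c in counts)
        assert [c.Ac for c in counts] == pytest.approx([0.2, 0.3, 0.5])

    def test_domain_bearing_segments_excluded(self):
        segs = [_seg("A" * 30, f"p{i}", "c1") for i in range(9)]
        segs.append(_seg("A" * 30, "p9", "c1", domain=True))
        counts = en.count_classes(segs)
        assert counts[0].Ntotal == 9

    def test_single_class_abundance_one(self):
        counts = en.count_classes([_seg("A" * 30)])
        assert counts[0].Ac == 1.0


class TestEnrichAndFilter:
    def _null_corpus(self, n_per_class=5):
        """Every segment of every class carries exactly one occurrence."""
        segs, matches = [], []
        for cls in ("c1", "c2", "c3"):
            for i in range(n_per_class):
                pid = f"{cls}_{i}"
                segs.append(_seg("A" * 30, pid, cls))
                matches.append(_match(pid, 3, 10))
        return segs, matches

    def test_uniform_one_per_segment_gives_f_exactly_one(self):
        segs, matches = self._null_corpus()
        results = en.enrich(matches, segs)
        for r in results:
            assert r.F == pytest.approx(1.0, abs=1e-9)

    def test_occurrences_conserved_across_classes(self):
        segs, matches = self._null_corpus()
        results = en.enrich(matches, segs)
        by_motif = {}
        for r in results:
            by_motif.setdefault(r.motif_id, []).append(r)
        for rows in by_motif.values():
            assert sum(r.Nm for r in rows) == rows[0].P

    def test_single_class_planting_overrepresents_that_class(self):
        segs = [_seg("A" * 30, f"p{i}", "c1") for i in range(10)]
        segs += [_seg("A" * 30, f"q{i}", "c2") for i in range(10)]
        matches = [_match(f"p{i}", 3, 10) for i in range(8)]
        matches.append(_match("q0", 3, 10))  # one chance match elsewhere
        results = {r.class_label: r for r in en.enrich(matches, segs)}
        assert results["c1"].F > 1.0
        assert results["c2"].F < 1.0

    def test_filter_is_strictly_greater(self):
        segs, matches = self._null_corpus()
        results = en.enrich(matches, segs)  # all F == 1.0 exactly
        assert en.filter_overrepresented(results, 1.0) == []

    def test_empty_input(self):
        assert en.filter_overrepresented([], 1.0) == []

    def test_species_presence_counts_distinct(self):
        segs = [_seg("A" * 30, "p1", species="X"), _seg("A" * 30, "p2", species="X"),
                _seg("A" * 30, "p3", species="Y")]
        matches = [_match("p1", 1, 5), _match("p2", 1, 5), _match("p3", 1, 5)]
        assert en.species_presence(matches, segs) == {"m": 2}
        assert en.species_presence([], segs) == {}


class TestPhosphositeContainment:
    def test_interior_site_contained_with_offset(self):
        seg = _seg("A" * 60, "p1", start=300)
        match = _match("p1", 24, 21)  # protein coords [323, 343]
        site = PhosphoSite("p1", 330, "S")
        out = en.map_phosphosites([match], [site], [seg])
        assert len(out) == 1 and out[0].motif_offset == 8

    def test_boundary_site_inclusive(self):
        seg = _seg("A" * 60, "p1", start=300)
        match = _match("p1", 24, 21)
        out = en.map_phosphosites([match], [PhosphoSite("p1", 323, "S")], [seg])
        assert len(out) == 1 and out[0].motif_offset == 1

    def test_site_past_end_not_contained(self):
        seg = _seg("A" * 60, "p1", start=300)
        match = _match("p1", 24, 21)
        out = en.map_phosphosites([match], [PhosphoSite("p1", 344, "S")], [seg])
        assert out == []

    def test_planted_sites_land_at_declared_offsets(self, corpus1000, analyzed1000):
        """Generator-emitted sites map back to their class's motif offsets."""
        _, _, trimmed, _ = analyzed1000
        offsets_by_class = {s.name: set(s.phospho_offsets)
                            for s in corpus1000.params.classes}
        seg_by_id = {s.protein_id: s for s in trimmed}
        sites = [PhosphoSite(r["protein_id"], r["position"], r["residue"])
                 for r in corpus1000.phospho_rows]
        matches = []
        for rec in corpus1000.records:
            t = corpus1000.truth[rec.id]
            if t.motif_interval is None or rec.id not in seg_by_id:
                continue
            seg = seg_by_id[rec.id]
            s = t.motif_interval[0] - seg.start + 1
            matches.append(_match(rec.id, s, t.motif_interval[1] - t.motif_interval[0] + 1,
                                  motif_id=rec.class_label))
        contained = en.map_phosphosites(matches, sites, trimmed)
        assert contained
        for cs in contained:
            assert cs.motif_offset in offsets_by_class[cs.motif_id]


class TestSequenceIdentity:
    @pytest.mark.parametrize(
        "consensus,word,expected",
        [
            ("FSYEEL", "FSYEEL", 1.0),
            ("FSYEEL", "FSYDEL", 5 / 6),
            ("NGB", "NGD", 1.0),
            ("NGB", "NGN", 1.0),
            ("NGB", "NGA", 2 / 3),
        ],
    )
    def test_identity_values(self, consensus, word, expected):
        assert en.sequence_identity(consensus, word) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            en.sequence_identity("AB", "ABC")


class TestConservationSummary:
    def _setup(self, words, site_offset=None, consensus_override=None):
        bg = np.full(20, 0.05)
        m = mo.build_pwm(words, bg, motif_id="m")
        if consensus_override:
            m.consensus = consensus_override
        segs = [_seg(w, f"p{i}") for i, w in enumerate(words)]
        matches = [_match(f"p{i}", 1, len(words[0])) for i in range(len(words))]
        sites = []
        if site_offset is not None:
            sites = [en.ContainedSite("p0", site_offset, "S", "m", site_offset)]
        return m, matches, segs, sites

    def test_high_tier(self):
        m, matches, segs, _ = self._setup(["FSYEELKKQQ"] * 10)
        c = en.conservation_summary(m, matches, segs, [])
        assert c.mean_SI == pytest.approx(100.0)
        assert c.tier == "high"

    @pytest.mark.parametrize(
        "word,expected_tier",
        [
            ("AAAAAAAAAA", "high"),      # 100%
            ("AAAAAAAADD", "moderate"),  # exactly 80% falls in moderate
            ("AAAAADDDDD", "moderate"),  # exactly 50% falls in moderate
            ("ADDDDDDDDD", "low"),       # 10%
        ],
    )
    def test_tier_boundaries(self, word, expected_tier):
        bg = np.full(20, 0.05)
        m = mo.build_pwm(["AAAAAAAAAA"] * 10, bg, motif_id="m")
        segs = [_seg(word, "p0")]
        matches = [_match("p0", 1, 10)]
        c = en.conservation_summary(m, matches, segs, [])
        assert c.tier == expected_tier

    def test_sty_rule_excludes_non_phosphorylatable_offset(self):
        words = ["FGGEELKKQQ"] * 10
        m, matches, segs, _ = self._setup(words)
        site = en.ContainedSite("p0", 2, "S", "m", 2)  # consensus[2] == 'G'
        c = en.conservation_summary(m, matches, segs, [site])
        assert not c.sty_ok

    def test_sty_rule_accepts_serine_offset(self):
        words = ["FSYEELKKQQ"] * 10
        m, matches, segs, sites = self._setup(words, site_offset=2)
        c = en.conservation_summary(m, matches, segs, sites)
        assert c.sty_ok

    def test_no_matches_returns_none(self):
        m, _, segs, _ = self._setup(["FSYEELKKQQ"] * 10)
        assert en.conservation_summary(m, [], segs, []) is None


class TestBuildReport:
    def test_rows_sorted_by_mean_si_with_offset_cell(self):
        bg = np.full(20, 0.05)
        m1 = mo.build_pwm(["FSYEELKKQQ"] * 5, bg, motif_id="m1")
        m2 = mo.build_pwm(["KKKKKKKKKK"] * 5, bg, motif_id="m2")
        enr = [
            en.EnrichmentResult("m1", "LRR-VI-2", 5, 5, 10, 20, 2.0, 3),
            en.EnrichmentResult("m2", "PERK-2", 5, 5, 10, 20, 2.0, 2),
        ]
        cons = {
            "m1": en.ConservationResult("m1", [1.0], 90.0, "high",
                                        [en.ContainedSite("p", 6, "S", "m1", 6),
                                         en.ContainedSite("q", 9, "S", "m1", 9)],
                                        True),
            "m2": en.ConservationResult("m2", [0.6], 60.0, "moderate", [], True),
        }
        rows = en.build_report(enr, cons, [m1, m2])
        assert [r["MeanSI"] for r in rows] == [90.0, 60.0]
        assert rows[0]["PhosphoSites"] == "6;9"

    def test_sty_failing_motif_excluded(self):
        bg = np.full(20, 0.05)
        m1 = mo.build_pwm(["FGGEELKKQQ"] * 5, bg, motif_id="m1")
        enr = [en.EnrichmentResult("m1", "c", 5, 5, 10, 20, 2.0, 1)]
        cons = {"m1": en.ConservationResult("m1", [1.0], 90.0, "high", [], False)}
        assert en.build_report(enr, cons, [m1]) == []

    def test_deterministic_rerun(self):
        bg = np.full(20, 0.05)
        m1 = mo.build_pwm(["FSYEELKKQQ"] * 5, bg, motif_id="m1")
        enr = [en.EnrichmentResult("m1", "c", 5, 5, 10, 20, 2.0, 1)]
        cons = {"m1": en.ConservationResult("m1", [1.0], 90.0, "high", [], True)}
        assert en.build_report(enr, cons, [m1]) == en.build_report(enr, cons, [m1])
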