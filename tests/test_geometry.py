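"""Transcript geometry against brute-force per-base oracles: genomic
projection round trips, metatranscript scaling, junction distances and
chromosome window densities."""

from __future__ import annotations

import numpy as np
import pytest

from m5cscope.geometry import (
    genome_to_transcript,
    genomic_window_density,
    junction_distance,
    junction_distance_histogram,
    junction_zone_classification,
    metagene_coordinate,
    metagene_profile,
    signed_junction_distance,
    transcript_to_genome,
)
from m5cscope.io_model import TranscriptCatalog, TranscriptModel, ValidationError
from conftest import make_site_table, random_transcript_model, walk_genomic_bases

K = "AAAACAAAA"


class TestGenomicProjection:
    def test_plus_strand_first_base(self):
        m = TranscriptModel("t", "g", "chr1", "+", ((100, 200),))
        assert transcript_to_genome(m, 0) == ("chr1", 100, "+")

    def test_minus_strand_first_base(self):
        m = TranscriptModel("t", "g", "chr1", "-", ((300, 400), (100, 200)))
        assert transcript_to_genome(m, 0) == ("chr1", 399, "-")

    def test_round_trip_and_per_base_walk(self, rng):
        for i in range(50):
            m = random_transcript_model(rng, f"t{i}")
            walk = walk_genomic_bases(m)
            for _ in range(10):
                p = int(rng.integers(0, m.length))
                _, g, _ = transcript_to_genome(m, p)
                assert g == walk[p]
                assert genome_to_transcript(m, g) == p

    def test_bijection_over_full_domain(self, rng):
        m = random_transcript_model(rng, "t")
        images = {transcript_to_genome(m, p)[1] for p in range(m.length)}
        assert len(images) == m.length
        assert images == set(walk_genomic_bases(m))

    def test_out_of_range_position_rejected(self):
        m = TranscriptModel("t", "g", "chr1", "+", ((100, 200),))
        with pytest.raises(ValidationError):
            transcript_to_genome(m, 100)


def region_label_oracle(model, p):
    """Brute-force region label via per-base comparison with the CDS span."""
    if p < model.cds_start_t:
        return "utr5"
    if p < model.cds_end_t:
        return "cds"
    return "utr3"


class TestMetagene:
    def model(self, u5=100, c=300, u3=200):
        return TranscriptModel(
            "t", "g", "chr1", "+", ((0, u5 + c + u3),), cds_start_t=u5, cds_end_t=u5 + c
        )

    def test_mid_cds_coordinate(self):
        assert metagene_coordinate(self.model(), 250) == pytest.approx(1.5)

    def test_first_cds_base_maps_to_one(self):
        assert metagene_coordinate(self.model(), 100) == 1.0
        assert metagene_coordinate(self.model(), 400) == 2.0  # first 3'UTR base

    def test_noncoding_returns_none(self):
        m = TranscriptModel("t", "g", "chr1", "+", ((0, 100),))
        assert metagene_coordinate(m, 50) is None

    def test_region_assignment_matches_per_base_walk(self, rng):
        for i in range(40):
            m = random_transcript_model(rng, f"t{i}", coding=True)
            if not m.is_coding:  # very short models stay non-coding
                continue
            for _ in range(5):
                p = int(rng.integers(0, m.length))
                x = metagene_coordinate(m, p)
                region = ("utr5", "cds", "utr3")[min(int(x), 2)]
                assert region == region_label_oracle(m, p)
                assert 0 <= x < 3

    def test_profile_mass_conservation(self, simple_catalog, rng):
        rows = [("tx1", int(p), K, 10, 0.5, 1.0) for p in rng.integers(0, 600, 50)]
        rows = list({r[:2]: r for r in rows}.values())  # dedup positions
        rows.append(("tx2", 10, K, 10, 0.5, 1.0))  # non-coding, skipped
        profile = metagene_profile(make_site_table(rows), simple_catalog, n_bins=30)
        assert profile.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert profile.n_mapped == len(rows) - 1
        assert profile.n_noncoding == 1

    def test_profile_region_mass_matches_oracle(self, simple_catalog, rng):
        positions = sorted(set(int(p) for p in rng.integers(0, 600, 80)))
        rows = [("tx1", p, K, 10, 0.5, 1.0) for p in positions]
        profile = metagene_profile(make_site_table(rows), simple_catalog, n_bins=90)
        model = simple_catalog["tx1"]
        labels = [region_label_oracle(model, p) for p in positions]
        for region, lo, hi in (("utr5", 0, 30), ("cds", 30, 60), ("utr3", 60, 90)):
            expected = labels.count(region) / len(positions)
            assert profile.density[lo:hi].sum() == pytest.approx(expected, abs=1e-9)


class TestJunctionDistance:
    def model_300_200_500(self):
        return TranscriptModel(
            "t", "g", "chr1", "+", ((0, 300), (1000, 1200), (2000, 2500))
        )

    def test_distance_between_junctions(self):
        assert junction_distance(self.model_300_200_500(), 350) == 50

    def test_junction_coordinate_has_distance_zero(self):
        m = self.model_300_200_500()
        assert junction_distance(m, 300) == 0
        assert junction_distance(m, 500) == 0

    def test_single_exon_undefined(self):
        m = TranscriptModel("t", "g", "chr1", "+", ((0, 100),))
        assert junction_distance(m, 50) is None

    def test_zero_iff_junction(self, rng):
        m = random_transcript_model(rng, "t")
        junctions = set(np.cumsum([e - s for s, e in m.exons])[:-1])
        for p in range(m.length):
            d = junction_distance(m, p)
            if junctions:
                assert (d == 0) == (p in junctions)

    def test_matches_exhaustive_min(self, rng):
        for i in range(30):
            m = random_transcript_model(rng, f"t{i}")
            junctions = list(np.cumsum([e - s for s, e in m.exons])[:-1])
            for _ in range(10):
                p = int(rng.integers(0, m.length))
                expected = min((abs(p - j) for j in junctions), default=None)
                assert junction_distance(m, p) == expected
                if junctions:
                    signed = min((p - j for j in junctions), key=abs)
                    assert abs(signed_junction_distance(m, p)) == expected

    def test_histogram_mass_accounting(self, simple_catalog, rng):
        rows = [("tx1", int(p), K, 10, 0.5, 1.0) for p in range(0, 600, 7)]
        rows += [("tx2", p, K, 10, 0.5, 1.0) for p in (1, 2)]  # single-exon
        table = make_site_table(rows)
        hist = junction_distance_histogram(table, simple_catalog)
        assert hist.counts.sum() + hist.n_undefined == len(rows)
        assert hist.n_undefined == 2


class TestJunctionZones:
    def make_catalog_and_sites(self, distances):
        """One long two-exon transcript; sites placed at controlled
        distances downstream of the junction at 1000."""
        m = TranscriptModel("t", "g", "chr1", "+", ((0, 1000), (5000, 7000)))
        rows = [("t", 1000 + d, K, 10, 0.5, 1.0) for d in distances]
        return TranscriptCatalog({"t": m}), make_site_table(rows)

    def test_boundary_conventions(self):
        cat, table = self.make_catalog_and_sites([100, 101, 400, 401])
        zones = junction_zone_classification(table, cat).set_index("zone")["count"]
        assert zones["proximal"] == 1  # d = 100, closed boundary
        assert zones["flank"] == 2     # 101 and 400
        assert zones["distal"] == 1    # 401

    def test_hand_enumerated_zone_counts(self):
        distances = [0, 5, 50, 100, 150, 250, 400, 500, 650, 800] * 2
        cat, table = self.make_catalog_and_sites(distances)
        zones = junction_zone_classification(table, cat).set_index("zone")["count"]
        assert zones["proximal"] == sum(1 for d in distances if d <= 100)
        assert zones["flank"] == sum(1 for d in distances if 100 < d <= 400)
        assert zones["distal"] == sum(1 for d in distances if d > 400)
        assert zones[["proximal", "flank", "distal"]].sum() == len(distances)


class TestWindowDensity:
    def catalog(self):
        m1 = TranscriptModel("t1", "g1", "chr1", "+", ((0, 60_000_000),))
        m2 = TranscriptModel("t2", "g2", "chr2", "+", ((0, 60_000_000),))
        return TranscriptCatalog({"t1": m1, "t2": m2})

    def test_half_open_window_edges(self):
        cat = self.catalog()
        t = make_site_table([("t1", 26_999_999, K, 10, 0.5, 1.0)])
        out = genomic_window_density(t, cat)
        assert out.iloc[0]["window_index"] == 0
        t = make_site_table([("t1", 27_000_000, K, 10, 0.5, 1.0)])
        out = genomic_window_density(t, cat)
        assert out.iloc[0]["window_index"] == 1

    def test_counts_match_floor_division_oracle(self, rng):
        cat = self.catalog()
        rows = []
        for i in range(50):
            tid = "t1" if rng.random() < 0.5 else "t2"
            rows.append((tid, int(rng.integers(0, 60_000_000)), K, 10, 0.5, 1.0))
        rows = list({(r[0], r[1]): r for r in rows}.values())
        out = genomic_window_density(make_site_table(rows), cat, window=27_000_000)
        expected: dict[tuple[str, int], int] = {}
        for tid, pos, *_ in rows:
            chrom = "chr1" if tid == "t1" else "chr2"
            key = (chrom, pos // 27_000_000)
            expected[key] = expected.get(key, 0) + 1
        got = {
            (r.chromosome, r.window_index): r["count"] for _, r in out.iterrows()
        }
        assert got == expected
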