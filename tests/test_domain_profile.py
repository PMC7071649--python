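import math

import numpy as np
import pytest

from bhlhsurvey.domain_profile import (
    AMINO_ACIDS,
    DomainHit,
    SiteConfig,
    annotate_regions,
    build_profile,
    classify_binding,
    conservation_profile,
    scan_domain,
    uniform_background,
)
from bhlhsurvey.sequence_io import ProteinRecord
from bhlhsurvey.synthetic import gen_proteome

from oracles import oracle_scan


def identity_hit(pid: str, n: int = 55, offset: int = 0) -> DomainHit:
    cmap = {c: c + offset for c in range(1, n + 1)}
    return DomainHit(protein_id=pid, start=1 + offset, end=n + offset,
                     score=100.0, column_map=cmap)


class TestBuildProfile:
    def test_background_column_scores_zero(self):
        # 20 sequences, one of each residue in a column: equals uniform bg
        seqs = [a * 3 for a in AMINO_ACIDS]
        prof = build_profile(seqs, pseudocount=1.0)
        for a in AMINO_ACIDS:
            assert prof.score(1, a) == pytest.approx(0.0, abs=1e-12)

    def test_conserved_column_sign(self):
        prof = build_profile(["LLL", "LLL", "LLL"], pseudocount=0.5)
        assert prof.score(2, "L") > 0
        for a in AMINO_ACIDS.replace("L", ""):
            assert prof.score(2, a) < 0

    def test_column_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=12)) for _ in range(6)]
        prof = build_profile(seqs, pseudocount=2.0)
        for p in prof.probs:
            assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            build_profile(["AAA", "AA"])

    def test_zero_background_rejected(self):
        bg = uniform_background()
        bg["W"] = 0.0
        with pytest.raises(ValueError, match="background"):
            build_profile(["AAA", "CCC"], background=bg)


class TestScanDomain:
    def test_planted_consensus_found_at_offset(self, profile):
        rng = np.random.default_rng(11)
        flank = "".join(rng.choice(list(AMINO_ACIDS), size=100))
        flank2 = "".join(rng.choice(list(AMINO_ACIDS), size=80))
        seq = flank + profile.consensus() + flank2
        hit = scan_domain(ProteinRecord("p", seq), profile, min_score=50)
        assert hit is not None
        assert hit.start == 101 and hit.end == 155
        assert hit.n_gaps == 0

    def test_modal_consensus_scores_columnwise_maximum(self, profile):
        hit = scan_domain(
            ProteinRecord("c", profile.consensus()), profile, min_score=0
        )
        assert hit.score == pytest.approx(profile.max_score(), abs=1e-9)

    def test_random_background_excluded_at_high_cutoff(self, profile):
        rng = np.random.default_rng(12)
        for i in range(3):
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=300))
            assert scan_domain(ProteinRecord(f"r{i}", seq), profile,
                               min_score=50.0) is None

    def test_column_map_strictly_increasing(self, profile):
        recs, _ = gen_proteome({"G-box": 3}, seed=9)
        for r in recs:
            hit = scan_domain(r, profile, min_score=50)
            mapped = [v for v in hit.column_map.values() if v is not None]
            assert mapped == sorted(mapped)
            assert len(set(mapped)) == len(mapped)

    @pytest.mark.parametrize("case_seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, case_seed):
        """DP scan equals brute-force enumeration of all glocal alignments
        on tiny profiles, including score, start, gap count and map."""
        rng = np.random.default_rng(100 + case_seed)
        seed_seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=6))
                     for _ in range(4)]
        prof = build_profile(seed_seqs, pseudocount=1.0,
                             gap_open=2.0, gap_extend=0.5)
        core = list(seed_seqs[0])
        if case_seed % 2:
            del core[2]  # force a deletion-favouring instance
        seq = ("".join(rng.choice(list(AMINO_ACIDS), size=4))
               + "".join(core)
               + "".join(rng.choice(list(AMINO_ACIDS), size=4)))
        hit = scan_domain(ProteinRecord("t", seq), prof, min_score=-1e9)
        score, start, gaps, cmap = oracle_scan(seq, prof)
        assert hit.score == score
        assert hit.start == start
        assert hit.n_gaps == gaps
        assert hit.column_map == cmap


class TestRegionsAndConservation:
    def test_region_boundaries(self, site_config):
        hit = identity_hit("p")
        annotate_regions(hit, site_config)
        assert hit.region_of_column[1] == "basic"
        assert hit.region_of_column[15] == "basic"
        assert hit.region_of_column[16] == "helix1"
        assert hit.region_of_column[42] == "loop"
        assert hit.region_of_column[55] == "helix2"

    def test_overlapping_boundaries_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            SiteConfig(
                regions={"basic": (1, 16), "helix1": (16, 28),
                         "loop": (29, 42), "helix2": (43, 55)},
                basic_residue_set=frozenset("RKH"),
                ebox_sites=[(13, frozenset("E"))],
                gbox_sites=[(9, frozenset("HK"))],
            )

    @pytest.mark.parametrize("n_same,in70,in90", [
        (7, False, False),   # 70% exactly: strictly-above rule keeps it out
        (8, True, False),
        (10, True, True),
    ])
    def test_conservation_strict_thresholds(self, n_same, in70, in90):
        records, hits = {}, []
        for i in range(10):
            res = "L" if i < n_same else "AVIMF"[i % 5]
            records[f"p{i}"] = ProteinRecord(f"p{i}", res * 5)
            hits.append(identity_hit(f"p{i}", n=5))
        prof = conservation_profile(hits, records)
        assert prof.percent[1] == pytest.approx(10.0 * n_same)
        assert (1 in prof.flags70) is in70
        assert (1 in prof.flags90) is in90

    def test_all_gap_column_excluded(self):
        records = {"a": ProteinRecord("a", "LLLL"), "b": ProteinRecord("b", "LLLL")}
        hits = []
        for pid in records:
            cmap = {1: 1, 2: 2, 3: None, 4: 3, 5: 4}
            hits.append(DomainHit(pid, 1, 4, 1.0, cmap))
        prof = conservation_profile(hits, records)
        assert 3 not in prof.percent
        assert 3 not in prof.flags70 and 3 not in prof.flags90


class TestClassifyBinding:
    def make(self, seq55: str, site_config):
        rec = ProteinRecord("x", seq55)
        return classify_binding(identity_hit("x", len(seq55)), rec, site_config)

    def base_domain(self, profile):
        return list(profile.consensus())

    def test_low_basic_count_dominates(self, profile, site_config):
        dom = self.base_domain(profile)
        # strip basic region down to 4 basic residues; keep all sites intact
        basics = [c for c in site_config.basic_region_columns
                  if dom[c - 1] in site_config.basic_residue_set
                  and c not in {c2 for c2, _ in site_config.ebox_sites}
                  and c not in {c2 for c2, _ in site_config.gbox_sites}]
        keep_sites = sum(
            1 for c in site_config.basic_region_columns
            if dom[c - 1] in site_config.basic_residue_set and c not in basics
        )
        for c in basics[max(0, 4 - keep_sites):]:
            dom[c - 1] = "S"
        call = self.make("".join(dom), site_config)
        assert call.basic_count == 4
        assert call.category == "atypical"

    def test_all_sites_present_is_gbox(self, profile, site_config):
        call = self.make(profile.consensus(), site_config)
        assert call.category == "G-box"
        assert call.basic_count >= 5

    def test_broken_gbox_site_is_ebox(self, profile, site_config):
        dom = self.base_domain(profile)
        gb_only = [c for c, _ in site_config.gbox_sites
                   if c not in {c2 for c2, _ in site_config.ebox_sites}]
        dom[gb_only[0] - 1] = "A"
        call = self.make("".join(dom), site_config)
        assert call.category == "E-box"

    def test_broken_ebox_site_is_non_ebox(self, profile, site_config):
        dom = self.base_domain(profile)
        col = max(c for c, _ in site_config.ebox_sites)
        dom[col - 1] = "G"
        call = self.make("".join(dom), site_config)
        assert call.category == "non-E-box"

    def test_gap_at_site_counts_as_absent(self, profile, site_config):
        seq = profile.consensus()
        cmap = {c: c for c in range(1, 56)}
        col = max(c for c, _ in site_config.ebox_sites)
        cmap[col] = None
        hit = DomainHit("x", 1, 55, 100.0, cmap)
        call = classify_binding(hit, ProteinRecord("x", seq), site_config)
        assert not call.ebox_sites_present
        assert call.category == "non-E-box"

    def test_invariant_to_non_site_residues(self, profile, site_config):
        dom = self.base_domain(profile)
        ref = self.make("".join(dom), site_config).category
        protected = (set(site_config.basic_region_columns)
                     | {c for c, _ in site_config.ebox_sites}
                     | {c for c, _ in site_config.gbox_sites})
        for col in range(1, 56):
            if col in protected:
                continue
            mutated = list(dom)
            mutated[col - 1] = "W"
            assert self.make("".join(mutated), site_config).category == ref

    def test_categories_partition_input(self, profile, site_config):
        recs, truth = gen_proteome(
            {"G-box": 5, "E-box": 4, "non-E-box": 3, "atypical": 3}, seed=21
        )
        cats = []
        for r in recs:
            hit = scan_domain(r, profile, min_score=site_config.min_score)
            cats.append(classify_binding(hit, r, site_config).category)
        counts = {c: cats.count(c) for c in set(cats)}
        assert sum(counts.values()) == len(recs)
        typical = sum(counts.get(c, 0) for c in ("G-box", "E-box", "non-E-box"))
        assert typical + counts.get("atypical", 0) == len(recs)
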