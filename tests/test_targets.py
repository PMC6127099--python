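"""3'UTR inference, seed scanning, site counting and the length ANOVA."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smallrna_traj.seqs import revcomp
from smallrna_traj.targets import (
    Seed,
    SeedSite,
    UtrRecord,
    count_sites,
    extract_utr_sequence,
    infer_three_prime_utrs,
    map_site_position,
    scan_seed_sites,
    stage_target_profile,
    utr_length_anova,
)

from .oracles import brute_utr_bases, gene_model_gff, naive_scan, random_gene_model


def _gff(tmp_path, text):
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path


class TestUtrInference:
    def test_plus_strand_example(self, tmp_path):
        model = {
            "exons": [(1, 100), (201, 300)],
            "cds": [(31, 100), (201, 240)],
            "strand": "+",
            "scaffold_len": 400,
        }
        utrs, errors = infer_three_prime_utrs(_gff(tmp_path, gene_model_gff(model)))
        assert not errors
        assert utrs[0].intervals == ((241, 300),)
        assert utrs[0].length == 60

    def test_minus_strand_downstream_is_lower_coordinates(self, tmp_path):
        model = {
            "exons": [(1, 100), (201, 300)],
            "cds": [(61, 100), (201, 270)],
            "strand": "-",
            "scaffold_len": 400,
        }
        utrs, errors = infer_three_prime_utrs(_gff(tmp_path, gene_model_gff(model)))
        assert not errors
        assert utrs[0].intervals == ((1, 60),)
        assert utrs[0].length == 60

    def test_cds_spanning_all_exons_gives_empty_utr(self, tmp_path):
        model = {
            "exons": [(1, 90)],
            "cds": [(1, 90)],
            "strand": "+",
            "scaffold_len": 200,
        }
        utrs, _ = infer_three_prime_utrs(_gff(tmp_path, gene_model_gff(model)))
        assert utrs[0].intervals == ()
        assert utrs[0].length == 0

    def test_cds_outside_exons_is_error_record_not_abort(self, tmp_path):
        model = {
            "exons": [(1, 90)],
            "cds": [(50, 120)],
            "strand": "+",
            "scaffold_len": 200,
        }
        utrs, errors = infer_three_prime_utrs(_gff(tmp_path, gene_model_gff(model)))
        assert utrs == []
        assert errors and "CDS" in errors[0]["error"]

    def test_matches_per_base_oracle_on_random_models(self, tmp_path):
        """Interval arithmetic equals brute-force base classification."""
        rng = np.random.default_rng(31)
        for i in range(100):
            model = random_gene_model(rng)
            if not model["cds"]:
                continue
            utrs, errors = infer_three_prime_utrs(
                _gff(tmp_path, gene_model_gff(model, gene_id=f"g{i}"))
            )
            assert not errors
            got = {
                b for s, e in utrs[0].intervals for b in range(s, e + 1)
            }
            assert got == brute_utr_bases(model), model


class TestExtractSequence:
    GENOME = {"chr1": "ACGTTGCAGGTCAATCGGATTACCGTAGGC"}  # 30 nt toy scaffold

    def test_plus_strand_verbatim(self):
        utr = UtrRecord("g", "t", "chr1", "+", ((3, 8),))
        assert extract_utr_sequence(utr, self.GENOME) == "GTTGCA"

    def test_minus_strand_revcomp(self):
        utr = UtrRecord("g", "t", "chr1", "-", ((3, 8),))
        assert extract_utr_sequence(utr, self.GENOME) == revcomp("GTTGCA")

    def test_two_interval_minus_strand_order(self):
        # transcript order on '-' = descending genomic intervals
        utr = UtrRecord("g", "t", "chr1", "-", ((21, 26), (3, 8)))
        expected = revcomp(self.GENOME["chr1"][20:26]) + revcomp(
            self.GENOME["chr1"][2:8]
        )
        assert extract_utr_sequence(utr, self.GENOME) == expected

    def test_out_of_bounds_interval_rejected(self):
        utr = UtrRecord("g", "t", "chr1", "+", ((25, 40),))
        with pytest.raises(ValueError):
            extract_utr_sequence(utr, self.GENOME)


class TestScan:
    SEED7 = Seed("m430-7mer", "AAGUGCU")
    SEED6 = Seed("m430-6mer", "AGUGCU")

    def test_site_motifs(self):
        assert self.SEED7.site_motif == "AGCACTT"
        assert self.SEED6.site_motif == "AGCACT"

    def test_known_utr_sites(self):
        utr = "UUUAGCACUUGGG"
        assert [s.start for s in scan_seed_sites(utr, self.SEED7)] == [4]
        assert [s.start for s in scan_seed_sites(utr, self.SEED6)] == [4]

    def test_tandem_sites(self):
        assert [s.start for s in scan_seed_sites("AGCACUAGCACU", self.SEED6)] == [1, 7]

    def test_invalid_seed_length_rejected(self):
        with pytest.raises(ValueError):
            Seed("bad", "AGUGC")

    def test_matches_naive_sliding_window_and_seven_implies_six(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            n = int(rng.integers(20, 400))
            utr = "".join("ACGT"[k] for k in rng.integers(0, 4, n))
            got7 = [s.start for s in scan_seed_sites(utr, self.SEED7)]
            got6 = [s.start for s in scan_seed_sites(utr, self.SEED6)]
            assert got7 == naive_scan(utr, self.SEED7.site_motif)
            assert got6 == naive_scan(utr, self.SEED6.site_motif)
            # the 6-mer motif is a prefix of the 7-mer motif
            assert set(got7) <= set(got6)

    def test_site_positions_map_back_inside_utr_intervals(self, tmp_path):
        rng = np.random.default_rng(41)
        genome = {"chr1": "".join("ACGT"[k] for k in rng.integers(0, 4, 600))}
        utr = UtrRecord("g", "t", "chr1", "-", ((401, 520), (101, 240)))
        seq = extract_utr_sequence(utr, genome)
        for seed in (self.SEED6, self.SEED7):
            for site in scan_seed_sites(seq, seed, "t"):
                for pos in (site.start, site.start + seed.k - 1):
                    scaffold, g = map_site_position(utr, pos)
                    assert scaffold == "chr1"
                    assert any(s <= g <= e for s, e in utr.intervals)


class TestCountSites:
    UTRS = [
        UtrRecord("g1", "t1a", "c", "+", ((1, 100),)),
        UtrRecord("g1", "t1b", "c", "+", ((1, 100),)),
        UtrRecord("g2", "t2", "c", "+", ((1, 100),)),
    ]

    def test_gene_count_is_max_over_transcripts(self):
        sites = [SeedSite("t1a", "s6", i, 6) for i in (1, 10, 20)] + [
            SeedSite("t1b", "s6", i, 6) for i in (1, 10, 20, 30, 40)
        ]
        _tx, genes = count_sites(sites, self.UTRS)
        assert genes.iloc[0]["gene"] == "g1"
        assert genes.iloc[0]["s6"] == 5

    def test_no_sites_empty_ranking(self):
        _tx, genes = count_sites([], self.UTRS)
        assert genes.empty

    def test_ranking_with_lexicographic_ties(self):
        sites = [SeedSite("t2", "s6", 1, 6), SeedSite("t1a", "s6", 1, 6)]
        _tx, genes = count_sites(sites, self.UTRS)
        assert list(genes["gene"]) == ["g1", "g2"]


class TestStageProfile:
    def test_intersection_counts(self):
        profile = stage_target_profile(
            ["g2", "g3", "g4"],
            {"S1": ["g1", "g2", "g3"]},
            {("S1", "escape"): ["g2"], ("S1", "diapause"): []},
        )
        row = profile.iloc[0]
        assert row["expressed_targets"] == 2
        assert row["de_escape_targets"] == 1
        assert row["de_diapause_targets"] == 0

    def test_disjoint_sets_zero(self):
        profile = stage_target_profile(["g9"], {"S1": ["g1"]})
        assert profile.iloc[0]["expressed_targets"] == 0

    def test_growing_expressed_sets_give_monotone_counts(self):
        targets = [f"g{i}" for i in range(0, 40, 3)]
        expressed = {
            f"S{k}": [f"g{i}" for i in range(10 + 10 * k)] for k in range(4)
        }
        profile = stage_target_profile(targets, expressed)
        counts = profile["expressed_targets"].tolist()
        assert counts == sorted(counts)


class TestUtrLengthAnova:
    def test_identical_groups(self):
        lengths = pd.Series([1, 2, 3, 1, 2, 3], index=list("abcdef"), dtype=float)
        counts = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        f, p = utr_length_anova(lengths, counts)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_hand_computed_f(self):
        lengths = pd.Series([1, 2, 3, 101, 102, 103], index=list("abcdef"), dtype=float)
        counts = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        f, p = utr_length_anova(lengths, counts)
        assert f == pytest.approx(15000.0)  # SSB 15000 / (SSW 4 / df 4)
        assert p < 1e-3

    def test_insufficient_bins_rejected(self):
        lengths = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        counts = pd.Series([0, 0, 0], index=list("abc"))
        with pytest.raises(ValueError):
            utr_length_anova(lengths, counts)

    def test_null_p_values_uniform(self):
        """Lengths independent of bins -> p approximately U(0,1) (KS check)."""
        rng = np.random.default_rng(19)
        pvals = []
        for _ in range(200):
            lengths = pd.Series(rng.normal(300, 50, size=60))
            counts = pd.Series(rng.integers(0, 5, size=60))
            _f, p = utr_length_anova(lengths, counts)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3
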