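"""Ground-truth guarantees of the synthetic study generator."""
from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from smallrna_traj._rng import spawn_rng
from smallrna_traj.io import read_fasta
from smallrna_traj.seqs import revcomp, to_dna
from smallrna_traj.simulate import (
    FamilySpec,
    SimConfig,
    decoy_records,
    generate_genome,
    generate_libraries,
    paralog_parts,
    precursor_sequence,
    sample_counts,
    write_references,
)

from .conftest import small_config
from .oracles import naive_scan


def _hash_tree(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


class TestGenerateGenome:
    def test_declining_family_structure(self, small_sim):
        """Five paralog loci placed in two clusters on two scaffolds."""
        _config, truth, _counts, _workdir = small_sim
        declining = truth.loci[truth.loci["family"] == "mir430"]
        assert len(declining) == 5
        assert declining["scaffold"].nunique() == 2

    def test_precursor_readback(self, small_sim):
        """Truth locus windows read back as the constructed precursors."""
        config, truth, _counts, _workdir = small_sim
        for fam in config.family_specs:
            parts = {p.name: p for p in paralog_parts(config, fam)}
            sub = truth.loci[truth.loci["family"] == fam.name]
            for row in sub.itertuples():
                window = truth.scaffolds[row.scaffold][
                    row.precursor_start - 1 : row.precursor_end
                ]
                if row.strand == "-":
                    window = revcomp(window)
                assert window == precursor_sequence(parts[row.paralog])

    def test_empty_family_still_valid(self, tmp_path):
        fam = FamilySpec(
            name="empty",
            n_paralogs=0,
            n_clusters=0,
            shared_5p="AGTAAGTGCT",
            shared_3p="TGTTGGGG",
            profile={"escape": (1,) * 7, "diapause": (1,) * 7},
        )
        config = SimConfig(
            seed=3, family_specs=(fam,), scaffold_length=30_000, n_genes=10
        )
        truth = generate_genome(config, tmp_path)
        assert truth.loci.empty
        assert (tmp_path / "annotation.gff3").read_text().startswith("##gff-version 3")

    def test_byte_identical_reruns(self, tmp_path):
        config = small_config(seed=11)
        a, b = tmp_path / "a", tmp_path / "b"
        truth_a = generate_genome(config, a)
        generate_libraries(config, truth_a, a)
        write_references(config, a / "refs", truth_a)
        truth_b = generate_genome(config, b)
        generate_libraries(config, truth_b, b)
        write_references(config, b / "refs", truth_b)
        assert _hash_tree(a) == _hash_tree(b)

    def test_seeded_site_counts_match_independent_scan(self, small_sim):
        """Truth site counts equal a naive scan of the spliced UTR sequence,
        and a configurable subset of UTRs carries 1-12 seeded copies."""
        config, truth, _counts, workdir = small_sim
        fam = config.site_family
        motif6 = revcomp(to_dna(fam.seed_6mer))
        genome = read_fasta(workdir / "genome.fa")
        from smallrna_traj.targets import extract_utr_sequence, infer_three_prime_utrs

        utrs, errors = infer_three_prime_utrs(workdir / "annotation.gff3")
        assert not errors
        by_tx = {u.transcript_id: u for u in utrs}
        for row in truth.target_sites.itertuples():
            seq = extract_utr_sequence(by_tx[row.transcript], genome)
            assert len(naive_scan(seq, motif6)) == row.n_sites_6mer
            assert 1 <= row.n_sites_6mer <= config.max_sites_per_utr
        assert len(truth.target_sites) > 0

    def test_most_transcripts_have_nonempty_utr(self, small_sim):
        _config, truth, _counts, _workdir = small_sim
        assert (truth.genes["utr_length"] > 0).mean() >= 0.8

    def test_sizing_error_on_too_short_scaffolds(self):
        with pytest.raises(ValueError):
            generate_genome(SimConfig(seed=0, scaffold_length=2_000, n_genes=5))


class TestGenerateLibraries:
    def test_counts_conserve_library_size(self, small_sim):
        config, _truth, counts, _workdir = small_sim
        assert (counts.sum(axis=0) == config.library_size).all()

    def test_fastq_reads_match_truth_counts(self, small_sim):
        config, truth, counts, workdir = small_sim
        lib = truth.design["library"].iloc[0]
        n_reads = sum(1 for _ in open(workdir / "reads" / f"{lib}.fastq")) // 4
        assert n_reads == config.library_size

    def test_zero_library_size(self, tmp_path):
        config = SimConfig(
            seed=5, library_size=0, scaffold_length=30_000, n_genes=10
        )
        truth = generate_genome(config, tmp_path)
        counts = generate_libraries(config, truth, tmp_path)
        assert (counts == 0).all().all()
        lib = truth.design["library"].iloc[0]
        assert (tmp_path / "reads" / f"{lib}.fastq").read_text() == ""

    def test_nb_sampler_mean_calibration(self):
        """Monte-Carlo: a tag with expected count 100 averages within 5%."""
        rng = spawn_rng(1, "mc-test")
        w = np.array([100.0, 300.0, 600.0])
        draws = np.array([sample_counts(w, 1000, 0.1, rng) for _ in range(1000)])
        assert draws.sum(axis=1).max() == 1000
        assert abs(draws[:, 0].mean() - 100) / 100 < 0.05

    def test_increasing_family_onset_recovered_from_truth_means(self, small_sim):
        """Expected means jump at stage index 3 (10S) in escape and index 4
        (16S) in diapause for the increasing family."""
        config, truth, _counts, _workdir = small_sim
        tag = "mir10-a"
        means = truth.expected_means.loc[tag]
        for traj, onset_idx in (("escape", 3), ("diapause", 4)):
            stage_means = np.array(
                [
                    means[[l for l in truth.design[(truth.design.stage == s) & (truth.design.trajectory == traj)]["library"]]].mean()
                    for s in config.stages
                ]
            )
            ratios = stage_means[1:] / np.maximum(stage_means[:-1], 1e-12)
            assert int(np.argmax(ratios)) + 1 == onset_idx


class TestReferences:
    def test_mirna_reference_covers_all_simulated_tags(self, small_sim):
        config, truth, _counts, workdir = small_sim
        ref = read_fasta(workdir / "refs" / "mirna.fa")
        ref_dna = {to_dna(s) for s in ref.values()}
        assert set(truth.mature_tags.values()) <= ref_dna
        # five declining paralogs share 5' and 3' ends
        fam = config.family_specs[0]
        canonical = [
            s for n, s in ref.items() if n.startswith("mir430") and ".iso" not in n
        ]
        assert len(canonical) == 5
        for seq in canonical:
            dna = to_dna(seq)
            assert dna.startswith(fam.shared_5p) and dna.endswith(fam.shared_3p)

    def test_empty_decoy_config_mirna_only(self, tmp_path):
        config = SimConfig(
            seed=9, decoy_counts={}, scaffold_length=30_000, n_genes=10
        )
        truth = generate_genome(config, tmp_path)
        paths = write_references(config, tmp_path / "refs", truth)
        assert set(paths) == {"miRNA", "terms"}
        from smallrna_traj.quant import annotate_tags, load_references

        refs = load_references(tmp_path / "refs")
        annot = annotate_tags(list(truth.mature_tags.values()), refs)
        assert (annot["category"] == "miRNA").all()

    def test_decoy_lengths_avoid_peak_lengths(self):
        for _name, _cat, seq in decoy_records(SimConfig(seed=0)):
            assert len(seq) not in (17, 22)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"replicates_per_group": 1},
            {"nb_dispersion": 0.0},
            {"background_fraction_17nt": 1.0},
            {"library_size": -1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(seed=0, **kwargs)
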