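"""Library simulation: chemistry rules, negative controls, statistical behavior."""

import math

import numpy as np
import pytest

from rrhp import (
    EpiProfile,
    LibraryConfig,
    detectable_sites,
    digest,
    make_genome,
    make_profile,
    simulate_library,
    size_select,
)
from rrhp.io import write_fastq
from rrhp.simulate import (
    HMC,
    MC,
    UNMODIFIED,
    apply_second_digestion,
    enumerate_molecules,
    junction_read_sequence,
    revcomp,
    survives_second_digestion,
)


def constant_profile(sites, hmc, mc):
    return EpiProfile({key: (hmc, mc) for key in sites.strand_pairs()})


class TestMakeGenome:
    def test_reaches_target_site_count_and_is_reproducible(self):
        g1 = make_genome(1, 10_000, 30, seed=7)
        g2 = make_genome(1, 10_000, 30, seed=7)
        assert g1.contigs == g2.contigs
        from rrhp import find_sites

        assert len(find_sites(g1)) >= 30

    def test_target_zero_plain_random(self):
        g = make_genome(1, 500, 0, seed=1)
        assert len(g["contig1"]) == 500

    def test_different_seeds_differ(self):
        assert make_genome(1, 5000, 10, seed=1).contigs != make_genome(1, 5000, 10, seed=2).contigs

    def test_infeasible_target_errors(self):
        with pytest.raises(ValueError):
            make_genome(1, 100, 90, seed=0)


class TestMakeProfile:
    def test_zero_hmc_fraction_one_means_all_zero(self, toy_sites):
        prof = make_profile(toy_sites, zero_hmc_fraction=1.0, seed=5)
        assert all(hmc == 0.0 for hmc, _ in (prof[k] for k in prof.keys()))

    def test_reproducible_and_covers_catalog(self, toy_sites):
        p1 = make_profile(toy_sites, seed=9)
        p2 = make_profile(toy_sites, seed=9)
        assert dict(p1.items()) == dict(p2.items())
        p1.check_matches(toy_sites)

    def test_fractions_in_bounds_and_sum_constraint(self, toy_sites):
        prof = make_profile(toy_sites, hmc_beta_params=(1, 1), mc_beta_params=(1, 1), seed=3)
        for _, (hmc, mc) in prof.items():
            assert 0.0 <= hmc <= 1.0 and 0.0 <= mc <= 1.0
            assert hmc + mc <= 1.0 + 1e-12

    def test_invalid_beta_params_error(self, toy_sites):
        with pytest.raises(ValueError):
            make_profile(toy_sites, hmc_beta_params=(0, 1))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"second_enzyme": "EcoRI"},
            {"digestion_failure_rate": 1.5},
            {"read_length": 3},
            {"pcr_duplicate_mean": 0.5},
            {"n_molecules_per_fragment": 0},
        ],
    )
    def test_rejects_out_of_bounds(self, kwargs):
        with pytest.raises(ValueError):
            LibraryConfig(**kwargs)


class TestSurvivalRule:
    def test_mspi_only_glucosyl_hmc_survives(self):
        assert survives_second_digestion(HMC, 0.9, "MspI", beta_gt=True, failure_rate=0)
        assert not survives_second_digestion(HMC, 0.9, "MspI", beta_gt=False, failure_rate=0)
        assert not survives_second_digestion(MC, 0.9, "MspI", beta_gt=True, failure_rate=0)
        assert not survives_second_digestion(UNMODIFIED, 0.9, "MspI", beta_gt=True, failure_rate=0)

    def test_hpaii_blocked_by_any_methylation(self):
        for bgt in (True, False):
            assert survives_second_digestion(MC, 0.9, "HpaII", bgt, 0)
            assert survives_second_digestion(HMC, 0.9, "HpaII", bgt, 0)
            assert not survives_second_digestion(UNMODIFIED, 0.9, "HpaII", bgt, 0)

    def test_escape_uniform_rescues_cleavable_molecule(self):
        assert survives_second_digestion(UNMODIFIED, 0.0005, "MspI", True, failure_rate=1e-3)


class TestSimulateLibrary:
    def test_negative_control_no_betagt_zero_reads(self, toy_genome, toy_sites, toy_profile):
        cfg = LibraryConfig(n_molecules_per_fragment=20, beta_gt=False,
                            digestion_failure_rate=0.0, seed=1)
        reads, truth = simulate_library(toy_genome, toy_profile, cfg)
        assert reads == []
        assert all(r["reads"] == 0 for r in truth.rows.values())

    def test_hpaii_negative_control_needs_methylation(self, toy_genome, toy_sites):
        prof = constant_profile(toy_sites, 0.0, 0.0)
        cfg = LibraryConfig(n_molecules_per_fragment=20, beta_gt=False,
                            second_enzyme="HpaII", digestion_failure_rate=0.0, seed=1)
        reads, _ = simulate_library(toy_genome, prof, cfg)
        assert reads == []

    def test_full_protection_recovers_every_pair(self, toy_genome, toy_sites):
        prof = constant_profile(toy_sites, 1.0, 0.0)
        cfg = LibraryConfig(n_molecules_per_fragment=60, seed=2)
        _, truth = simulate_library(toy_genome, prof, cfg)
        assert all(r["reads"] >= 1 for r in truth.rows.values())

    def test_background_scaling(self, toy_genome, toy_sites):
        # with no 5hmC, reads come only from incomplete digestion
        f = 0.02
        cfg = LibraryConfig(n_molecules_per_fragment=100, digestion_failure_rate=f, seed=4)
        prof = constant_profile(toy_sites, 0.0, 0.0)
        reads, truth = simulate_library(toy_genome, prof, cfg)
        catalog = size_select(digest(toy_genome), *cfg.insert_range)
        junction_ends = sum(
            (frag.left_site is not None) + (frag.right_site is not None) for frag in catalog
        )
        # per molecule: P(hetero) = 0.5, then the P5 end (0.5 each) must be a junction
        n_eligible = cfg.n_molecules_per_fragment * 0.5 * junction_ends / 2
        expected = n_eligible * f
        sd = math.sqrt(n_eligible * f * (1 - f))
        assert cfg.n_molecules_per_fragment * len(catalog.fragments) >= 1e4
        assert abs(len(reads) - expected) <= 3 * sd

    def test_proportionality_unbiased(self, toy_genome, toy_sites, toy_profile):
        cfg = LibraryConfig(n_molecules_per_fragment=100, seed=6)
        _, truth = simulate_library(toy_genome, toy_profile, cfg)
        expected = sum(r["hmc_true"] * r["drawn"] for r in truth.rows.values())
        var = sum(r["hmc_true"] * (1 - r["hmc_true"]) * r["drawn"] for r in truth.rows.values())
        observed = sum(r["surviving"] for r in truth.rows.values())
        assert abs(observed - expected) <= 3 * math.sqrt(var)

    def test_seed_determinism_byte_identical(self, toy_genome, toy_profile, tmp_path):
        cfg = LibraryConfig(n_molecules_per_fragment=15, seq_error_rate=0.01,
                            pcr_duplicate_mean=1.3, seed=8)
        out = []
        for tag in ("a", "b"):
            reads, truth = simulate_library(toy_genome, toy_profile, cfg)
            fq = tmp_path / f"{tag}.fq"
            tt = tmp_path / f"{tag}.tsv"
            write_fastq(reads, fq)
            truth.to_tsv(tt)
            out.append((fq.read_bytes(), tt.read_bytes()))
        assert out[0] == out[1]

    def test_profile_catalog_mismatch_errors(self, toy_genome, toy_sites):
        prof = constant_profile(toy_sites, 0.5, 0.0)
        cfg = LibraryConfig(insert_range=(60, 200), seed=1)  # different catalog
        with pytest.raises(ValueError):
            simulate_library(toy_genome, prof, cfg)

    def test_pcr_duplication_inflates_reads(self, toy_genome, toy_sites):
        prof = constant_profile(toy_sites, 1.0, 0.0)
        base = LibraryConfig(n_molecules_per_fragment=30, seed=3)
        dup = LibraryConfig(n_molecules_per_fragment=30, pcr_duplicate_mean=2.0, seed=3)
        _, t1 = simulate_library(toy_genome, prof, base)
        _, t2 = simulate_library(toy_genome, prof, dup)
        assert all(r["reads"] == r["surviving"] for r in t1.rows.values())
        assert all(r["reads"] >= r["surviving"] for r in t2.rows.values())
        assert sum(r["reads"] for r in t2.rows.values()) > sum(
            r["reads"] for r in t1.rows.values()
        )


class TestEnzymeNesting:
    def test_mspi_betagt_survivors_subset_of_hpaii(self, toy_genome, toy_sites, toy_profile):
        catalog = size_select(digest(toy_genome), 40, 430)
        rng = np.random.default_rng(12)
        cfg = LibraryConfig(n_molecules_per_fragment=40, seed=12)
        molecules = enumerate_molecules(catalog, toy_profile, cfg, rng)
        mspi = {m.molecule_id for m in apply_second_digestion(molecules, "MspI", True, 0.0)}
        hpaii = {m.molecule_id for m in apply_second_digestion(molecules, "HpaII", True, 0.0)}
        assert mspi <= hpaii
        # 5mC molecules are exactly the HpaII-only survivors when failure is 0
        assert {m.molecule_id for m in molecules if m.state == MC} == hpaii - mspi


class TestJunctionReads:
    def test_reads_start_with_ccgg_tag(self, toy_genome, toy_sites):
        prof = constant_profile(toy_sites, 1.0, 0.0)
        reads, _ = simulate_library(toy_genome, prof, LibraryConfig(n_molecules_per_fragment=5, seed=9))
        assert reads
        assert all(seq[:4] == "CCGG" for _, seq in reads)

    def test_forward_and_reverse_sequences(self):
        from rrhp import Genome

        g = Genome({"c": "CCGG" + "ATAT" * 10 + "CCGG"})
        sel = size_select(digest(g), 10, 100)
        frag = sel.fragments[0]
        fwd = junction_read_sequence(g, frag, "+", 12)
        assert fwd == g["c"][frag.left_site.pos : frag.left_site.pos + 12]
        rev = junction_read_sequence(g, frag, "-", 12)
        end = frag.right_site.pos + 4
        assert rev == revcomp(g["c"][end - 12 : end])
        assert fwd.startswith("CCGG") and rev.startswith("CCGG")
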