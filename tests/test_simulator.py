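from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from conftest import truth_intervals
from mescan.formats_io import read_blast6, read_manifest, read_sam
from mescan.locus_caller import cluster_reads
from mescan.pipeline import call_cohort, process_sample
from mescan.read_filtering import MEFamily
from mescan.simulator import (
    FamilySimParams,
    NoiseParams,
    SimulationConfig,
    SomaticEvent,
    simulate_cellset,
    simulate_reads,
    simulate_truth,
    transmit,
)


def _config(**kw):
    defaults = dict(
        seed=11,
        n_chroms=2,
        chrom_length=400_000,
        families=[FamilySimParams.for_family("L1HS")],
        n_fixed_loci=20,
        samples=["S1", "S2"],
        depth_mean=20.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestTransmit:
    def test_homozygous_always_transmits(self):
        rng = np.random.default_rng(0)
        assert all(transmit(2, rng) == 1 for _ in range(100))

    def test_non_carrier_never_transmits(self):
        rng = np.random.default_rng(0)
        assert all(transmit(0, rng) == 0 for _ in range(100))

    def test_heterozygous_transmits_half_the_time(self):
        rng = np.random.default_rng(42)
        mean = np.mean([transmit(1, rng) for _ in range(10_000)])
        assert 0.485 <= mean <= 0.515

    def test_invalid_copies_rejected(self):
        with pytest.raises(ValueError):
            transmit(3, np.random.default_rng(0))


class TestSimulateTruth:
    def test_fixed_loci_carried_by_everyone(self):
        truth = simulate_truth(_config())
        for locus in truth.loci:
            assert locus.allele_frequency == 1.0
            for s in ("S1", "S2"):
                assert truth.genotypes[(s, locus.locus_id)] == 2

    def test_zero_frequency_has_no_carriers(self):
        truth = simulate_truth(
            _config(n_fixed_loci=0, n_polymorphic_loci=20, allele_freq=0.0)
        )
        assert all(c == 0 for c in truth.genotypes.values())

    def test_min_spacing_twice_window(self):
        config = _config(n_fixed_loci=50, chrom_length=2_000_000)
        truth = simulate_truth(config)
        by_chrom: dict[str, list[int]] = {}
        for locus in truth.loci:
            by_chrom.setdefault(locus.chrom, []).append(locus.position)
        for positions in by_chrom.values():
            positions.sort()
            gaps = np.diff(positions)
            assert (gaps >= 2 * config.window).all()

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_truth(_config(n_fixed_loci=100_000))

    def test_hardy_weinberg_genotype_frequencies(self):
        """Unrelated genotypes at frequency p follow p^2 / 2pq / q^2
        within 3 sigma at 10,000 loci."""
        p = 0.3
        config = _config(
            n_chroms=5,
            chrom_length=5_000_000,
            n_fixed_loci=0,
            n_polymorphic_loci=10_000,
            allele_freq=p,
            samples=["S1"],
        )
        truth = simulate_truth(config)
        copies = np.array(
            [truth.genotypes[("S1", l.locus_id)] for l in truth.loci]
        )
        n = copies.size
        for k, expected in ((2, p * p), (1, 2 * p * (1 - p)),
                            (0, (1 - p) * (1 - p))):
            observed = (copies == k).mean()
            sigma = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) <= 3 * sigma

    def test_mendelian_child_carrier_fraction(self):
        from mescan.formats_io import PedigreeTrio

        config = _config(
            n_chroms=5,
            chrom_length=5_000_000,
            n_fixed_loci=0,
            n_polymorphic_loci=10_000,
            samples=[],
            trios=[PedigreeTrio("F1", "fa", "mo", "ch")],
            forced_parent_genotypes=(1, 0),
            seed=42,
        )
        truth = simulate_truth(config)
        fraction = truth.carrier_fraction("ch")
        assert abs(fraction - 0.5) <= 3 * np.sqrt(0.25 / 10_000)


class TestSimulateReads:
    def test_same_seed_byte_identical(self, tmp_path):
        config = _config()
        for sub in ("a", "b"):
            truth = simulate_truth(config)
            simulate_reads(truth, config, tmp_path / sub)
        for name in [p.name for p in (tmp_path / "a").iterdir()]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_outputs_parse_with_package_readers(self, small_cohort):
        config, truth, manifest = small_cohort
        entries = read_manifest(manifest)
        assert len(entries) == 4
        records = read_blast6(manifest.parent / entries[0].blast6_path)
        assert records and all(r.bit_score >= 0 for r in records)
        alignments = read_sam(manifest.parent / entries[0].sam_path)
        assert alignments and all(
            a.start < a.end for a in alignments if not a.is_unmapped
        )

    def test_noise_free_reads_fall_near_planted_loci(self, small_cohort):
        config, truth, manifest = small_cohort
        entries = read_manifest(manifest)
        positions = {
            (l.chrom, l.strand): [] for l in truth.loci
        }
        for l in truth.loci:
            positions[(l.chrom, l.strand)].append(l.position)
        for entry in entries:
            for aln in read_sam(manifest.parent / entry.sam_path):
                junction = aln.end if aln.strand == "+" else aln.start
                near = [
                    p
                    for p in positions.get((aln.chrom, aln.strand), [])
                    if abs(p - junction) <= config.read_length
                ]
                assert near, (aln.chrom, junction)

    def test_poisson_read_counts(self, tmp_path):
        """Per-locus read counts have unit index of dispersion
        (chi-square test at alpha = 0.01 over 1000 loci)."""
        config = _config(
            n_chroms=4,
            chrom_length=2_000_000,
            n_fixed_loci=1000,
            samples=["S1"],
            seed=23,
        )
        truth = simulate_truth(config)
        manifest = simulate_reads(truth, config, tmp_path)
        entry = read_manifest(manifest)[0]
        counts: dict[str, int] = {}
        for aln in read_sam(manifest.parent / entry.sam_path):
            locus_id = aln.read_id.split(":")[1]
            counts[locus_id] = counts.get(locus_id, 0) + 1
        observed = np.array(
            [counts.get(l.locus_id, 0) for l in truth.loci], dtype=float
        )
        n = observed.size
        dispersion = (n - 1) * observed.var(ddof=1) / observed.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < dispersion < hi

    def test_mapq0_everywhere_kills_all_evidence(self, tmp_path):
        config = _config(noise=NoiseParams(mapq0_rate=1.0))
        truth = simulate_truth(config)
        manifest = simulate_reads(truth, config, tmp_path)
        entries = read_manifest(manifest)
        fam = MEFamily("L1HS", bit_cutoff=56.0)
        for entry in entries:
            result = process_sample(entry, fam, base_dir=manifest.parent)
            assert result.evidence == []

    def test_pipeline_recovers_all_planted_loci(self, small_cohort):
        """Noise-free end-to-end: every planted locus is recovered with a
        called position within a read length of the truth."""
        config, truth, manifest = small_cohort
        entries = read_manifest(manifest)
        fam = MEFamily("L1HS", bit_cutoff=56.0)
        loci, _, _ = call_cohort(entries, fam, base_dir=manifest.parent)
        recovered = 0
        for t in truth.loci:
            if any(
                l.chrom == t.chrom
                and abs(l.position - t.position) <= config.read_length
                for l in loci
            ):
                recovered += 1
        assert recovered == len(truth.loci)


class TestCellset:
    def _cell_config(self, somatic_events=(), seed=31):
        return _config(
            seed=seed,
            samples=[],
            cell_types={"I1": ["T", "iPSC", "NSC", "neuron"],
                        "I2": ["T", "iPSC", "NSC", "neuron"]},
            n_fixed_loci=0,
            n_polymorphic_loci=10,
            allele_freq=0.9,
            somatic_events=list(somatic_events),
        )

    def test_germline_loci_emit_in_all_cell_types(self, tmp_path):
        config = self._cell_config()
        truth = simulate_truth(config)
        manifest = simulate_cellset(truth, config, tmp_path)
        entries = read_manifest(manifest)
        assert len(entries) == 8
        carried = [
            l for l in truth.loci
            if truth.genotypes[("I1", l.locus_id)] > 0
        ]
        for entry in entries:
            if entry.individual_id != "I1":
                continue
            seen = {
                aln.read_id.split(":")[1]
                for aln in read_sam(manifest.parent / entry.sam_path)
            }
            # depth 20 per carried locus: absence by chance is ~e^-10
            for locus in carried:
                assert locus.locus_id in seen

    def test_somatic_reads_confined_to_assigned_cell_type(self, tmp_path):
        config = self._cell_config(
            somatic_events=[SomaticEvent("I1", "neuron", 1.0, 2)]
        )
        truth = simulate_truth(config)
        manifest = simulate_cellset(truth, config, tmp_path)
        somatic_ids = set(truth.somatic[("I1", "neuron")])
        assert len(somatic_ids) == 2
        for entry in read_manifest(manifest):
            seen = {
                aln.read_id.split(":")[1]
                for aln in read_sam(manifest.parent / entry.sam_path)
            }
            if entry.individual_id == "I1" and entry.cell_type == "neuron":
                assert somatic_ids <= seen
            else:
                assert not (somatic_ids & seen)
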