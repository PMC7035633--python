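from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mescan.annotator import KnownLociDB
from mescan.cohort_analysis import (
    CellSampleSet,
    denovo_candidates,
    false_negative_estimate,
    germline_shared_loci,
    inheritance_error_rate,
    observed_inheritance_rate,
    somatic_candidates,
    trio_report,
)
from mescan.cutoff_selector import PresenceMatrix
from mescan.formats_io import GenomicInterval, PedigreeTrio
from mescan.simulator import SimulationConfig, simulate_truth


def make_matrix(carriers, samples, extra_support=None):
    """PresenceMatrix from {locus: set(samples present)}; present loci get
    5 supporting reads, plus optional sub-threshold reads."""
    loci = sorted(carriers)
    present = pd.DataFrame(False, index=loci, columns=samples)
    support = pd.DataFrame(0, index=loci, columns=samples, dtype=int)
    for locus, who in carriers.items():
        for s in who:
            present.at[locus, s] = True
            support.at[locus, s] = 5
    for (locus, s), n in (extra_support or {}).items():
        support.at[locus, s] = n
    return PresenceMatrix(present=present, support_reads=support)


TRIOS = [
    PedigreeTrio("F1", "fa1", "mo1", "ch1"),
    PedigreeTrio("F2", "fa2", "mo2", "ch2"),
]
SAMPLES = ["fa1", "mo1", "ch1", "fa2", "mo2", "ch2"]


class TestDenovo:
    def test_child_only_zero_elsewhere_is_candidate(self):
        matrix = make_matrix({"A": {"ch1"}}, SAMPLES)
        assert denovo_candidates(matrix, TRIOS) == ["A"]

    def test_present_in_unrelated_adult_excluded(self):
        matrix = make_matrix({"A": {"ch1", "fa2"}}, SAMPLES)
        assert denovo_candidates(matrix, TRIOS) == []

    def test_strict_zero_flag_controls_subthreshold_reads(self):
        matrix = make_matrix(
            {"A": {"ch1"}}, SAMPLES, extra_support={("A", "fa1"): 2}
        )
        assert denovo_candidates(matrix, TRIOS, strict_zero=True) == []
        assert denovo_candidates(matrix, TRIOS, strict_zero=False) == ["A"]

    def test_never_intersects_parental_loci(self):
        rng = np.random.default_rng(1)
        carriers = {
            f"L{i}": {
                s for s in SAMPLES if rng.random() < 0.4
            }
            for i in range(50)
        }
        carriers["L50"] = {"ch2"}
        matrix = make_matrix(carriers, SAMPLES)
        candidates = set(denovo_candidates(matrix, TRIOS))
        parental = {
            locus
            for locus, who in carriers.items()
            if who & {"fa1", "mo1", "fa2", "mo2"}
        }
        assert candidates & parental == set()


class TestInheritanceErrorRate:
    def test_one_of_three_child_loci_unexplained(self):
        matrix = make_matrix(
            {"A": {"ch1", "fa1"}, "B": {"ch1", "mo1"}, "C": {"ch1"}},
            SAMPLES,
        )
        assert inheritance_error_rate(matrix, TRIOS[0]) == pytest.approx(1 / 3)

    def test_all_parental_gives_zero(self):
        matrix = make_matrix(
            {"A": {"ch1", "fa1"}, "B": {"ch1", "mo1", "fa1"}}, SAMPLES
        )
        assert inheritance_error_rate(matrix, TRIOS[0]) == 0.0

    def test_childless_sample_gives_zero(self):
        matrix = make_matrix({"A": {"fa1"}}, SAMPLES)
        assert inheritance_error_rate(matrix, TRIOS[0]) == 0.0

    def test_zero_on_error_free_mendelian_simulation(self):
        """With perfect detection, every child locus is explained by a
        parent: Mendelian violations require detection error."""
        trios = [
            PedigreeTrio(f"F{i}", f"fa{i}", f"mo{i}", f"ch{i}")
            for i in range(4)
        ]
        config = SimulationConfig(
            seed=13,
            n_chroms=2,
            chrom_length=3_000_000,
            n_fixed_loci=0,
            n_polymorphic_loci=500,
            allele_freq=0.3,
            trios=trios,
        )
        truth = simulate_truth(config)
        samples = truth.samples
        carriers = {
            locus.locus_id: {
                s for s in samples if truth.genotypes[(s, locus.locus_id)] > 0
            }
            for locus in truth.loci
        }
        matrix = make_matrix(carriers, samples)
        for trio in trios:
            assert inheritance_error_rate(matrix, trio) == 0.0


class TestObservedInheritanceRate:
    def test_half_of_single_parent_loci_in_child(self):
        carriers = {}
        for i in range(10):
            who = {"fa1", "fa2"}  # carried by 2 cohort parents
            if i < 5:
                who = who | {"ch1"}
            carriers[f"L{i}"] = who
        matrix = make_matrix(carriers, SAMPLES)
        per_trio, _ = observed_inheritance_rate(
            matrix, TRIOS, "single_parent"
        )
        assert per_trio["F1"] == pytest.approx(0.5)

    def test_trio_without_qualifying_loci_excluded(self):
        matrix = make_matrix({"A": {"fa1", "mo1", "ch1"}}, SAMPLES)
        with pytest.warns(UserWarning, match="no qualifying loci"):
            per_trio, _ = observed_inheritance_rate(
                matrix, TRIOS, "single_parent"
            )
        assert "F2" not in per_trio

    @pytest.mark.parametrize(
        "genotypes,mode,expected,tol",
        [
            ((1, 0), "single_parent", 0.5, 0.015),
            ((1, 1), "both_parents", 0.75, 0.013),
            ((2, 0), "single_parent", 1.0, 0.0),
        ],
    )
    def test_mendelian_convergence(self, genotypes, mode, expected, tol):
        """Observed child inheritance converges to the Mendelian
        expectation: 0.5 for one het parent, 0.75 for two het parents,
        exactly 1.0 for a homozygous parent (3-sigma binomial band at
        n = 10,000)."""
        trios = [PedigreeTrio("F1", "fa1", "mo1", "ch1"),
                 PedigreeTrio("F2", "fa2", "mo2", "ch2")]
        config = SimulationConfig(
            seed=42,
            n_chroms=4,
            chrom_length=8_000_000,
            n_fixed_loci=0,
            n_polymorphic_loci=10_000,
            trios=trios,
            forced_parent_genotypes=genotypes,
        )
        truth = simulate_truth(config)
        samples = truth.samples
        carriers = {
            locus.locus_id: {
                s for s in samples if truth.genotypes[(s, locus.locus_id)] > 0
            }
            for locus in truth.loci
        }
        matrix = make_matrix(carriers, samples)
        per_trio, average = observed_inheritance_rate(matrix, trios, mode)
        assert average == pytest.approx(expected, abs=tol)


class TestFalseNegativeEstimate:
    def test_both_conventions_reported(self):
        rates = {"Y045": 0.65, "F2": 0.52}
        out = false_negative_estimate(rates)
        assert out["F2"]["diff"] == pytest.approx(0.13)
        assert out["F2"]["ratio"] == pytest.approx(0.20)
        assert out["Y045"]["diff"] == 0.0

    def test_equal_rates_give_zero(self):
        out = false_negative_estimate({"a": 0.5, "b": 0.5})
        assert all(v["diff"] == 0.0 for v in out.values())

    def test_estimates_never_negative(self):
        out = false_negative_estimate({"a": 0.4, "b": 0.6, "c": 0.5})
        assert all(v["diff"] >= 0 and v["ratio"] >= 0 for v in out.values())

    def test_requires_two_trios(self):
        with pytest.raises(ValueError):
            false_negative_estimate({"a": 0.5})


def make_cellset(individual, support, cutoff=1):
    """CellSampleSet from {locus: {cell_type: reads}}; presence = reads
    >= cutoff."""
    cell_types = sorted({ct for v in support.values() for ct in v})
    loci = sorted(support)
    reads = pd.DataFrame(0, index=loci, columns=cell_types, dtype=int)
    for locus, by_ct in support.items():
        for ct, n in by_ct.items():
            reads.at[locus, ct] = n
    present = reads >= cutoff
    return CellSampleSet(
        individual_id=individual, present=present, support_reads=reads
    )


class TestSomatic:
    CTS = ["T", "iPSC", "NSC", "neuron"]

    def test_single_cell_type_private_locus_is_candidate(self):
        cs1 = make_cellset(
            "I1", {"A": {"neuron": 8, "T": 0, "iPSC": 0, "NSC": 0}}
        )
        cs2 = make_cellset(
            "I2", {"A": {"neuron": 0, "T": 0, "iPSC": 0, "NSC": 0}}
        )
        assert somatic_candidates([cs1, cs2], None) == [("I1", "neuron", "A")]

    def test_single_read_in_second_cell_type_disqualifies(self):
        cs = make_cellset(
            "I1", {"A": {"neuron": 8, "iPSC": 1, "T": 0, "NSC": 0}}
        )
        assert somatic_candidates([cs], None) == []

    def test_reads_in_second_individual_disqualify(self):
        cs1 = make_cellset("I1", {"A": {"neuron": 8, "T": 0}})
        cs2 = make_cellset("I2", {"A": {"neuron": 2, "T": 0}})
        assert somatic_candidates([cs1, cs2], None) == []

    def test_known_polymorphic_locus_excluded(self):
        from mescan.locus_caller import CandidateLocus

        locus = CandidateLocus("A", "SVA", "chr1", 5100, "+", {})
        db = KnownLociDB(
            reference_meis=[],
            polymorphic_meis=[GenomicInterval("chr1", 5000, 5300, "dbRIP")],
        )
        cs = make_cellset("I1", {"A": {"neuron": 8, "T": 0}})
        assert somatic_candidates([cs], db, {"A": locus}) == []

    def test_germline_requires_all_cell_types(self):
        cs = make_cellset(
            "I1",
            {
                "A": {ct: 5 for ct in self.CTS},
                "B": {"T": 5, "iPSC": 5, "NSC": 5, "neuron": 0},
            },
        )
        assert germline_shared_loci([cs]) == {"I1": ["A"]}


def test_trio_report_assembles_all_metrics():
    carriers = {
        "A": {"ch1", "fa1", "fa2"},
        "B": {"ch1", "mo1", "mo2"},
        "C": {"ch1"},
        "D": {"fa1", "mo1", "fa2", "mo2", "ch2"},
    }
    matrix = make_matrix(carriers, SAMPLES)
    reports = trio_report(matrix, TRIOS, "L1HS")
    by_family = {r.family_id: r for r in reports}
    assert by_family["F1"].child_locus_count == 3
    assert by_family["F1"].inheritance_error_rate == pytest.approx(1 / 3)
    assert 0 <= by_family["F1"].single_parent_rate <= 1
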