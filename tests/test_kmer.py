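"""Canonical k-mer counting and spectrum-based genome profiling."""

import numpy as np
import pytest
from Bio.Seq import Seq

from cvalkit import kmer, synth
from cvalkit.errors import EstimationError, ValidationError
from cvalkit.kmer import Spectrum


def brute_force_spectrum(reads, k):
    """Independent oracle: substring counting with Biopython revcomp."""
    counts = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            window = read[i:i + k].upper()
            if any(c not in "ACGT" for c in window):
                continue
            canon = min(window, str(Seq(window).reverse_complement()))
            counts[canon] = counts.get(canon, 0) + 1
    hist = {}
    for occ in counts.values():
        hist[occ] = hist.get(occ, 0) + 1
    return hist


class TestCounting:
    def test_manual_enumeration_acgta(self):
        spec = kmer.count_kmers(["ACGTA"], k=3)
        # ACG,CGT both canonicalize to ACG; GTA beats revcomp TAC
        assert spec.counts == {1: 1, 2: 1}

    def test_empty_input_gives_empty_spectrum(self):
        assert kmer.count_kmers([], k=21).counts == {}

    def test_windows_with_n_are_skipped(self):
        assert kmer.count_kmers(["ACNGT"], k=3).counts == {}
        # one valid window survives on a longer read
        assert kmer.count_kmers(["ACGNT"], k=3).counts == {1: 1}

    def test_even_k_rejected(self):
        with pytest.raises(ValidationError, match="odd"):
            kmer.count_kmers(["ACGT"], k=4)

    @pytest.mark.parametrize("k", [3, 15, 21, 27, 31])
    def test_matches_brute_force_oracle(self, k, rng):
        bases = np.array(list("ACGTN"))
        reads = ["".join(rng.choice(bases, size=rng.integers(k, 400),
                                    p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                 for _ in range(60)]
        assert kmer.count_kmers(reads, k=k).counts == brute_force_spectrum(reads, k)

    def test_occurrence_mass_equals_valid_windows(self, rng):
        k = 21
        reads = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(100)]
        spec = kmer.count_kmers(reads, k=k)
        assert spec.total_mass(1) == sum(len(r) - k + 1 for r in reads)

    def test_reverse_complements_double_depths(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(20)]
        rc = [str(Seq(r).reverse_complement()) for r in reads]
        a = kmer.count_kmers(reads, k=17)
        b = kmer.count_kmers(reads + rc, k=17)
        assert sum(a.counts.values()) == sum(b.counts.values())  # same distinct set
        assert {2 * d for d in a.counts} == set(b.counts)
        assert all(b.counts[2 * d] == c for d, c in a.counts.items())

    def test_fastq_file_counting(self, tmp_path):
        reads = [("r1", "ACGTACGT", "IIIIIIII"), ("r2", "ACGTACGT", "IIIIIIII")]
        p = tmp_path / "reads.fastq"
        synth.write_fastq(reads, p)
        spec = kmer.count_kmers_in_file(p, k=5)
        assert spec.total_mass(1) == 2 * (8 - 5 + 1)


class TestSpectrumIO:
    def test_two_column_round_trip(self, tmp_path):
        spec = Spectrum(k=21, counts={1: 100, 13: 50, 26: 500})
        p = tmp_path / "hist.txt"
        spec.write(p)
        lines = p.read_text().splitlines()
        assert lines[0].split() == ["1", "100"]
        back = Spectrum.read(p, k=21)
        assert back.counts == spec.counts


class TestErrorCutoff:
    def test_valley_found_after_error_slope(self):
        spec = Spectrum(k=21, counts={1: 1000, 2: 200, 3: 50, 10: 500, 11: 480})
        assert kmer.error_cutoff(spec) == 4

    def test_single_peak_falls_back_to_one(self):
        assert kmer.error_cutoff(Spectrum(k=21, counts={10: 100})) == 1

    def test_monotone_decay_warns_no_genomic_peak(self):
        spec = Spectrum(k=21, counts={1: 10, 2: 5, 3: 2})
        with pytest.warns(UserWarning, match="no genomic peak"):
            assert kmer.error_cutoff(spec) == 1


class TestGenomeSize:
    def test_single_peak_exact(self):
        d_hom, size = kmer.genome_size(Spectrum(k=21, counts={10: 100}), 1)
        assert d_hom == 10
        assert size == 100

    def test_expected_spectrum_recovered_within_one_percent(self):
        cfg = synth.KmerSimConfig(genome_length=10**5, coverage=30, k=21,
                                  read_length=150, heterozygosity=0,
                                  repeat_fraction=0, error_rate=0, noise=False)
        spec = synth.simulate_kmer_spectrum(cfg)
        d_hom, size = kmer.genome_size(spec, kmer.error_cutoff(spec))
        assert abs(size - 10**5) / 10**5 < 0.01
        assert d_hom == pytest.approx(26.0, abs=0.5)

    def test_poisson_noise_spectrum_within_three_percent(self):
        cfg = synth.KmerSimConfig(genome_length=10**5, coverage=30, k=21,
                                  read_length=150, heterozygosity=0,
                                  repeat_fraction=0, error_rate=0,
                                  noise=True, seed=19)
        spec = synth.simulate_kmer_spectrum(cfg)
        _, size = kmer.genome_size(spec, kmer.error_cutoff(spec))
        assert abs(size - 10**5) / 10**5 < 0.03

    def test_invariant_to_coverage_doubling(self):
        sizes = []
        for cov in (30, 60):
            cfg = synth.KmerSimConfig(genome_length=10**5, coverage=cov, k=21,
                                      heterozygosity=0, repeat_fraction=0,
                                      error_rate=0, noise=False)
            spec = synth.simulate_kmer_spectrum(cfg)
            sizes.append(kmer.genome_size(spec, kmer.error_cutoff(spec))[1])
        assert abs(sizes[1] - sizes[0]) / sizes[0] < 0.03

    def test_empty_above_cutoff_rejected(self):
        with pytest.raises(EstimationError):
            kmer.genome_size(Spectrum(k=21, counts={1: 10}), 5)


class TestRepeatFraction:
    def test_single_peak_has_no_repeats(self):
        assert kmer.repeat_fraction(Spectrum(k=21, counts={10: 100}), 1, 10.0) == 0

    def test_equal_mass_split(self):
        spec = Spectrum(k=21, counts={10: 100, 20: 50})
        assert kmer.repeat_fraction(spec, 1, 10.0) == pytest.approx(0.5)

    def test_simulator_ground_truth_recovered(self):
        cfg = synth.KmerSimConfig(genome_length=10**5, coverage=30, k=21,
                                  heterozygosity=0, repeat_fraction=0.5,
                                  repeat_multiplicity=2, error_rate=0,
                                  noise=False)
        spec = synth.simulate_kmer_spectrum(cfg)
        c = kmer.error_cutoff(spec)
        d_hom, _ = kmer.genome_size(spec, c)
        assert kmer.repeat_fraction(spec, c, d_hom) == pytest.approx(0.5, abs=0.05)


class TestHeterozygosity:
    def test_no_het_peak_gives_zero(self):
        spec = Spectrum(k=21, counts={26: 1000})
        assert kmer.heterozygosity(spec, 1, 26.0, 21) == 0.0

    def test_closed_form_mass_ratio(self):
        # two clean delta peaks: het mass 13*154 = 2002, hom mass 26*308 = 8008
        spec = Spectrum(k=21, counts={13: 154, 26: 308})
        h = kmer.heterozygosity(spec, 1, 26.0, 21, depth_correction=False)
        f = 2002 / (2002 + 8008)
        assert h == pytest.approx(1 - (1 - f) ** (1 / 21), rel=1e-12)
        # reference point: f = 0.2 at k = 21 gives h = 1 - 0.8^(1/21)
        assert 1 - 0.8 ** (1 / 21) == pytest.approx(0.01057, abs=1e-5)

    def test_simulator_ground_truth_within_20_percent(self):
        cfg = synth.KmerSimConfig(genome_length=2 * 10**5, coverage=30, k=21,
                                  heterozygosity=0.01, repeat_fraction=0,
                                  error_rate=0, noise=False)
        spec = synth.simulate_kmer_spectrum(cfg)
        c = kmer.error_cutoff(spec)
        d_hom, _ = kmer.genome_size(spec, c)
        h = kmer.heterozygosity(spec, c, d_hom, 21)
        assert abs(h - 0.01) / 0.01 < 0.2

    def test_unresolvable_peak_rejected(self):
        with pytest.raises(EstimationError, match="unresolvable"):
            kmer.heterozygosity(Spectrum(k=21, counts={3: 10}), 1, 3.0, 21)


class TestReport:
    def test_single_peak_chained_report(self):
        est = kmer.kmer_report(Spectrum(k=21, counts={10: 100}))
        assert est.genome_size_bp == 100
        assert est.repeat_fraction == 0
        assert est.heterozygosity == 0

    def test_bp_to_pg_conversion(self):
        # 9.1548e9 distinct k-mers at depth 10 -> genome 9.1548e9 bp
        est = kmer.kmer_report(Spectrum(k=21, counts={10: int(9.1548e9)}))
        assert round(est.genome_size_pg, 2) == 9.36

    def test_method_difference(self):
        assert kmer.method_difference(9.64, 9.36) == 0.28
        assert kmer.method_difference(14.45, 14.19) == 0.26


class TestReadFilters:
    def test_low_quality_reads_dropped(self):
        good = ("g", "ACGT", "IIII")           # Q40
        bad = ("b", "ACGT", "!!!!")            # Q0
        assert kmer.filter_reads([good, bad]) == [good]

    def test_duplicate_pairs_dropped_when_requested(self):
        p1 = [("a1", "AAAA", "IIII"), ("a2", "CCCC", "IIII")]
        dup = [("b1", "AAAA", "IIII"), ("b2", "CCCC", "IIII")]
        other = [("c1", "GGGG", "IIII"), ("c2", "TTTT", "IIII")]
        kept = kmer.filter_reads(p1 + dup + other, drop_duplicate_pairs=True)
        assert [r[0] for r in kept] == ["a1", "a2", "c1", "c2"]
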