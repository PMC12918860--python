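import collections
import math

import numpy as np
import pytest
from scipy import stats

from somamotif.indel_classes import classify_indel
from somamotif.motif_enrichment import compile_motif, default_registry
from somamotif.rates_trends import age_correlation
from somamotif.synthetic_data import (
    AlleleFractionModel,
    CLONAL_ONLY,
    generate_reference,
    simulate_clock,
    simulate_indels,
    simulate_snv_catalogue,
    simulate_sv_cohort,
)


class TestGenerateReference:
    def test_deterministic(self):
        a = generate_reference(10_000, gc=0.5, seed=1)
        b = generate_reference(10_000, gc=0.5, seed=1)
        assert a["chr1"] == b["chr1"]

    def test_different_seeds_differ(self):
        a = generate_reference(5_000, seed=1)
        b = generate_reference(5_000, seed=2)
        assert a["chr1"] != b["chr1"]

    def test_cpg_factor_zero(self):
        ref = generate_reference(20_000, cpg_factor=0.0, seed=3,
                                 homopolymer_runs=[("G", 5, 10)])
        assert "CG" not in ref["chr1"]

    def test_gc_content(self):
        ref = generate_reference(50_000, gc=0.6, seed=4)
        seq = ref["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.6, abs=0.02)

    def test_planted_runs(self):
        ref = generate_reference(50_000, seed=5,
                                 homopolymer_runs=[("T", 6, 50)])
        seq = ref["chr1"]
        count = 0
        i = 0
        while i < len(seq):
            if seq[i] == "T":
                j = i
                while j < len(seq) and seq[j] == "T":
                    j += 1
                if j - i >= 6:
                    count += 1
                i = j
            else:
                i += 1
        assert count >= 50

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_reference(500, seed=1)
        with pytest.raises(ValueError):
            generate_reference(2000, gc=1.5, seed=1)


class TestSnvCatalogue:
    def test_all_process_records_match_motif(self):
        ref = generate_reference(100_000, seed=6)
        records, labels = simulate_snv_catalogue(ref, 0, {"nCg": 500}, seed=7)
        assert len(records) == 500
        assert set(labels) == {"nCg-process"}
        motif = compile_motif("nCg>nTg")
        for r in records:
            assert motif.matches(ref.trinucleotide(r.chrom, r.pos), r.ref, r.alt)

    def test_background_count_and_reproducibility(self):
        ref = generate_reference(50_000, seed=8)
        r1, l1 = simulate_snv_catalogue(ref, 1000, seed=9)
        r2, l2 = simulate_snv_catalogue(ref, 1000, seed=9)
        assert len(r1) == 1000 and l1 == l2 and r1 == r2

    def test_truth_counts_conserved(self):
        ref = generate_reference(100_000, seed=10)
        _, labels = simulate_snv_catalogue(ref, 200, {"nCg": 50, "aTn": 30},
                                           seed=11)
        counter = collections.Counter(labels)
        assert counter == {"background": 200, "nCg-process": 50, "aTn-process": 30}

    def test_clonal_af_model_against_truncnorm_mass(self):
        # oracle: empirical mass of N(0.5, 0.02) inside the clonal windows
        rng = np.random.default_rng(0)
        draws = rng.normal(0.5, 0.02, 10_000)
        expected = np.mean(((draws >= 0.45) & (draws <= 0.55)))
        ref = generate_reference(200_000, seed=12)
        records, _ = simulate_snv_catalogue(
            ref, 4000, af_model=AlleleFractionModel(weights=(1.0, 0.0, 0.0)),
            seed=13)
        afs = np.array([r.af for r in records])
        passed = np.mean(((afs >= 0.45) & (afs <= 0.55)) | (afs >= 0.90))
        assert passed == pytest.approx(expected, abs=0.01)

    def test_clonal_only_mixture_passes_filter(self):
        ref = generate_reference(100_000, seed=14)
        records, _ = simulate_snv_catalogue(ref, 2000, af_model=CLONAL_ONLY,
                                            seed=15)
        afs = np.array([r.af for r in records])
        passed = np.mean(((afs >= 0.45) & (afs <= 0.55)) | (afs >= 0.90))
        assert passed >= 0.97

    def test_insufficient_sites_error_names_motif(self):
        ref = generate_reference(2_000, cpg_factor=0.0, seed=16)
        with pytest.raises(ValueError, match="nCg"):
            simulate_snv_catalogue(ref, 0, {"nCg": 100}, seed=17)

    def test_min_spacing_respected(self):
        ref = generate_reference(100_000, seed=18)
        records, _ = simulate_snv_catalogue(ref, 500, {"nCg": 100}, seed=19,
                                            min_spacing=11)
        pos = sorted(r.pos for r in records)
        assert min(np.diff(pos)) >= 11


class TestIndels:
    def test_slippage_classified_as_homopolymer(self):
        ref = generate_reference(60_000, seed=20,
                                 homopolymer_runs=[("T", 6, 80), ("A", 7, 80)])
        records, labels = simulate_indels(ref, slippage_n=100, dsb_n=0, seed=21)
        assert labels == ["slippage"] * 100
        channels = [classify_indel(r, ref) for r in records]
        frac = np.mean([c.family == "homopolymer" for c in channels])
        assert frac >= 0.95

    def test_dsb_microhomology_split_within_binomial_bounds(self):
        ref = generate_reference(80_000, seed=22)
        records, labels = simulate_indels(ref, slippage_n=0, dsb_n=50,
                                          mh_probs={0: 0.5, 1: 0.5}, seed=23)
        mh1 = sum(classify_indel(r, ref).family == "microhomology"
                  for r in records)
        lo, hi = stats.binom.interval(0.99, 50, 0.5)
        assert lo <= mh1 <= hi

    def test_dsb_lengths_in_range(self):
        ref = generate_reference(50_000, seed=24)
        records, _ = simulate_indels(ref, slippage_n=0, dsb_n=30, seed=25)
        for r in records:
            assert 5 <= len(r.ref) - 1 <= 24

    def test_no_runs_error(self):
        ref = generate_reference(5_000, seed=26)
        with pytest.raises(ValueError, match="runs"):
            simulate_indels(ref, slippage_n=10, dsb_n=0, min_run=30, seed=27)


class TestSvCohort:
    def test_recovery(self):
        from somamotif.sv_hotspots import call_hotspots

        svs, truth = simulate_sv_cohort(5, 10, hotspot_spec=(2, 400_000), seed=28)
        call_hotspots(svs)
        hot = [s for s, t in zip(svs, truth) if t]
        assert sum(s.in_hotspot for s in hot) / len(hot) >= 0.95

    def test_no_loci_chance_level(self):
        from somamotif.sv_hotspots import call_hotspots

        svs, truth = simulate_sv_cohort(5, 2, hotspot_spec=(0, 400_000),
                                        seed=29, chrom_length=1_000_000_000)
        assert not any(truth)
        call_hotspots(svs)
        frac = np.mean([s.in_hotspot for s in svs])
        # union bound on the chance flag rate at this density: each of the 2
        # breakpoints sees 16 foreign breakpoints, each within 1 Mb w.p.
        # <= 2 Mb / 1000 Mb
        bound = 2 * 16 * (2_000_000 / 1_000_000_000)
        assert frac <= bound + 0.2

    def test_empty(self):
        svs, truth = simulate_sv_cohort(3, 0, seed=30)
        assert svs == [] and truth == []

    def test_deletion_dominated_mix(self):
        svs, _ = simulate_sv_cohort(10, 40, seed=31)
        counts = collections.Counter(s.sv_type for s in svs)
        assert counts["DEL"] == max(counts.values())
        assert counts["DUP"] >= counts["TRA"]


class TestClock:
    def test_poisson_means(self):
        counts, _ = simulate_clock({"A": 40.0, "B": 80.0}, {"nCg": 5.0}, seed=32)
        lo40, hi40 = stats.poisson.interval(0.999, 200)
        lo80, hi80 = stats.poisson.interval(0.999, 400)
        assert lo40 <= counts["A"]["nCg"] <= hi40
        assert lo80 <= counts["B"]["nCg"] <= hi80

    def test_zero_rate(self):
        counts, _ = simulate_clock([50.0, 60.0], {"nCg": 0.0}, seed=33)
        assert all(c["nCg"] == 0 for c in counts.values())

    def test_age_correlation_power(self):
        detected = 0
        for seed in range(30):
            ages = {f"D{i}": float(a) for i, a in enumerate(
                np.random.default_rng(seed).uniform(40, 90, 10))}
            counts, _ = simulate_clock(ages, {"nCg": 5.0}, seed=seed)
            values = {d: float(c["nCg"]) for d, c in counts.items()}
            _, p = age_correlation(values, ages, sided="one")
            detected += p <= 0.05
        assert detected / 30 >= 0.9

    def test_telomere_consistent_with_divisions(self):
        from somamotif.rates_trends import estimate_divisions

        _, telomere = simulate_clock({"A": 60.0}, {}, seed=34)
        div = estimate_divisions(telomere["A"])
        assert 0 <= div <= 80

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            simulate_clock({"A": -5.0}, {"nCg": 1.0}, seed=35)
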