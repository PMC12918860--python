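import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from somamotif.catalogue_io import MutationRecord
from somamotif.genome import Reference, complement, revcomp
from somamotif.motif_enrichment import (
    ContextCounter,
    EnrichmentCounts,
    bh_adjust,
    compile_motif,
    compute_enrichment,
    compute_meml,
    count_motif_and_context,
    default_registry,
    fisher_enrichment_test,
    meml_pair_fraction,
    meml_prevalence,
    motif_panel,
    select_scattered,
)
from somamotif.synthetic_data import generate_reference, simulate_snv_catalogue

import oracles
from conftest import make_snv


class TestCompileMotif:
    def test_ncg_match(self):
        motif = compile_motif("nCg>nTg")
        ref = Reference({"chr1": "ACGT"})
        assert motif.matches(ref.trinucleotide("chr1", 2), "C", "T")

    def test_atn_reverse_complement_match(self):
        motif = compile_motif("aTn>aCn")
        ref = Reference({"chr1": "CATG"})
        # A->G at pos 2 is T->C on the minus strand with an upstream a
        assert motif.matches(ref.trinucleotide("chr1", 2), "A", "G")

    @pytest.mark.parametrize("text", [
        "nCg>nAg>x", "nCg", "nCgg>nTgg", "nCg>nTa", "nXg>nTg", "aAn>aGn",
    ])
    def test_malformed(self, text):
        with pytest.raises(ValueError):
            compile_motif(text)

    def test_registry_ships_eleven_motifs(self):
        registry = default_registry()
        assert len(registry) == 11
        names = {m.name for m in registry}
        assert {"nCg>nTg", "aTn>aCn", "yCn>yTn", "nTt>nCt"} <= names
        by_name = {m.name: m for m in registry}
        assert by_name["rCg>rTg"].parent == "nCg>nTg"
        assert by_name["yCh>yTh"].parent == "yCn>yTn"


class TestSelectScattered:
    def test_distance_10_both_removed(self):
        a, b = make_snv(pos=100), make_snv(pos=110)
        assert select_scattered([a, b]) == []

    def test_distance_11_both_kept(self):
        a, b = make_snv(pos=100), make_snv(pos=111)
        assert select_scattered([a, b]) == [a, b]

    def test_single_record_kept(self):
        a = make_snv(pos=100)
        assert select_scattered([a]) == [a]

    def test_whole_cluster_removed(self):
        cluster = [make_snv(pos=p) for p in (100, 108, 116)]
        lone = make_snv(pos=400)
        assert select_scattered(cluster + [lone]) == [lone]

    def test_different_chromosomes_independent(self):
        a = make_snv(pos=100)
        b = make_snv(chrom="chr2", pos=105)
        assert select_scattered([a, b]) == [a, b]


class TestCounts:
    def test_single_cg_in_at_window(self):
        # 41-base window all A/T except one central CpG; mutation at its C
        seq = "AT" * 10 + "CG" + "TA" * 10
        ref = Reference({"chr1": seq})
        rec = make_snv(pos=21, ref="C", alt="T")
        counts = count_motif_and_context([rec], ref, compile_motif("nCg>nTg"))
        assert counts == EnrichmentCounts(1, 1, 2, 2)

    def test_zero_records(self, toy_reference):
        counts = count_motif_and_context([], toy_reference, compile_motif("nCg>nTg"))
        assert counts == EnrichmentCounts(0, 0, 0, 0)

    def test_overlapping_windows_sum_independently(self, toy_reference):
        recs = [r for r in (make_snv(pos=p, ref=toy_reference.base_at("chr1", p),
                                     alt="T" if toy_reference.base_at("chr1", p) == "C"
                                     else "A")
                            for p in (100, 110))]
        motif = compile_motif("nCg>nTg")
        cls = [r for r in recs if motif.matches_class(r.ref, r.alt)]
        if len(cls) == 2:
            both = count_motif_and_context(cls, toy_reference, motif)
            parts = [count_motif_and_context([r], toy_reference, motif) for r in cls]
            assert both.ctx_motif == sum(p.ctx_motif for p in parts)
            assert both.ctx_base == sum(p.ctx_base for p in parts)

    def test_window_truncated_at_contig_edge(self):
        ref = Reference({"chr1": "ACGTACGTAC"})
        rec = make_snv(pos=2, ref="C", alt="T")
        counts = count_motif_and_context([rec], ref, compile_motif("nCg>nTg"))
        # context limited to the 10 bases that exist
        assert counts.ctx_base == ref["chr1"].count("C") + ref["chr1"].count("G")

    def test_wrong_class_rejected(self, toy_reference):
        rec = make_snv(pos=100, ref="A", alt="C")
        with pytest.raises(ValueError, match="not of class"):
            count_motif_and_context([rec], toy_reference, compile_motif("nCg>nTg"))

    def test_brute_force_oracle_small_genomes(self):
        registry = default_registry()
        for seed in range(3):
            ref = generate_reference(2000, gc=0.5, seed=seed)
            records, _ = simulate_snv_catalogue(ref, 60, seed=seed + 50)
            seqs = {c: ref[c] for c in ref}
            for motif in registry:
                cls = [r for r in records if motif.matches_class(r.ref, r.alt)]
                got = count_motif_and_context(cls, ref, motif)
                exp = oracles.brute_force_counts(
                    [(r.chrom, r.pos, r.ref, r.alt) for r in cls],
                    seqs, f"{motif.pattern}>{motif.pattern[0]}{motif.alt_base.lower()}{motif.pattern[2]}")
                assert (got.mut_motif, got.mut_class, got.ctx_motif,
                        got.ctx_base) == exp, motif.name

    def test_reverse_complement_invariance(self):
        ref = generate_reference(3000, gc=0.45, seed=9)
        records, _ = simulate_snv_catalogue(ref, 80, {"nCg": 20}, seed=10)
        rc_ref = ref.reverse_complemented()
        n = ref.length("chr1")
        rc_records = [
            make_snv(pos=n - r.pos + 1, ref=complement(r.ref),
                     alt=complement(r.alt))
            for r in records
        ]
        for motif in default_registry():
            cls = [r for r in records if motif.matches_class(r.ref, r.alt)]
            rc_cls = [r for r in rc_records if motif.matches_class(r.ref, r.alt)]
            a = count_motif_and_context(cls, ref, motif)
            b = count_motif_and_context(rc_cls, rc_ref, motif)
            assert a == b, motif.name


class TestEnrichmentArithmetic:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 100, 1000, 10000), 1.0),
        ((30, 100, 1000, 10000), 3.0),
    ])
    def test_examples(self, counts, expected):
        res = compute_enrichment(EnrichmentCounts(*counts))
        assert res.enrichment == pytest.approx(expected)

    def test_zero_denominator_is_nan(self):
        res = compute_enrichment(EnrichmentCounts(5, 100, 0, 10000))
        assert math.isnan(res.enrichment)
        assert math.isnan(res.motif_rate)

    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 5000), st.integers(0, 5000))
    @settings(max_examples=200, deadline=None)
    def test_identity_with_component_rates(self, a, b, c, d):
        mut_motif, mut_class = min(a, b), max(a, b)
        ctx_motif, ctx_base = min(c, d), max(c, d)
        res = compute_enrichment(
            EnrichmentCounts(mut_motif, mut_class, ctx_motif, ctx_base))
        if not math.isnan(res.enrichment) and res.background_rate > 0:
            assert res.enrichment == pytest.approx(
                res.motif_rate / res.background_rate, rel=1e-12)


class TestFisher:
    def test_no_evidence_gives_one(self):
        assert fisher_enrichment_test(EnrichmentCounts(0, 10, 5, 100)) == 1.0

    def test_hypergeometric_oracle(self):
        counts = EnrichmentCounts(5, 10, 5, 105)
        # table [[5, 5], [5, 100]]
        assert fisher_enrichment_test(counts) == pytest.approx(
            oracles.fisher_greater(5, 5, 5, 100), abs=1e-12)

    def test_proportional_counts_not_significant(self):
        p = fisher_enrichment_test(EnrichmentCounts(10, 100, 1000, 10000))
        assert p >= 0.5


class TestMeml:
    def test_formula(self):
        c = EnrichmentCounts(100, 200, 100, 1000)
        assert compute_meml(c, enrichment=2.0, q=0.01) == pytest.approx(50.0)

    def test_zero_when_not_enriched(self):
        c = EnrichmentCounts(100, 200, 100, 1000)
        assert compute_meml(c, enrichment=0.8, q=0.001) == 0.0

    def test_zero_when_insignificant(self):
        c = EnrichmentCounts(100, 200, 100, 1000)
        assert compute_meml(c, enrichment=3.0, q=0.2) == 0.0

    def test_bounded_by_mut_motif(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 500))
            e = float(rng.uniform(0.1, 50))
            meml = compute_meml(EnrichmentCounts(m, m + 10, 10, 1000), e, q=0.01)
            assert 0 <= meml < max(m, 1)


class TestBH:
    def test_q_geq_p_and_monotone(self, rng):
        p = rng.uniform(0, 1, 40)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, math.nan, 0.5])
        assert math.isnan(q[1]) and not math.isnan(q[0])


class TestMotifPanel:
    def test_single_unit_bh_identity(self):
        ref = generate_reference(5000, seed=3)
        records, _ = simulate_snv_catalogue(ref, 50, seed=4)
        panel = motif_panel({"S1": records}, ref,
                            registry=[compile_motif("nCg>nTg")])
        row = panel.iloc[0]
        assert row.q == pytest.approx(row.p)

    def test_empty_catalogue_row(self):
        ref = generate_reference(2000, seed=5)
        panel = motif_panel({"S1": []}, ref, registry=[compile_motif("nCg>nTg")])
        row = panel.iloc[0]
        assert row.mut_class == 0 and math.isnan(row.enrichment) and row.meml == 0

    def test_donor_pooling_dedups_shared_variants(self):
        ref = generate_reference(5000, seed=6)
        records, _ = simulate_snv_catalogue(ref, 40, seed=7,
                                            sample_id="S1", donor_id="D1")
        import dataclasses
        dup = [dataclasses.replace(r, sample_id="S2") for r in records]
        panel = motif_panel({"S1": records, "S2": dup}, ref,
                            registry=[compile_motif("nCg>nTg")], level="donor")
        single = motif_panel({"S1": records}, ref,
                             registry=[compile_motif("nCg>nTg")])
        assert panel.iloc[0].mut_class == single.iloc[0].mut_class

    def test_prevalence(self):
        df = pd.DataFrame({
            "motif": ["m"] * 4, "meml": [0.0, 2.0, 3.0, 0.0],
        })
        assert meml_prevalence(df)["m"] == pytest.approx(0.5)


class TestPairFraction:
    def test_six_percent(self):
        records = [make_snv(pos=100 + 12 * i, ref="T", alt="C") for i in range(50)]
        records += [make_snv(pos=2000 + 12 * i, ref="A", alt="G") for i in range(50)]
        assert meml_pair_fraction(6.0, records, "AT") == pytest.approx(6.0)

    def test_zero_meml(self):
        records = [make_snv(ref="T", alt="C")]
        assert meml_pair_fraction(0.0, records, "AT") == 0.0

    def test_no_pair_mutations_is_nan(self):
        records = [make_snv(ref="C", alt="T")]
        assert math.isnan(meml_pair_fraction(5.0, records, "AT"))
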