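"""Amplicon allele extraction and editing-outcome statistics."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from xshred import alleles as al
from xshred import simulate as sim


@pytest.fixture(scope="module")
def ref_spec():
    rng = np.random.default_rng(17)
    left = "".join(rng.choice(list("ACGT"), size=60))
    right = "".join(rng.choice(list("ACGT"), size=70))
    window = "AACAGATCAAGAGGAAACATCGG"
    return al.AmpliconSpec(reference=left + window + right, window_start=60)


def _reads(seqs, quality=38):
    return [(f"r{i}", s, [quality] * len(s)) for i, s in enumerate(seqs)]


class TestQualityFilter:
    @pytest.mark.parametrize("q,kept", [(29, 0), (30, 1), (38, 1)])
    def test_mean_quality_boundary_inclusive(self, q, kept):
        reads = _reads(["ACGT" * 20], quality=q)
        out, dropped = al.quality_filter(reads)
        assert len(out) == kept and dropped == 1 - kept

    def test_empty_input(self):
        out, dropped = al.quality_filter([])
        assert out == [] and dropped == 0


class TestExtractAllele:
    def test_reference_read_is_intact(self, ref_spec):
        a = al.extract_allele(ref_spec.reference, ref_spec)
        assert a.is_intact(ref_spec) and a.net_indel == 0

    def test_four_bp_deletion_at_cut_site(self, ref_spec):
        cut = ref_spec.cut_position
        read = ref_spec.reference[: cut - 2] + ref_spec.reference[cut + 2 :]
        a = al.extract_allele(read, ref_spec)
        assert a.window.count("-") == 4
        assert a.net_indel == -4 and not a.is_intact(ref_spec)
        gap_start = a.window.index("-")
        assert abs(gap_start - ref_spec.cut_offset) <= 4  # at/near the cut

    def test_insertion_at_cut_site(self, ref_spec):
        cut = ref_spec.cut_position
        read = ref_spec.reference[:cut] + "TTA" + ref_spec.reference[cut:]
        a = al.extract_allele(read, ref_spec)
        assert a.window == ref_spec.window
        assert a.net_indel == 3 and len(a.insertions) == 1

    def test_equivalent_indel_representations_collapse(self, ref_spec):
        """A deletion in a repeated context maps to one left-aligned allele."""
        ref = ref_spec.reference
        ws = ref_spec.window_start
        # delete one of the two As in the '..GAGGAA..' run (positions 14,15)
        read1 = ref[: ws + 14] + ref[ws + 15 :]
        read2 = ref[: ws + 15] + ref[ws + 16 :]
        a1 = al.extract_allele(read1, ref_spec)
        a2 = al.extract_allele(read2, ref_spec)
        assert a1.key == a2.key

    def test_garbage_read_is_unalignable(self, ref_spec):
        read = "TG" * (len(ref_spec.reference) // 2)
        assert al.extract_allele(read, ref_spec) is None

    def test_truth_recovery_on_simulated_reads(self, genome):
        """Allele calls track the source repeat unit's truth allele: exactly
        for error-free reads, and within 1% of the unavoidable window-error
        bound (a sequencing error inside the 23-bp window legitimately
        changes the called allele) at 0.1% base error."""
        cl = genome.clusters[0]
        spec = al.AmpliconSpec(
            reference=cl.reference_amplicon, window_start=cl.window_start
        )
        model = sim.EditingModel(cycles=1, cleavage_prob=0.5, disrupting_repair_prob=0.9)
        haps, _ = sim.simulate_editing(cl, model, 1, seed=6)
        hap = haps[0]
        truth_keys = {
            u.amplicon: al.extract_allele(u.amplicon, spec).key for u in hap.units
        }
        amps = hap.surviving_amplicons()
        for err, floor in ((0.0, 1.0), (0.001, 0.999**23 - 0.01)):
            reads = sim.simulate_amplicon_reads(hap, depth=1_500, error_rate=err, seed=8)
            ok = total = exact_ok = exact_total = 0
            for _rid, seq, _ in reads:
                a = al.extract_allele(seq, spec)
                if a is None:
                    continue
                total += 1
                same_len = [amp for amp in amps if len(amp) == len(seq)]
                src = min(
                    same_len,
                    key=lambda amp: sum(x != y for x, y in zip(amp, seq)),
                    default=None,
                )
                hit = src is not None and a.key == truth_keys[src]
                ok += hit
                if seq == src:  # error-free read: call must be exact
                    exact_total += 1
                    exact_ok += hit
            assert total > 0 and ok / total >= floor
            assert exact_total > 0 and exact_ok == exact_total


class TestSampleStatistics:
    def test_intact_fraction_extremes_and_arithmetic(self, ref_spec):
        ref = ref_spec.reference
        cut = ref_spec.cut_position
        mutant = ref[: cut - 1] + ref[cut + 1 :]
        table_all = al.build_allele_table(_reads([ref] * 10), ref_spec)
        assert al.intact_fraction(table_all) == 1.0
        table_none = al.build_allele_table(_reads([mutant] * 10), ref_spec)
        assert al.intact_fraction(table_none) == 0.0
        table_mix = al.build_allele_table(_reads([ref] * 90 + [mutant] * 10), ref_spec)
        assert al.intact_fraction(table_mix) == pytest.approx(0.90)

    def test_intact_fraction_undefined_without_reads(self, ref_spec):
        table = al.build_allele_table([], ref_spec)
        assert math.isnan(al.intact_fraction(table))

    def test_frequencies_sum_to_one(self, ref_spec):
        ref = ref_spec.reference
        cut = ref_spec.cut_position
        variants = [ref, ref[: cut - 2] + ref[cut:], ref[:cut] + "GG" + ref[cut:]]
        table = al.build_allele_table(_reads(variants * 7), ref_spec)
        assert table["frequency"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_census_single_allele(self, ref_spec):
        table = al.build_allele_table(_reads([ref_spec.reference] * 50), ref_spec)
        c = al.census_alleles(table)
        assert c["freq_criterion"] == 1 and c["reads_criterion"] == 1
        assert c["freq_criterion_excl_wt"] == 0

    def test_census_thresholds_exclude_rare_allele(self, ref_spec):
        ref = ref_spec.reference
        cut = ref_spec.cut_position
        rare = ref[: cut - 1] + ref[cut:]
        reads = _reads([ref] * 991 + [rare] * 9)
        table = al.build_allele_table(reads, ref_spec)
        c = al.census_alleles(table)
        # 9 reads, 0.9% frequency: below both criteria
        assert c["freq_criterion"] == 1 and c["reads_criterion"] == 1

    def test_census_matches_direct_tally(self, ref_spec, rng):
        ref = ref_spec.reference
        cut = ref_spec.cut_position
        variants = [ref]
        for d in range(1, 6):
            variants.append(ref[: cut - d] + ref[cut:])
        counts = rng.multinomial(2_000, [0.6, 0.2, 0.1, 0.05, 0.03, 0.02])
        seqs = [v for v, n in zip(variants, counts) for _ in range(n)]
        table = al.build_allele_table(_reads(seqs), ref_spec)
        c = al.census_alleles(table)
        freq_tally = sum(1 for n in counts if n / 2_000 >= 0.01)
        reads_tally = sum(1 for n in counts if n >= 10)
        assert c["freq_criterion"] == freq_tally
        assert c["reads_criterion"] == reads_tally


class TestClassification:
    def _tables(self, ref_spec):
        ref = ref_spec.reference
        cut = ref_spec.cut_position
        pre = ref[: cut - 3] + ref[cut:]  # shared pre-existing variant
        novo = ref[:cut] + "AT" + ref[cut:]  # de-novo product
        ctrl1 = al.build_allele_table(_reads([ref] * 96 + [pre] * 4), ref_spec)
        ctrl2 = al.build_allele_table(_reads([ref] * 95 + [pre] * 5), ref_spec)
        exp = al.build_allele_table(_reads([ref] * 60 + [pre] * 25 + [novo] * 15), ref_spec)
        return {"c1": ctrl1, "c2": ctrl2, "m1": exp}, pre, novo

    def test_classes_recovered(self, ref_spec):
        tables, pre, novo = self._tables(ref_spec)
        classes = al.classify_alleles(tables, ["c1", "c2"])
        key_pre = al.extract_allele(pre, ref_spec).key
        key_novo = al.extract_allele(novo, ref_spec).key
        key_wt = al.extract_allele(ref_spec.reference, ref_spec).key
        assert classes.loc[key_pre, "class"] == "pre-existing"
        assert classes.loc[key_novo, "class"] == "de-novo"
        assert classes.loc[key_wt, "class"] == "intact"

    def test_no_controls_refused(self, ref_spec):
        tables, _, _ = self._tables(ref_spec)
        with pytest.raises(ValueError, match="control"):
            al.classify_alleles(tables, [])

    def test_unknown_control_id_refused(self, ref_spec):
        tables, _, _ = self._tables(ref_spec)
        with pytest.raises(ValueError, match="not in tables"):
            al.classify_alleles(tables, ["nope"])


class TestResistance:
    def test_pam_and_target_mutated_allele_is_resistant(self, ref_spec):
        allele = al.Allele(window="AACAAATCAAGAGGAAACATCAG")
        flag, ev = al.flag_resistant(allele, ref_spec)
        assert flag and ev["pam_mutated"]

    def test_reference_window_not_resistant(self, ref_spec):
        assert not al.flag_resistant(al.Allele(window=ref_spec.window), ref_spec)[0]

    def test_distal_substitution_with_intact_pam_not_resistant(self, ref_spec):
        w = list(ref_spec.window)
        w[0] = "T" if w[0] != "T" else "C"
        flag, ev = al.flag_resistant(al.Allele(window="".join(w)), ref_spec)
        assert not flag and ev["distal_substitutions"] == [0]

    def test_seed_substitution_is_resistant(self, ref_spec):
        w = list(ref_spec.window)
        w[15] = "T" if w[15] != "T" else "C"
        flag, ev = al.flag_resistant(al.Allele(window="".join(w)), ref_spec)
        assert flag and ev["seed_substitutions"] == [15]

    def test_indel_is_resistant(self, ref_spec):
        w = ref_spec.window[:10] + "-" + ref_spec.window[11:]
        assert al.flag_resistant(al.Allele(window=w), ref_spec)[0]


class TestFrequencySummary:
    def test_median_over_experimental_samples(self, ref_spec):
        ref = ref_spec.reference
        cut = ref_spec.cut_position
        var = ref[: cut - 2] + ref[cut:]
        key = al.extract_allele(var, ref_spec).key
        tables = {"ctrl": al.build_allele_table(_reads([ref] * 10), ref_spec)}
        for name, n_var in (("m1", 1), ("m2", 2), ("m3", 3)):
            tables[name] = al.build_allele_table(
                _reads([ref] * (10 - n_var) + [var] * n_var), ref_spec
            )
        out = al.allele_frequency_summary(tables, ["ctrl"])
        assert out.loc[key, "median_experimental"] == pytest.approx(0.2)
        assert out.loc[key, "ctrl"] == 0.0

    def test_single_sample_median_is_value(self, ref_spec):
        t = {"m": al.build_allele_table(_reads([ref_spec.reference] * 5), ref_spec)}
        out = al.allele_frequency_summary(t, [])
        assert (out["median_experimental"] == out["m"]).all()


class TestLinkedMarker:
    @pytest.fixture()
    def marker_spec(self, genome):
        cl = genome.clusters[0]
        assert cl.marker_span is not None
        a, b = cl.marker_span
        return al.AmpliconSpec(
            reference=cl.reference_amplicon,
            window_start=cl.window_start,
            marker=al.Marker(a, cl.reference_amplicon[a:b], ""),
        ), cl

    def test_perfect_linkage_not_dissociated(self, marker_spec):
        spec, cl = marker_spec
        resistant_amp = cl.units[11].amplicon_seq
        reads = _reads([spec.reference] * 500 + [resistant_amp] * 100)
        out = al.linked_marker_dissociation(reads, spec)
        assert out["n_resistant_reads"] == 100
        assert out["n_dissociated"] == 0 and not out["dissociation_detected"]

    @staticmethod
    def _conversion_read(spec):
        """Resistant target window spliced onto the reference backbone:
        the marker keeps its reference form (a gene-conversion product)."""
        ref, ws = spec.reference, spec.window_start
        nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
        return (
            ref[: ws + 4]
            + nxt[ref[ws + 4]]
            + ref[ws + 5 : ws + 21]
            + "A"  # central PAM G -> A
            + ref[ws + 22 :]
        )

    def test_half_dissociated_detected(self, marker_spec):
        spec, cl = marker_spec
        resistant_amp = cl.units[11].amplicon_seq
        converted = self._conversion_read(spec)
        reads = _reads([resistant_amp] * 50 + [converted] * 50)
        out = al.linked_marker_dissociation(reads, spec, error_rate=0.001)
        assert out["n_dissociated"] == 50
        assert out["dissociation_detected"] and out["p_value"] < 1e-6

    def test_conversion_power_at_depth(self, marker_spec):
        """5% gene-conversion reads at depth 5000 are detected with power >= 0.9."""
        spec, cl = marker_spec
        resistant_amp = cl.units[11].amplicon_seq
        converted = self._conversion_read(spec)
        rng = np.random.default_rng(123)
        detected = 0
        n_rep = 20
        for _ in range(n_rep):
            n_res = 1_000  # resistant read pool within a 5000-read sample
            n_conv = rng.binomial(n_res, 0.05)
            reads = _reads(
                [spec.reference] * 4_000
                + [resistant_amp] * (n_res - n_conv)
                + [converted] * n_conv
            )
            out = al.linked_marker_dissociation(reads, spec, error_rate=0.001)
            detected += out["dissociation_detected"]
        assert detected / n_rep >= 0.9

    def test_marker_outside_amplicon_rejected(self, ref_spec):
        with pytest.raises(ValueError, match="marker"):
            al.AmpliconSpec(
                reference=ref_spec.reference,
                window_start=60,
                marker=al.Marker(10_000, "ACGTAC", ""),
            )

    def test_missing_marker_definition_rejected(self, ref_spec):
        with pytest.raises(ValueError, match="marker"):
            al.linked_marker_dissociation([], ref_spec)


class TestCodingEffect:
    @pytest.fixture()
    def coding_spec(self, ref_spec):
        return al.AmpliconSpec(
            reference=ref_spec.reference, window_start=60, frame=0
        )

    def test_two_bp_deletion_is_frameshift(self, coding_spec):
        cut = coding_spec.cut_position
        read = coding_spec.reference[: cut - 1] + coding_spec.reference[cut + 1 :]
        a = al.extract_allele(read, coding_spec)
        assert al.classify_coding_effect(a, coding_spec).kind == "frameshift"

    def test_three_bp_deletion_is_in_frame(self, coding_spec):
        cut = coding_spec.cut_position
        read = coding_spec.reference[: cut - 1] + coding_spec.reference[cut + 2 :]
        a = al.extract_allele(read, coding_spec)
        eff = al.classify_coding_effect(a, coding_spec)
        assert eff.kind == "in-frame indel" and eff.net_indel == -3

    def test_missense_matches_translation_oracle(self, coding_spec):
        ref = coding_spec.reference
        ws = coding_spec.window_start
        # change the first base of the codon at the window start
        pos = ws - ws % 3
        old = ref[pos]
        new = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
        mutated_window = list(coding_spec.window)
        mutated_window[pos - ws] = new
        a = al.Allele(window="".join(mutated_window))
        eff = al.classify_coding_effect(a, coding_spec)
        edited = ref[:pos] + new + ref[pos + 1 :]
        ref_aa = str(Seq(ref[: len(ref) - len(ref) % 3]).translate())
        alt_aa = str(Seq(edited[: len(edited) - len(edited) % 3]).translate())
        diff = [(i, r, x) for i, (r, x) in enumerate(zip(ref_aa, alt_aa)) if r != x]
        if diff:
            i, r, x = diff[0]
            assert eff.kind == "missense"
            assert eff.protein_change == f"{r}{i + 1}>{x}"
        else:
            assert eff.kind == "synonymous"

    def test_no_frame_warns_and_reports_none(self, ref_spec):
        a = al.Allele(window=ref_spec.window)
        with pytest.warns(UserWarning, match="frame"):
            eff = al.classify_coding_effect(a, ref_spec)
        assert eff.kind == "none"


class TestEstimatorCalibration:
    def test_intact_fraction_within_multinomial_envelope(self, genome):
        """Across 20 seeds, the estimated intact fraction stays inside the
        exact binomial 99% envelope of the simulated truth (<=1 excursion
        expected by construction of the envelope)."""
        from scipy import stats

        cl = genome.clusters[0]
        spec = al.AmpliconSpec(
            reference=cl.reference_amplicon, window_start=cl.window_start
        )
        model = sim.EditingModel(cycles=1, cleavage_prob=0.5, disrupting_repair_prob=0.9)
        outside = 0
        depth = 1_000
        for s in range(20):
            haps, _ = sim.simulate_editing(cl, model, 1, seed=300 + s)
            hap = haps[0]
            p_truth = sum(u.state == "intact" for u in hap.units) / 12
            reads = sim.simulate_amplicon_reads(hap, depth=depth, error_rate=0.0,
                                                seed=600 + s)
            est = al.intact_fraction(al.build_allele_table(reads, spec))
            lo, hi = stats.binom.interval(0.99, depth, p_truth)
            outside += not (lo / depth <= est <= hi / depth)
        assert outside <= 1
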