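"""Panel QC: parsing, Tm, cross-dimers, spacing, amplicon prediction."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plexcal.errors import DegeneracyError, InputError, SchemaError
from plexcal.iupac import (
    IUPAC_SETS,
    IUPAC_COMPLEMENT,
    expand_degenerate,
    reverse_complement,
)
from plexcal.panel import (
    PrimerPair,
    PrimerPanel,
    cross_dimer_score,
    degraded_dna_check,
    dimer_matrix,
    melting_temperature,
    parse_panel,
    predict_amplicon,
    run_panel_qc,
    spacing_check,
    tm_spread_check,
)

primer_seq = st.text(alphabet="ACGT", min_size=4, max_size=12)


def make_pair(fwd="ACGTACGTACGTACGTACGT", rev="TGCATGCATGCATGCATGCA",
              target="t", size=100, conc=0.2, multiplex=True):
    return PrimerPair(
        target_name=target, forward_name=f"{target}-F", forward_seq=fwd,
        reverse_name=f"{target}-R", reverse_seq=rev,
        concentration=conc, product_size=size, in_multiplex=multiplex,
    )


# ---------------------------------------------------------------------------
# Parsing


class TestParsePanel:
    def test_published_panel_fixture(self, table1_panel):
        assert len(table1_panel.multiplex_pairs) == 7
        assert len(table1_panel.pairs) == 8
        sizes = sorted(p.product_size for p in table1_panel.multiplex_pairs)
        assert sizes == [86, 107, 129, 144, 167, 198, 228]
        singleplex = [p for p in table1_panel.pairs if not p.in_multiplex]
        assert len(singleplex) == 1 and singleplex[0].product_size == 210

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("")
        with pytest.raises(SchemaError):
            parse_panel(f)

    def test_duplicate_multiplex_target(self, fixture_dir, tmp_path):
        df = pd.read_csv(fixture_dir / "panel.tsv", sep="\t")
        dup = pd.concat([df, df[df.target == "Collembola"]])
        f = tmp_path / "dup.tsv"
        dup.to_csv(f, sep="\t", index=False)
        with pytest.raises(SchemaError, match="duplicate"):
            parse_panel(f)

    def test_malformed_sequence_reports_row(self, fixture_dir, tmp_path):
        df = pd.read_csv(fixture_dir / "panel.tsv", sep="\t")
        df.loc[0, "fwd_seq"] = "ACGTX"
        f = tmp_path / "bad.tsv"
        df.to_csv(f, sep="\t", index=False)
        with pytest.raises(SchemaError, match="row 2"):
            parse_panel(f)


# ---------------------------------------------------------------------------
# Melting temperature


class TestMeltingTemperature:
    @pytest.mark.parametrize("seq,tm", [("AAAA", 8.0), ("ACGT", 12.0)])
    def test_wallace_examples(self, seq, tm):
        est = melting_temperature(seq, method="wallace")
        assert est.minimum == est.mean == est.maximum == tm

    def test_wallace_matches_biopython(self):
        from Bio.SeqUtils import MeltingTemp

        seq = "CTGTTTATCCTCCTTTAGCATCTAC"
        est = melting_temperature(seq, method="wallace")
        assert est.mean == pytest.approx(float(MeltingTemp.Tm_Wallace(seq)))

    def test_degenerate_expansion_statistics(self):
        # Col3F has one Y and two R sites -> 8 expansions; brute-force oracle
        seq = "GGACGATYTTRTTRGTTCGT"
        est = melting_temperature(seq, method="wallace")
        assert est.n_expansions == 8
        expected = []
        for exp in expand_degenerate(seq):
            at = sum(exp.count(b) for b in "AT")
            expected.append(2.0 * at + 4.0 * (len(exp) - at))
        assert est.minimum == min(expected)
        assert est.maximum == max(expected)
        # each degenerate site resolves A/T (2 °C) or G/C (4 °C)
        assert est.maximum - est.minimum == 6.0

    def test_expansion_cap(self):
        with pytest.raises(DegeneracyError):
            melting_temperature("N" * 4, degeneracy_cap=64)

    def test_nearest_neighbor_plausible(self):
        est = melting_temperature(
            "CTGTTTATCCTCCTTTAGCATCTAC", method="nearest_neighbor"
        )
        assert 40.0 < est.mean < 75.0

    def test_nearest_neighbor_length_floor(self):
        with pytest.raises(InputError):
            melting_temperature("ACGT", method="nearest_neighbor")


class TestTmSpread:
    def test_identical_primers_pass(self):
        pairs = tuple(
            make_pair(target=f"t{i}", size=100 + 25 * i) for i in range(3)
        )
        panel = PrimerPanel(pairs=pairs)
        finding = tm_spread_check(panel)
        assert finding.spread == 0.0 and finding.passed

    def test_spread_beyond_tolerance_fails(self):
        # 20-mers: 16 A/T + 4 G/C -> 48 °C; 10 A/T + 10 G/C -> 60 °C
        cool = "AT" * 8 + "GC" * 2
        warm = "AT" * 5 + "GC" * 5
        panel = PrimerPanel(pairs=(
            make_pair(fwd=cool, rev=cool, target="a", size=100),
            make_pair(fwd=warm, rev=warm, target="b", size=150),
        ))
        finding = tm_spread_check(panel, tolerance=5.0)
        assert finding.spread == pytest.approx(12.0)
        assert not finding.passed

    def test_published_panel_reports_both_methods(self, table1_panel):
        wallace = tm_spread_check(table1_panel, tolerance=10.0, method="wallace")
        nn = tm_spread_check(table1_panel, tolerance=10.0,
                             method="nearest_neighbor")
        assert wallace.spread > 0 and nn.spread > 0
        assert len(wallace.tm_by_primer) == 14


# ---------------------------------------------------------------------------
# Cross-dimers


def brute_force_dimer(a: str, b: str) -> tuple[int, int]:
    """Independent enumeration: every antiparallel pairing a[i]:b[j] lies on
    an anti-diagonal i + j = s; scan each diagonal for complementary runs.

    Returns (longest run, longest run touching either 3' terminus).
    """
    def complementary(x, y):
        return bool(IUPAC_SETS[x] & IUPAC_SETS[IUPAC_COMPLEMENT[y]])

    best = anchored = 0
    for s in range(len(a) + len(b) - 1):
        run = 0
        for i in range(len(a)):
            j = s - i
            if not 0 <= j < len(b):
                continue
            if complementary(a[i], b[j]):
                run += 1
                best = max(best, run)
                # run spans a[i-run+1..i] pairing b[j..j+run-1]
                if i == len(a) - 1 or j + run - 1 == len(b) - 1:
                    anchored = max(anchored, run)
            else:
                run = 0
    return best, anchored


class TestCrossDimer:
    def test_perfect_duplex(self):
        a = "ACGTTGCAGT"
        d = cross_dimer_score(a, reverse_complement(a))
        assert d.score == len(a)
        assert d.three_prime_anchored

    def test_self_incompatible_homopolymer(self):
        d = cross_dimer_score("AAAAAAAAAA", "AAAAAAAAAA")
        assert d.score == 0

    def test_three_prime_tail(self):
        # both primers end in mutually complementary 6-mers
        tail = "GCCGGC"
        a = "TTTTTTTT" + tail
        # T-rich bodies cannot pair with each other, so only the tails interact
        b = "TTTTTTTT" + reverse_complement(tail)
        d = cross_dimer_score(a, b)
        assert d.score == 6
        assert d.anchored_score == 6
        assert d.three_prime_anchored

    def test_degenerate_codes_pair_by_set_intersection(self):
        # R (A/G) can pair with Y (C/T): A:T and G:C both possible
        d = cross_dimer_score("AAARAAA", "TTTYTTT")
        assert d.score == 7

    @given(primer_seq, primer_seq)
    def test_symmetry(self, a, b):
        assert cross_dimer_score(a, b).score == cross_dimer_score(b, a).score

    @given(primer_seq, primer_seq)
    def test_reverse_complement_invariance(self, a, b):
        assert (
            cross_dimer_score(a, b).score
            == cross_dimer_score(reverse_complement(a), reverse_complement(b)).score
        )

    @given(primer_seq, primer_seq)
    def test_brute_force_oracle(self, a, b):
        expected_score, expected_anchored = brute_force_dimer(a, b)
        d = cross_dimer_score(a, b)
        assert (d.score, d.anchored_score) == (expected_score, expected_anchored)


class TestDimerMatrix:
    def test_combination_count(self):
        # 8 multiplex pairs = 16 primers -> C(16,2) + 16 self-pairs = 136
        pairs = tuple(
            make_pair(fwd="ACGT" * 5, rev="TTGCA" * 4, target=f"t{i}",
                      size=100 + 21 * i)
            for i in range(8)
        )
        findings = dimer_matrix(PrimerPanel(pairs=pairs))
        assert len(findings) == 136

    def test_planted_complementary_pair_flagged(self):
        clean = "ATATATATTATA"
        planted = reverse_complement("GCACGTGCGT") + "AA"
        pairs = (
            make_pair(fwd=clean, rev="GCACGTGCGT" + "TT", target="a", size=100),
            make_pair(fwd=planted, rev=clean, target="b", size=130),
        )
        findings = dimer_matrix(PrimerPanel(pairs=pairs), score_threshold=8)
        flagged = {(f.primer_a, f.primer_b) for f in findings if f.failed}
        assert ("a-R", "b-F") in flagged


# ---------------------------------------------------------------------------
# Spacing and length rules


class TestSpacing:
    def test_published_sizes_on_capillary(self, table1_panel):
        findings = spacing_check(table1_panel)
        gaps = [f.gap for f in findings]
        assert gaps == [21, 22, 15, 23, 31, 30]
        failed = [f for f in findings if not f.passed]
        assert len(failed) == 1
        assert (failed[0].size_low, failed[0].size_high) == (129, 144)

    def test_agarose_wide_gap_passes(self):
        pairs = (make_pair(target="a", size=100), make_pair(target="b", size=150))
        panel = PrimerPanel(pairs=pairs, platform="agarose")
        findings = spacing_check(panel)
        assert len(findings) == 1 and findings[0].passed

    def test_agarose_scales_above_300bp(self):
        pairs = (make_pair(target="a", size=400), make_pair(target="b", size=435))
        panel = PrimerPanel(pairs=pairs, platform="agarose")
        (finding,) = spacing_check(panel)
        assert finding.required_gap == pytest.approx(40.0)
        assert not finding.passed

    def test_single_product_vacuous(self):
        panel = PrimerPanel(pairs=(make_pair(),))
        assert spacing_check(panel) == []

    def test_permutation_invariance(self, table1_panel):
        shuffled = PrimerPanel(
            pairs=tuple(reversed(table1_panel.pairs)),
            platform=table1_panel.platform,
        )
        assert spacing_check(shuffled) == spacing_check(table1_panel)


class TestDegradedDna:
    def test_published_sizes_all_below_limit(self, fixture_dir):
        panel = parse_panel(fixture_dir / "panel.tsv", degraded_dna_mode=True)
        findings = degraded_dna_check(panel)
        assert len(findings) == 7 and all(f.passed for f in findings)

    def test_boundary_is_strict(self):
        panel = PrimerPanel(pairs=(make_pair(size=300),), degraded_dna_mode=True)
        (finding,) = degraded_dna_check(panel)
        assert not finding.passed

    def test_mode_off_yields_nothing(self):
        panel = PrimerPanel(pairs=(make_pair(size=500),), degraded_dna_mode=False)
        assert degraded_dna_check(panel) == []


# ---------------------------------------------------------------------------
# Amplicon prediction


class TestPredictAmplicon:
    def test_constructed_template(self):
        pair = make_pair(size=90)
        template = pair.forward_seq + "A" * 50 + reverse_complement(pair.reverse_seq)
        hits = predict_amplicon(template, pair)
        assert hits == [(0, len(template), len(pair.forward_seq) + 50
                         + len(pair.reverse_seq))]

    def test_degenerate_primer_matches_concrete_base(self):
        pair = make_pair(fwd="ACGTYACGTYACGTYACGTY", size=90)
        concrete = pair.forward_seq.replace("Y", "C")
        template = concrete + "G" * 40 + reverse_complement(pair.reverse_seq)
        assert len(predict_amplicon(template, pair)) == 1

    def test_missing_reverse_site_gives_empty_list(self):
        pair = make_pair(size=90)
        template = pair.forward_seq + "A" * 80
        assert predict_amplicon(template, pair) == []

    def test_fixture_round_trip(self, fixture_dir, table1_panel):
        from plexcal.io import read_fasta
        from plexcal.fixtures import row_slug, PANEL_ROWS

        fasta = dict(read_fasta(fixture_dir / "templates.fasta"))
        by_target = {(p.target_name, p.in_multiplex): p for p in table1_panel.pairs}
        for row in PANEL_ROWS:
            pair = by_target[(row[0], row[7])]
            hits = predict_amplicon(fasta[row_slug(row)], pair)
            assert hits == [(0, pair.product_size, pair.product_size)]


class TestFullReport:
    def test_published_panel_report(self, table1_panel):
        report = run_panel_qc(table1_panel)
        # the 129/144 bp spacing sits below the capillary rule, so the
        # report surfaces a failure rather than silently passing
        assert not report.overall_pass
        assert any(not f.passed for f in report.spacing_findings)
        doc = report.to_dict()
        assert set(doc) >= {"tm", "dimers", "spacing", "length", "overall_pass"}
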