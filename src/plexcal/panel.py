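"""Multiplex primer-panel QC.

Checks a panel against the design rules that make a multiplex assay
workable: balanced primer melting temperatures, absence of primer
cross-dimers (especially 3'-anchored ones, which polymerase can extend),
amplicon size spacing resolvable on the chosen separation platform, a
length ceiling when degraded DNA is targeted, and degeneracy-aware
in-silico amplicon prediction against template sequences.

Dimer detection is an ungapped complementarity-run scan with base-set
semantics for IUPAC degenerate codes — auditable and exactly checkable by
enumeration, unlike thermodynamic duplex energies.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqUtils import MeltingTemp

from .errors import InputError, SchemaError
from .iupac import (
    IUPAC_SETS,
    expand_degenerate,
    reverse_complement,
    validate_iupac,
)

PLATFORMS = ("agarose", "capillary", "sequencer")

#: Minimum resolvable size gap (bp) between adjacent amplicons.
#: Agarose scales with fragment size; see :func:`required_gap`.
CAPILLARY_MIN_GAP = 20
AGAROSE_MIN_GAP_SMALL = 30
AGAROSE_SMALL_LIMIT = 300
SEQUENCER_MIN_GAP = 1

PANEL_COLUMNS = [
    "target", "fwd_name", "fwd_seq", "rev_name", "rev_seq",
    "conc_uM", "size_bp", "in_multiplex",
]


@dataclass(frozen=True)
class PrimerPair:
    target_name: str
    forward_name: str
    forward_seq: str
    reverse_name: str
    reverse_seq: str
    concentration: float  # µM final in the reaction
    product_size: int  # bp
    in_multiplex: bool = True

    def __post_init__(self) -> None:
        fwd = validate_iupac(self.forward_seq, context=self.forward_name)
        rev = validate_iupac(self.reverse_seq, context=self.reverse_name)
        if not fwd or not rev:
            raise InputError(f"{self.target_name}: empty primer sequence")
        if self.concentration <= 0:
            raise InputError(f"{self.target_name}: concentration must be positive")
        if self.product_size < len(fwd) + len(rev):
            raise InputError(
                f"{self.target_name}: product size {self.product_size} bp is "
                "smaller than the combined primer footprints"
            )
        object.__setattr__(self, "forward_seq", fwd)
        object.__setattr__(self, "reverse_seq", rev)

    @property
    def primers(self) -> list[tuple[str, str]]:
        return [(self.forward_name, self.forward_seq),
                (self.reverse_name, self.reverse_seq)]


@dataclass(frozen=True)
class PrimerPanel:
    pairs: tuple[PrimerPair, ...]
    platform: str = "capillary"
    degraded_dna_mode: bool = False

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise InputError(
                f"unknown platform {self.platform!r}; expected one of {PLATFORMS}"
            )
        seen: set[str] = set()
        for pair in self.multiplex_pairs:
            if pair.target_name in seen:
                raise SchemaError(
                    f"duplicate multiplex target {pair.target_name!r}"
                )
            seen.add(pair.target_name)

    @property
    def multiplex_pairs(self) -> tuple[PrimerPair, ...]:
        return tuple(p for p in self.pairs if p.in_multiplex)

    @property
    def multiplex_primers(self) -> list[tuple[str, str]]:
        """(name, sequence) for every primer taking part in the multiplex."""
        return [pr for pair in self.multiplex_pairs for pr in pair.primers]


def parse_panel(
    path: str | Path,
    platform: str = "capillary",
    degraded_dna_mode: bool = False,
) -> PrimerPanel:
    """Read a TSV/CSV panel definition into a :class:`PrimerPanel`.

    Expected columns: target, fwd_name, fwd_seq, rev_name, rev_seq, conc_uM,
    size_bp, in_multiplex. The delimiter is sniffed, so both TSV and CSV work.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise SchemaError(f"{path}: empty or undelimited panel file") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: panel has no rows")

    pairs = []
    for idx, row in df.iterrows():
        try:
            pairs.append(
                PrimerPair(
                    target_name=str(row["target"]),
                    forward_name=str(row["fwd_name"]),
                    forward_seq=str(row["fwd_seq"]),
                    reverse_name=str(row["rev_name"]),
                    reverse_seq=str(row["rev_seq"]),
                    concentration=float(row["conc_uM"]),
                    product_size=int(row["size_bp"]),
                    in_multiplex=_parse_bool(row["in_multiplex"]),
                )
            )
        except InputError as exc:
            raise SchemaError(f"{path}, row {idx + 2}: {exc}") from exc
    return PrimerPanel(pairs=tuple(pairs), platform=platform,
                       degraded_dna_mode=degraded_dna_mode)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "y"}:
        return True
    if text in {"false", "0", "no", "n"}:
        return False
    raise InputError(f"cannot interpret {value!r} as a boolean")


# ---------------------------------------------------------------------------
# Melting temperature


@dataclass(frozen=True)
class TmEstimate:
    """Tm statistics over the degeneracy expansions of one primer (°C)."""

    minimum: float
    mean: float
    maximum: float
    n_expansions: int

    @property
    def spread(self) -> float:
        return self.maximum - self.minimum


def _wallace_tm(seq: str) -> float:
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def melting_temperature(
    seq: str,
    method: str = "wallace",
    degeneracy_cap: int = 64,
    na_mM: float = 50.0,
    primer_nM: float = 250.0,
) -> TmEstimate:
    """Primer Tm, reported as min/mean/max over degeneracy expansions.

    ``wallace`` is the 2·(A+T) + 4·(G+C) rule of thumb; ``nearest_neighbor``
    uses the Biopython nearest-neighbour thermodynamics (SantaLucia 1997
    unified parameters) with the given monovalent-salt and primer
    concentrations. Non-degenerate primers yield min == mean == max.
    """
    seq = validate_iupac(seq, context="primer")
    expansions = expand_degenerate(seq, cap=degeneracy_cap)
    if method == "wallace":
        tms = [_wallace_tm(s) for s in expansions]
    elif method == "nearest_neighbor":
        if len(seq) < 8:
            raise InputError("nearest-neighbor Tm needs length >= 8")
        tms = [
            float(MeltingTemp.Tm_NN(s, Na=na_mM, dnac1=primer_nM, dnac2=primer_nM))
            for s in expansions
        ]
    else:
        raise InputError(f"unknown Tm method {method!r}")
    return TmEstimate(
        minimum=min(tms),
        mean=statistics.fmean(tms),
        maximum=max(tms),
        n_expansions=len(expansions),
    )


@dataclass(frozen=True)
class TmFinding:
    tm_by_primer: dict[str, TmEstimate]
    spread: float  # max mean Tm − min mean Tm across the panel, °C
    tolerance: float
    passed: bool


def tm_spread_check(
    panel: PrimerPanel,
    tolerance: float = 5.0,
    method: str = "wallace",
    degeneracy_cap: int = 64,
) -> TmFinding:
    """Check that all multiplex primer Tms sit within ``tolerance`` °C.

    Degenerate primers enter the spread through their mean-expansion Tm.
    """
    tms = {
        name: melting_temperature(seq, method=method, degeneracy_cap=degeneracy_cap)
        for name, seq in panel.multiplex_primers
    }
    means = [t.mean for t in tms.values()]
    spread = max(means) - min(means) if means else 0.0
    return TmFinding(tm_by_primer=tms, spread=spread, tolerance=tolerance,
                     passed=spread <= tolerance)


# ---------------------------------------------------------------------------
# Cross-dimer scan


@dataclass(frozen=True)
class DimerScore:
    """Longest ungapped complementarity run between two primers.

    ``score`` is the longest run over all antiparallel offsets;
    ``anchored_score`` the longest run that includes the 3' terminus of
    either primer (extensible by polymerase, hence the riskier kind).
    """

    score: int
    anchored_score: int
    three_prime_anchored: bool
    alignment: str


def cross_dimer_score(a: str, b: str) -> DimerScore:
    """Scan every ungapped antiparallel offset of two primers for dimers.

    Complementarity uses base-set semantics: degenerate codes pair when the
    base set of one intersects the complement set of the other. The score is
    symmetric in (a, b).
    """
    a = validate_iupac(a, context="primer a")
    b = validate_iupac(b, context="primer b")
    if not a or not b:
        raise InputError("primers must be non-empty")
    rc_b = reverse_complement(b)  # rc_b[m] pairs with b[len(b)-1-m]

    best = DimerScore(0, 0, False, "")
    best_run: tuple[int, int, int] | None = None  # (offset, start_in_a, length)
    best_anchored = 0

    for offset in range(-(len(b) - 1), len(a)):
        lo = max(0, offset)
        hi = min(len(a), offset + len(b))
        run = 0
        for i in range(lo, hi):
            if IUPAC_SETS[a[i]] & IUPAC_SETS[rc_b[i - offset]]:
                run += 1
            else:
                run = 0
                continue
            # run currently ends at i; anchored if it touches a's 3' end
            # (i == len(a)-1) or b's 3' end (rc index 0, i.e. i - offset
            # - run + 1 == 0).
            anchored = (i == len(a) - 1) or (i - offset - run + 1 == 0)
            if anchored:
                best_anchored = max(best_anchored, run)
            if run > best.score:
                best_run = (offset, i - run + 1, run)
                best = DimerScore(run, best_anchored, False, "")
    if best_run is None:
        return DimerScore(0, 0, False, "(no complementary positions)")

    alignment = _render_alignment(a, b, rc_b, best_run[0])
    return DimerScore(
        score=best.score,
        anchored_score=best_anchored,
        three_prime_anchored=best_anchored == best.score and best.score > 0,
        alignment=alignment,
    )


def _render_alignment(a: str, b: str, rc_b: str, offset: int) -> str:
    """Three-line rendering: a 5'→3', pairing bars, b 3'→5'."""
    pad_a = max(0, -offset)
    pad_b = max(0, offset)
    top = " " * pad_a + f"5'-{a}-3'"
    bottom = " " * pad_b + f"3'-{b[::-1]}-5'"
    bars = []
    for i in range(len(a)):
        m = i - offset
        if 0 <= m < len(b) and IUPAC_SETS[a[i]] & IUPAC_SETS[rc_b[m]]:
            bars.append("|")
        else:
            bars.append(" ")
    # bars sit under a's characters, which start after pad_a + the "5'-" prefix
    mid = " " * (pad_a + 3) + "".join(bars)
    return "\n".join([top, mid, bottom])


@dataclass(frozen=True)
class DimerFinding:
    primer_a: str
    primer_b: str
    score: int
    anchored_score: int
    alignment: str
    failed: bool


def dimer_matrix(
    panel: PrimerPanel,
    score_threshold: int = 8,
    anchored_threshold: int = 5,
) -> list[DimerFinding]:
    """Score every unordered multiplex primer combination, self-pairs included.

    A combination fails when its run length reaches ``score_threshold``
    anywhere or ``anchored_threshold`` at a 3' terminus.
    """
    primers = panel.multiplex_primers
    findings = []
    for i in range(len(primers)):
        for j in range(i, len(primers)):
            name_a, seq_a = primers[i]
            name_b, seq_b = primers[j]
            d = cross_dimer_score(seq_a, seq_b)
            findings.append(
                DimerFinding(
                    primer_a=name_a,
                    primer_b=name_b,
                    score=d.score,
                    anchored_score=d.anchored_score,
                    alignment=d.alignment,
                    failed=(d.score >= score_threshold
                            or d.anchored_score >= anchored_threshold),
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Size spacing and degraded-DNA checks


@dataclass(frozen=True)
class SpacingFinding:
    size_low: int
    size_high: int
    gap: int
    required_gap: float
    passed: bool


def required_gap(platform: str, lower_size: int) -> float:
    """Minimum resolvable gap between a fragment of ``lower_size`` and the next.

    Capillary electrophoresis resolves 20 bp differences; agarose needs
    >30 bp below 300 bp and, as a house rule, 10% of fragment size above;
    a sequencer resolves single base pairs (dye multiplexing not modelled).
    """
    if platform == "capillary":
        return CAPILLARY_MIN_GAP
    if platform == "agarose":
        if lower_size < AGAROSE_SMALL_LIMIT:
            return AGAROSE_MIN_GAP_SMALL
        return 0.10 * lower_size
    if platform == "sequencer":
        return SEQUENCER_MIN_GAP
    raise InputError(f"unknown platform {platform!r}")


def spacing_check(panel: PrimerPanel) -> list[SpacingFinding]:
    """Check adjacent multiplex product sizes against the platform's resolution."""
    sizes = sorted(p.product_size for p in panel.multiplex_pairs)
    findings = []
    for low, high in zip(sizes, sizes[1:]):
        req = required_gap(panel.platform, low)
        gap = high - low
        findings.append(
            SpacingFinding(size_low=low, size_high=high, gap=gap,
                           required_gap=req, passed=gap >= req)
        )
    return findings


@dataclass(frozen=True)
class LengthFinding:
    target_name: str
    product_size: int
    max_len: int
    passed: bool


def degraded_dna_check(panel: PrimerPanel, max_len: int = 300) -> list[LengthFinding]:
    """Flag products too long for degraded template DNA (rule: < ``max_len`` bp).

    Inactive (returns no findings) unless the panel is in degraded-DNA mode.
    """
    if not panel.degraded_dna_mode:
        return []
    return [
        LengthFinding(
            target_name=p.target_name,
            product_size=p.product_size,
            max_len=max_len,
            passed=p.product_size < max_len,
        )
        for p in panel.multiplex_pairs
    ]


# ---------------------------------------------------------------------------
# In-silico amplicon prediction


def _find_sites(template: str, primer: str) -> list[int]:
    """Start positions where the primer matches the template.

    Degenerate codes on either side match when their base sets intersect.
    """
    hits = []
    n, m = len(template), len(primer)
    for i in range(n - m + 1):
        if all(IUPAC_SETS[template[i + j]] & IUPAC_SETS[primer[j]] for j in range(m)):
            hits.append(i)
    return hits


def predict_amplicon(
    template: str,
    pair: PrimerPair,
    max_length: int = 2000,
) -> list[tuple[int, int, int]]:
    """Predict PCR products of a primer pair on a template strand.

    Returns (start, end, length) per product, 0-based half-open on the given
    strand, the product spanning both primer footprints. Exact
    degeneracy-compatible matching only — no mismatch tolerance. An empty
    list means no binding sites, which is not an error.
    """
    template = validate_iupac(template, context="template")
    fwd_sites = _find_sites(template, pair.forward_seq)
    rc_rev = reverse_complement(pair.reverse_seq)
    rev_sites = _find_sites(template, rc_rev)

    products = []
    for f in fwd_sites:
        fwd_end = f + len(pair.forward_seq)
        for r in rev_sites:
            end = r + len(rc_rev)
            if r >= fwd_end and end - f <= max_length:
                products.append((f, end, end - f))
    products.sort()
    return products


# ---------------------------------------------------------------------------
# Full report


@dataclass(frozen=True)
class QCReport:
    tm: TmFinding
    dimer_findings: list[DimerFinding]
    spacing_findings: list[SpacingFinding]
    length_findings: list[LengthFinding]
    overall_pass: bool
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tm": {
                "spread": self.tm.spread,
                "tolerance": self.tm.tolerance,
                "passed": self.tm.passed,
                "per_primer": {
                    name: {"min": t.minimum, "mean": t.mean, "max": t.maximum,
                           "n_expansions": t.n_expansions}
                    for name, t in self.tm.tm_by_primer.items()
                },
            },
            "dimers": [
                {"primer_a": f.primer_a, "primer_b": f.primer_b,
                 "score": f.score, "anchored_score": f.anchored_score,
                 "failed": f.failed, "alignment": f.alignment}
                for f in self.dimer_findings
            ],
            "spacing": [
                {"size_low": f.size_low, "size_high": f.size_high, "gap": f.gap,
                 "required_gap": f.required_gap, "passed": f.passed}
                for f in self.spacing_findings
            ],
            "length": [
                {"target": f.target_name, "size_bp": f.product_size,
                 "max_len": f.max_len, "passed": f.passed}
                for f in self.length_findings
            ],
            "overall_pass": self.overall_pass,
            "notes": list(self.notes),
        }


def run_panel_qc(
    panel: PrimerPanel,
    tm_tolerance: float = 5.0,
    tm_method: str = "wallace",
    dimer_score_threshold: int = 8,
    dimer_anchored_threshold: int = 5,
    degraded_max_len: int = 300,
    degeneracy_cap: int = 64,
) -> QCReport:
    """Run every panel check and aggregate into a single pass/fail report."""
    tm = tm_spread_check(panel, tolerance=tm_tolerance, method=tm_method,
                         degeneracy_cap=degeneracy_cap)
    dimers = dimer_matrix(panel, score_threshold=dimer_score_threshold,
                          anchored_threshold=dimer_anchored_threshold)
    spacing = spacing_check(panel) if len(panel.multiplex_pairs) >= 2 else []
    length = degraded_dna_check(panel, max_len=degraded_max_len)
    notes = (
        "agarose spacing above 300 bp uses a 10%-of-size house rule",
        "report coordinates are 1-based inclusive in text, 0-based half-open in data",
    )
    overall = (
        tm.passed
        and not any(f.failed for f in dimers)
        and all(f.passed for f in spacing)
        and all(f.passed for f in length)
    )
    return QCReport(tm=tm, dimer_findings=dimers, spacing_findings=spacing,
                    length_findings=length, overall_pass=overall, notes=notes)
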