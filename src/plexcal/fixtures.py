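"""Fixture generator: the published primer panel plus synthetic companion data.

The panel table transcribes the published seven-plex assay for high-Alpine
arthropod gut-content analysis (COI targets for four *Nebria*/*Oreonebria*
ground beetles, *Pardosa* wolf spiders and *Mitopus glacialis*, plus an 18S
Collembola pair) together with its singleplex verification pair. Middle-dot
decimals of the printed table ("0·2") are normalised to ASCII ("0.2").

Everything else here is SYNTHETIC and labelled as such: the true amplicon
sequences live in GenBank and are deliberately not fetched, so template
FASTA records are random filler flanked by the real primer footprints at
the printed product lengths; concentration replicates and the RFU
sensitivity grid come from documented toy models that encode the assay's
narrative behaviour (full detection at >= 20 copies, partial at 7, none at
5), purely so the toolkit is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .balancing import CONDITIONS
from .config import RunConfig
from .io import write_fasta
from .iupac import first_expansion, reverse_complement
from .panel import PANEL_COLUMNS, PrimerPanel, parse_panel

# (target, fwd_name, fwd_seq, rev_name, rev_seq, conc_uM, size_bp, in_multiplex)
PANEL_ROWS: list[tuple] = [
    ("Pardosa spp.", "Pard-sp-S238", "CTGTTTATCCTCCTTTAGCATCTAC",
     "Pard-sp-A239", "AGCCCCAGCTAAATGAAGAG", 0.2, 86, True),
    ("Nebria rufescens", "Neb-ruf-S249", "TCAGTCGGAATTACTGCATTAC",
     "Neb-ruf-A250", "GGGTCAAAGAAAGTTGTATTTAAG", 0.1, 107, True),
    ("Oreonebria castanea", "Ore-cas-S240", "CTCTGTTGACTTAGCTATTTTCAGA",
     "Ore-cas-A241", "AATAAAGGTATTCGATCAAAGGA", 0.2, 129, True),
    ("Mitopus glacialis", "Mit-gla-S243", "TATACCCCCCTCTATCAAGAAAT",
     "Mit-gla-A244", "TACCTTGTGTTCGTATGTTGATG", 0.1, 144, True),
    ("Nebria jockischii", "Neb-joc-S242", "GTGAACAGTTTACCCTCCACTG",
     "Neb-joc-A243", "TTCGGTCAAAAGTTATACCAATT", 0.1, 167, True),
    ("Nebria germari", "Neb-ger-S241", "CGAATGAATAATATAAGATTTTGACTT",
     "Neb-ger-A242", "AGCCCCTAAAATTGAAGAAATA", 0.4, 198, True),
    ("Collembola", "Col3F", "GGACGATYTTRTTRGTTCGT",
     "Col-gen-A246", "TTTCACCTCTAACGTCGCAG", 0.4, 228, True),
    ("Nebria germari", "Neb-ger-S256", "ATTAGGAAACCCTGGGTCC",
     "Neb-ger-A255", "AGTTAATGAAGGGGGAAGAAG", 1.0, 210, False),
]

#: Standardised-mix copy numbers per target (dilution series endpoints 10000
#: and 5 copies/µL; M1–M4 are the printed template mixes).
MIX_LEVELS: dict[str, float] = {
    "stock": 10000, "M1": 2100, "M2": 1000, "M3": 200, "M4": 100, "floor": 5,
}

#: Copy levels of the synthetic sensitivity grid: the series floor (5), the
#: narrative partial-detection level (7), the LOD bracket (20, 30) and two
#: comfortably detectable levels.
GRID_COPY_LEVELS = (5.0, 7.0, 20.0, 30.0, 100.0, 1000.0)


def panel_dataframe() -> pd.DataFrame:
    return pd.DataFrame(PANEL_ROWS, columns=PANEL_COLUMNS)


def target_slug(name: str) -> str:
    """FASTA-safe id: header id is read up to the first whitespace."""
    return name.replace(" ", "_").replace(".", "")


def row_slug(row: tuple) -> str:
    """Unique fragment id per panel row (the verification pair shares its
    target with a multiplex pair and is suffixed)."""
    slug = target_slug(row[0])
    return slug if row[7] else f"{slug}_verification"


@dataclass(frozen=True)
class Fixture:
    panel_table: pd.DataFrame
    mix_levels: dict[str, float]
    synthetic_readings: pd.DataFrame
    synthetic_fasta: list[tuple[str, str]]
    measurements: pd.DataFrame
    directory: Path


def synthetic_template(
    fwd_seq: str, rev_seq: str, product_size: int, rng: np.random.Generator
) -> str:
    """SYNTHETIC amplicon: real primer footprints, random filler between.

    Degenerate primer positions are resolved to their alphabetically first
    base so a degeneracy-aware matcher still finds the footprint. Not a
    biological sequence.
    """
    fwd = first_expansion(fwd_seq)
    rev_rc = reverse_complement(first_expansion(rev_seq))
    filler_len = product_size - len(fwd) - len(rev_rc)
    filler = "".join(rng.choice(list("ACGT"), size=filler_len))
    return fwd + filler + rev_rc


def synthetic_measurements(rng: np.random.Generator) -> pd.DataFrame:
    """SYNTHETIC triplicate fluorometry: cleaned PCR products at 10–50 ng/µL
    with 2% replicate scatter."""
    rows = []
    for row in PANEL_ROWS:
        base = rng.uniform(10.0, 50.0)
        reps = np.maximum(base * (1.0 + rng.normal(0.0, 0.02, size=3)), 0.0)
        rows.append({
            "fragment_id": row_slug(row),
            "rep1": round(reps[0], 3),
            "rep2": round(reps[1], 3),
            "rep3": round(reps[2], 3),
        })
    return pd.DataFrame(rows)


def synthetic_readings(rng: np.random.Generator, replicates: int = 3) -> pd.DataFrame:
    """SYNTHETIC RFU sensitivity grid encoding the assay narrative.

    Toy model per (target, condition, level, replicate):
      level >= 20 copies  -> detected, RFU uniform in [0.3, 1.5]
      level == 7 copies   -> unstable: the last replicate fails
                             (RFU in [0.02, 0.08]), the rest detect weakly
                             (RFU in [0.12, 0.25])
      level == 5 copies   -> undetected, RFU uniform in [0.0, 0.08]
    """
    targets = [r[0] for r in PANEL_ROWS if r[7]]
    rows = []
    for target in targets:
        for cond in CONDITIONS:
            for level in GRID_COPY_LEVELS:
                for rep in range(1, replicates + 1):
                    if level >= 20:
                        rfu = rng.uniform(0.3, 1.5)
                    elif level == 7:
                        rfu = (rng.uniform(0.02, 0.08) if rep == replicates
                               else rng.uniform(0.12, 0.25))
                    else:
                        rfu = rng.uniform(0.0, 0.08)
                    rows.append({
                        "target": target,
                        "copies": level,
                        "condition": cond,
                        "replicate": rep,
                        "rfu": round(float(rfu), 4),
                    })
    return pd.DataFrame(rows)


def toy_response_model(
    seed: int, targets: tuple[str, ...] | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """SYNTHETIC monotone concentration → RFU response for balancing tests.

    Returns (efficiencies, starting concentrations). Signal is linear,
    ``rfu = efficiency * concentration_uM``, with per-target efficiencies
    uniform in [0.7, 1.4] — the kind of spread an unbalanced panel shows.
    Starting concentrations sit on the 0.1 µM grid in [0.4, 0.8] µM: in that
    range one 0.1 µM step moves a signal by at most 25%, within the default
    balance band, so the ±step rule converges instead of hunting. (Below
    ~0.3 µM the grid is too coarse relative to a proportional band and the
    loop correctly reports oscillation — a property of the rule, not a bug.)
    """
    if targets is None:
        targets = tuple(r[0] for r in PANEL_ROWS if r[7])
    rng = np.random.default_rng(seed)
    eff = {t: float(rng.uniform(0.7, 1.4)) for t in targets}
    start = {t: round(int(rng.integers(4, 9)) * 0.1, 10) for t in targets}
    return eff, start


def generate_fixture(out_dir: str | Path, seed: int = 1) -> Fixture:
    """Write the complete fixture directory; deterministic for a given seed.

    Files: panel.tsv (static transcription, byte-identical across runs),
    templates.fasta, measurements.csv, readings.csv, mix_levels.csv,
    config.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    panel_df = panel_dataframe()
    panel_df.to_csv(out / "panel.tsv", sep="\t", index=False)

    fasta = [
        (row_slug(row), synthetic_template(row[2], row[4], row[6], rng))
        for row in PANEL_ROWS
    ]
    write_fasta(fasta, out / "templates.fasta")

    measurements = synthetic_measurements(rng)
    measurements.to_csv(out / "measurements.csv", index=False)

    readings = synthetic_readings(rng)
    readings.to_csv(out / "readings.csv", index=False)

    pd.DataFrame(
        [{"mix": k, "copies_per_target": v} for k, v in MIX_LEVELS.items()]
    ).to_csv(out / "mix_levels.csv", index=False)

    RunConfig(seed=seed).save(out / "config.json")

    return Fixture(
        panel_table=panel_df,
        mix_levels=dict(MIX_LEVELS),
        synthetic_readings=readings,
        synthetic_fasta=fasta,
        measurements=measurements,
        directory=out,
    )


def load_fixture_panel(directory: str | Path, **kwargs) -> PrimerPanel:
    return parse_panel(Path(directory) / "panel.tsv", **kwargs)
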