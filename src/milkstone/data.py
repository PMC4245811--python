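"""Bundled reference data.

The shipped ortholog panel is a synthetic approximation of a dairy-species
beta-lactoglobulin panel (see the file's own header comment and
docs/methods.md): a bovine-type base sequence plus constructed species
variants carrying clade-structured substitutions, sufficient for
genus/species discrimination among cattle, buffalo, sheep, goat, reindeer
and horse. It is not a transcription of any sequence database.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def default_panel_fasta() -> Path:
    """Path to the bundled synthetic BLG ortholog panel FASTA."""
    return Path(str(resources.files("milkstone") / "data" / "synthetic_blg_panel.fasta"))


def default_panel(**kwargs):
    """Reference panel built from the bundled synthetic FASTA."""
    from .panel import ReferencePanel, load_fasta

    return ReferencePanel(load_fasta(default_panel_fasta()), **kwargs)


# Regional summary of the published archaeological dental-calculus survey
# this package models: per region, (date label, samples analyzed,
# BLG-positive individuals, matching spectra, pooled-extract note). The
# Norway row is a single pooled extract of five individuals that tested
# positive, counted as one positive sample.
SURVEY_ROWS: tuple[tuple[str, str, int, int, int, bool], ...] = (
    ("Britain", "ca. 800 BCE to 1895 CE", 33, 11, 128, False),
    ("Denmark", "ca. 3000-1500 BCE", 2, 0, 0, False),
    ("Norway", "1100-1700 CE", 5, 1, 43, True),
    ("Germany", "ca. 3000 BCE to 1200 CE", 9, 0, 0, False),
    ("Hungary", "ca. 3000-1500 BCE", 2, 1, 38, False),
    ("Italy", "ca. 2700 BCE to 200 CE", 17, 4, 11, False),
    ("Armenia", "ca. 2000-700 BCE", 4, 1, 2, False),
    ("Russia", "ca. 3000-1500 BCE", 2, 1, 8, False),
    ("St. Helena", "ca. 1840-1872 CE", 18, 0, 0, False),
    ("Eastern Settlement", "ca. 890-1230 CE", 2, 2, 38, False),
    ("Western Settlement", "ca. 1290-1430 CE", 4, 1, 1, False),
)

#: Rows belonging to the Eurasian survey (Europe + northern Southwest Asia).
EURASIAN_REGIONS: tuple[str, ...] = (
    "Britain", "Denmark", "Norway", "Germany", "Hungary", "Italy",
    "Armenia", "Russia",
)


def survey_samples():
    """The survey expanded to per-sample records (one synthetic
    :class:`~milkstone.assign.SampleResult` per individual, spectra counts
    distributed so the per-region totals match the published row)."""
    from .assign import SampleResult

    samples = []
    for region, dates, n, n_pos, spectra, pooled in SURVEY_ROWS:
        for i in range(n):
            positive = i < n_pos
            count = (spectra - (n_pos - 1)) if (positive and i == 0) else (1 if positive else 0)
            samples.append(
                SampleResult(
                    sample_id=f"{region.replace(' ', '')}-{i:02d}",
                    accepted_peptides=[],
                    consensus_taxon="Pecora" if positive else None,
                    total_blg_spectra=count,
                    pooled=pooled and i == 0,
                    region=region,
                    dates=dates,
                )
            )
    return samples
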