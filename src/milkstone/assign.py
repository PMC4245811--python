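"""Per-sample taxonomic consensus and protein coverage.

Accepted peptides carry a diagnostic taxon (the LCA of the panel species
that could have produced them); a sample's consensus call is the deepest
taxon compatible with all of its peptides, species-level hits are flagged
separately, and protein coverage is the union of peptide intervals mapped
onto the panel consensus sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .panel import ReferencePanel, Taxonomy, collapse

log = logging.getLogger(__name__)


@dataclass
class SampleResult:
    sample_id: str
    accepted_peptides: list[tuple[str, int, str | None]]  # (seq, spectra, taxon)
    consensus_taxon: str | None
    species_hits: set[str] = field(default_factory=set)
    multi_species: bool = False
    total_blg_spectra: int = 0
    coverage_pct: float = 0.0
    coverage_intervals: list[tuple[int, int]] = field(default_factory=list)
    pooled: bool = False
    region: str = ""
    dates: str = ""

    @property
    def positive(self) -> bool:
        """A sample counts BLG-positive with even one accepted spectrum."""
        return self.total_blg_spectra >= 1


def sample_consensus(
    sample_id: str,
    assignments: Sequence[tuple[str, str | None, int]],
    taxonomy: Taxonomy,
    pooled: bool = False,
    region: str = "",
    dates: str = "",
) -> SampleResult:
    """Consensus dairy-taxon call for one sample.

    ``assignments`` holds (peptide_seq, diagnostic_taxon, spectra_count).
    The consensus is the LCA of all non-None diagnostic taxa; species-level
    assignments (taxonomy leaves among the panel species) populate
    ``species_hits``; two or more distinct species set ``multi_species``.
    """
    taxa = [t for _, t, _ in assignments if t is not None]
    consensus = taxonomy.lca(taxa) if taxa else None
    # species-level = taxa with no child in the taxonomy (leaves)
    children_of = set(taxonomy.parent.values()) - {None}
    species_hits = {t for t in taxa if t not in children_of}
    total = sum(c for _, _, c in assignments)
    return SampleResult(
        sample_id=sample_id,
        accepted_peptides=[(s, c, t) for s, t, c in assignments],
        consensus_taxon=consensus,
        species_hits=species_hits,
        multi_species=len(species_hits) >= 2,
        total_blg_spectra=total,
        pooled=pooled,
        region=region,
        dates=dates,
    )


def map_peptide_to_consensus(
    peptide_seq: str, consensus: str, deamidation_aware: bool = True
) -> tuple[int, int] | None:
    """Leftmost exact match of the peptide on the consensus, under the
    I/L (and optionally N/D, Q/E) equivalence rules; None if absent."""
    hay = collapse(consensus, deamidation_aware)
    needle = collapse(peptide_seq, deamidation_aware)
    i = hay.find(needle)
    if i < 0:
        return None
    return (i, i + len(needle))


def coverage(intervals: Sequence[tuple[int, int]], consensus_length: int) -> float:
    """Percent of consensus residues covered by the union of half-open
    ``[start, end)`` intervals. Unrounded; round only when reporting."""
    if consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    for s, e in intervals:
        if not (0 <= s <= e <= consensus_length):
            raise ValueError(f"interval ({s}, {e}) outside [0, {consensus_length})")
    covered = 0
    last_end = 0
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            covered += e - s
            last_end = e
        last_end = max(last_end, e)
    return 100.0 * covered / consensus_length


def sample_coverage(
    peptide_seqs: Sequence[str],
    panel: ReferencePanel,
    deamidation_aware: bool | None = None,
) -> tuple[float, list[tuple[int, int]]]:
    """Coverage of the panel consensus by a set of peptides; peptides that
    do not map are excluded with a warning."""
    aware = panel.deamidation_aware if deamidation_aware is None else deamidation_aware
    intervals = []
    unmapped = []
    for seq in peptide_seqs:
        iv = map_peptide_to_consensus(seq, panel.consensus, aware)
        if iv is None:
            unmapped.append(seq)
            continue
        intervals.append(iv)
    if unmapped:
        log.warning(
            "%d peptide(s) do not map to the consensus and are excluded "
            "from coverage (species-variant positions differ from the "
            "majority consensus): %s%s",
            len(unmapped),
            ", ".join(unmapped[:3]),
            "..." if len(unmapped) > 3 else "",
        )
    return coverage(intervals, len(panel.consensus)), intervals


def analyze_sample(
    sample_id: str,
    peptides: Sequence[tuple[str, int]],  # (peptide_seq, spectra_count)
    panel: ReferencePanel,
    pooled: bool = False,
    region: str = "",
    dates: str = "",
) -> SampleResult:
    """Full per-sample analysis from accepted peptide sequences: diagnostic
    taxa, consensus call, species flags and consensus coverage."""
    assignments = [
        (seq, panel.diagnostic_level(seq), count) for seq, count in peptides
    ]
    result = sample_consensus(
        sample_id, assignments, panel.taxonomy, pooled=pooled, region=region, dates=dates
    )
    blg = [(s, t, c) for s, t, c in assignments if t is not None]
    result.accepted_peptides = [(s, c, t) for s, t, c in blg]
    result.total_blg_spectra = sum(c for _, _, c in blg)
    pct, intervals = sample_coverage([s for s, _, _ in blg], panel)
    result.coverage_pct = pct
    result.coverage_intervals = intervals
    return result


def results_table(results: Sequence[SampleResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": r.sample_id,
            "region": r.region,
            "dates": r.dates,
            "positive": r.positive,
            "consensus_taxon": r.consensus_taxon or "",
            "species_hits": ";".join(sorted(r.species_hits)),
            "multi_species": r.multi_species,
            "total_blg_spectra": r.total_blg_spectra,
            "coverage_pct": round(r.coverage_pct, 1),
            "pooled": r.pooled,
        }
        for r in results
    )
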