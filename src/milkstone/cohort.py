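"""Regional cohort aggregation of per-sample milk-protein results.

Produces the classic survey-table shape: one row per region with sample
count, BLG-positive count (pooled extracts counted once, flagged) and total
matching spectra, plus the headline positive fraction across a region
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .assign import SampleResult


@dataclass
class CohortRow:
    region: str
    date_range: str
    n_samples: int
    n_positive: int
    total_spectra: int
    pooled_note: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_samples):
            raise ValueError(f"{self.region}: n_positive outside [0, n_samples]")
        if self.total_spectra < self.n_positive:
            raise ValueError(f"{self.region}: fewer spectra than positive samples")


def summarize(samples: Sequence[SampleResult]) -> list[CohortRow]:
    """Aggregate per-sample results into per-region rows (input order of
    first appearance preserved). Pooled samples count as one sample."""
    order: list[str] = []
    grouped: dict[str, list[SampleResult]] = {}
    for s in samples:
        if s.region not in grouped:
            grouped[s.region] = []
            order.append(s.region)
        grouped[s.region].append(s)
    rows = []
    for region in order:
        group = grouped[region]
        dates = sorted({s.dates for s in group if s.dates})
        rows.append(
            CohortRow(
                region=region,
                date_range="; ".join(dates),
                n_samples=len(group),
                n_positive=sum(1 for s in group if s.positive),
                total_spectra=sum(s.total_blg_spectra for s in group),
                pooled_note=any(s.pooled for s in group),
            )
        )
    return rows


def positive_fraction(
    rows: Sequence[CohortRow],
    region_filter: Callable[[CohortRow], bool] | Sequence[str] | None = None,
) -> float:
    """Percent of samples that are BLG-positive over the selected rows,
    reported to one decimal. ``region_filter`` may be a predicate, a list of
    region names, or None (all rows)."""
    if region_filter is None:
        selected = list(rows)
    elif callable(region_filter):
        selected = [r for r in rows if region_filter(r)]
    else:
        names = set(region_filter)
        selected = [r for r in rows if r.region in names]
    n = sum(r.n_samples for r in selected)
    if n == 0:
        raise ValueError("no samples selected")
    return round(100.0 * sum(r.n_positive for r in selected) / n, 1)


def cohort_table(rows: Sequence[CohortRow]):
    import pandas as pd

    return pd.DataFrame(
        {
            "region": r.region,
            "dates": r.date_range,
            "n_samples": r.n_samples,
            "n_positive": r.n_positive,
            "total_spectra": r.total_spectra,
            "pooled": r.pooled_note,
        }
        for r in rows
    )
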