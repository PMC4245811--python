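"""Peptide-spectrum matching and target-decoy FDR filtering.

Spectra are MGF peak lists (capped at the 200 most intense peaks, as in
the Proteowizard conversion this mirrors). Candidates are drawn from the
panel peptidome within a +/-10 ppm precursor window; fragments are matched
greedily within +/-0.07 Da; and the ion score is a documented binomial
approximation on the Mascot scale, ``-10*log10`` of the chance probability
of matching at least the observed number of fragments.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf
from scipy.stats import binom

from .masses import PROTON, WATER, RESIDUE_MASS, mz_from_mass
from .panel import Peptide, ProteinRecord, ReferencePanel

log = logging.getLogger(__name__)

MAX_PEAKS = 200  # most intense peaks retained per spectrum
PRECURSOR_TOL_PPM = 10.0
FRAGMENT_TOL_DA = 0.07
SCORE_CUTOFF = 25.0
ALPHA = 0.05
SEARCH_CHARGES = (2, 3, 4, 5)  # charge states considered when searching
DEFAULT_CHARGES_WHEN_MISSING = (2, 3)


@dataclass
class Spectrum:
    spectrum_id: str
    precursor_mz: float
    charge: int | None  # None when the peak list does not state it
    peaks: list[tuple[float, float]]  # (m/z, intensity), ascending m/z
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p[0])
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"{self.spectrum_id}: negative intensity")

    @property
    def mz_span(self) -> float:
        if len(self.peaks) < 2:
            return 0.0
        return self.peaks[-1][0] - self.peaks[0][0]


@dataclass
class PSM:
    spectrum_id: str
    sample_id: str
    peptide: Peptide
    matched_fragments: int
    considered_fragments: int
    ion_score: float
    p_value: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if not (0 <= self.matched_fragments <= self.considered_fragments):
            raise ValueError("matched fragments out of range")
        if self.ion_score < 0:
            raise ValueError("ion_score must be >= 0")


@dataclass
class FDRResult:
    threshold: float
    alpha: float
    accepted_psms: list[PSM]
    n_targets_accepted: int
    n_decoys_accepted: int
    estimated_fdr: float


def _cap_peaks(
    mzs: Sequence[float], intensities: Sequence[float], cap: int = MAX_PEAKS
) -> list[tuple[float, float]]:
    pairs = list(zip(mzs, intensities))
    if len(pairs) > cap:
        pairs.sort(key=lambda p: p[1], reverse=True)
        pairs = pairs[:cap]
    pairs.sort(key=lambda p: p[0])
    return pairs


def read_mgf(path: str | Path, sample_id: str | None = None) -> list[Spectrum]:
    """Read an MGF peak-list file.

    Retains the 200 most intense peaks per spectrum (then re-sorts by m/z).
    Blocks without a precursor mass are skipped with a warning. The sample
    id defaults to the file stem.
    """
    path = Path(path)
    sid = path.stem if sample_id is None else sample_id
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                log.warning("%s: block %d has no PEPMASS, skipped", path.name, i)
                continue
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else None
            title = str(params.get("title", f"{path.stem}.{i}"))
            peaks = _cap_peaks(entry["m/z array"], entry["intensity array"])
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    peaks=peaks,
                    sample_id=sid,
                )
            )
    return spectra


class PeptidomeIndex:
    """Panel peptidome indexed by neutral monoisotopic mass."""

    def __init__(self, forms: Sequence[Peptide]):
        self.forms = sorted(forms, key=lambda p: p.mono_mass)
        self.masses = [p.mono_mass for p in self.forms]

    @classmethod
    def from_panel(
        cls,
        panel: ReferencePanel,
        background_records: Sequence["ProteinRecord"] = (),
    ) -> "PeptidomeIndex":
        """Search index over the panel peptidome, optionally extended with a
        background/contaminant database (plus its reversed decoys), so that
        non-BLG spectra compete against their own best explanation the way
        they would in a full-proteome search."""
        forms = list(panel.peptidome())
        if background_records:
            from .panel import build_decoys, digest, enumerate_modified_forms

            bg = list(background_records) + build_decoys(background_records)
            for rec in bg:
                for pep in digest(
                    rec.sequence,
                    max_missed=panel.max_missed,
                    min_len=panel.min_len,
                    max_len=panel.max_len,
                    semi=panel.semi,
                    parent_accession=rec.accession,
                    is_decoy=rec.is_decoy,
                ):
                    if panel.min_mass <= pep.mono_mass <= panel.max_mass:
                        forms.extend(
                            enumerate_modified_forms(
                                pep, panel.modifications, panel.max_variable_mods
                            )
                        )
        return cls(forms)

    def candidates(
        self, precursor_mz: float, charge: int, tol_ppm: float = PRECURSOR_TOL_PPM
    ) -> list[Peptide]:
        """All forms whose theoretical m/z at ``charge`` lies within
        +/-``tol_ppm`` (relative, symmetric) of ``precursor_mz``."""
        neutral = (precursor_mz - PROTON) * charge
        half = precursor_mz * tol_ppm * 1e-6 * charge  # window in neutral-mass Da
        lo = bisect.bisect_left(self.masses, neutral - half)
        hi = bisect.bisect_right(self.masses, neutral + half)
        out = []
        for p in self.forms[lo:hi]:
            theo = mz_from_mass(p.mono_mass, charge)
            if abs(precursor_mz - theo) / theo * 1e6 <= tol_ppm:
                out.append(p)
        return out


def candidate_peptides(
    precursor_mz: float,
    charge: int,
    index: PeptidomeIndex,
    tol_ppm: float = PRECURSOR_TOL_PPM,
) -> list[Peptide]:
    return index.candidates(precursor_mz, charge, tol_ppm)


def theoretical_fragments(
    peptide: Peptide, max_frag_charge: int = 1
) -> list[tuple[str, float]]:
    """Singly charged b- and y-ion ladders (plus 2+ when requested).

    b_i = sum of the first i residue masses + proton;
    y_i = sum of the last i residue masses + water + proton.
    Modification deltas are added at their positions.
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("peptide too short to fragment")
    delta = [0.0] * n
    for pos, spec in peptide.mods:
        delta[pos] += spec.delta_mass
    res = [RESIDUE_MASS[aa] + d for aa, d in zip(seq, delta)]

    prefix = np.cumsum(res)
    total = prefix[-1]
    ions: list[tuple[str, float]] = []
    for i in range(1, n):
        b = prefix[i - 1] + PROTON
        y = (total - prefix[i - 1]) + WATER + PROTON
        ions.append((f"b{i}", b))
        ions.append((f"y{n - i}", y))
        if max_frag_charge >= 2:
            ions.append((f"b{i}++", (prefix[i - 1] + 2 * PROTON) / 2))
            ions.append((f"y{n - i}++", ((total - prefix[i - 1]) + WATER + 2 * PROTON) / 2))
    return ions


def _match_count(
    frag_mzs: Sequence[float], peaks: Sequence[tuple[float, float]], tol: float
) -> int:
    """Greedy one-to-one nearest-peak matching; each peak usable once."""
    peak_mzs = [m for m, _ in peaks]
    used = [False] * len(peak_mzs)
    matched = 0
    for f in sorted(frag_mzs):
        j = bisect.bisect_left(peak_mzs, f)
        best, best_d = -1, tol
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(peak_mzs) and not used[k]:
                d = abs(peak_mzs[k] - f)
                if d <= best_d:
                    best, best_d = k, d
        if best >= 0:
            used[best] = True
            matched += 1
    return matched


#: Effective chance window (Da) for fragment/peak coincidences. Peptide
#: fragment masses cluster on the ~1 Da residue-mass lattice with nearly
#: equal mass defects, and peptide-derived peaks come in complementary
#: b/y pairs on that lattice, so for tolerances below half a lattice unit
#: the probability that an unrelated fragment lands within tolerance of a
#: peptide-derived peak is governed by the lattice structure, not by
#: 2*tol. Two lattice units is the conservative default.
LATTICE_WINDOW_DA = 2.0


def score_psm(
    spectrum: Spectrum,
    peptide: Peptide,
    frag_tol_da: float = FRAGMENT_TOL_DA,
    max_frag_charge: int = 1,
    lattice_window_da: float | None = LATTICE_WINDOW_DA,
) -> PSM:
    """Score one candidate against one spectrum.

    The chance probability is the binomial tail Pr(X >= k) with n the number
    of theoretical fragments, k the number matched, and per-fragment hit
    probability p = n_peaks * w / observed m/z span (clipped to [0,1]),
    where the chance window w is 2*tol, widened to one lattice unit
    (``lattice_window_da``, default 1.0 Da; pass None to disable) because
    peptide-derived peaks are not uniform on the m/z axis. The ion score is
    -10*log10(P), floored at 0. Degenerate spectra (fewer than two peaks)
    score 0.
    """
    frags = theoretical_fragments(peptide, max_frag_charge)
    n = len(frags)
    span = spectrum.mz_span
    if span <= 0 or len(spectrum.peaks) < 2:
        return PSM(
            spectrum.spectrum_id, spectrum.sample_id, peptide, 0, n, 0.0, 1.0,
            peptide.is_decoy,
        )
    k = _match_count([mz for _, mz in frags], spectrum.peaks, frag_tol_da)
    window = 2.0 * frag_tol_da
    if lattice_window_da is not None:
        window = max(window, lattice_window_da)
    p_hit = min(1.0, len(spectrum.peaks) * window / span)
    p_value = float(binom.sf(k - 1, n, p_hit)) if k > 0 else 1.0
    p_value = min(max(p_value, 1e-300), 1.0)
    score = max(0.0, -10.0 * np.log10(p_value))
    return PSM(
        spectrum.spectrum_id, spectrum.sample_id, peptide, k, n, score, p_value,
        peptide.is_decoy,
    )


def best_psm(
    spectrum: Spectrum,
    index: PeptidomeIndex,
    tol_ppm: float = PRECURSOR_TOL_PPM,
    frag_tol_da: float = FRAGMENT_TOL_DA,
) -> PSM | None:
    """Best peptide-spectrum match over the searched charge states.

    Spectra with a stated charge are searched at that charge (if 2..5);
    charge-missing spectra are tried at 2 and 3. Ties break toward more
    matched fragments, then the lexicographically smaller peptide.
    """
    if spectrum.charge is not None:
        charges: tuple[int, ...] = (
            (spectrum.charge,) if spectrum.charge in SEARCH_CHARGES else ()
        )
    else:
        charges = DEFAULT_CHARGES_WHEN_MISSING
    best: PSM | None = None
    for z in charges:
        for cand in index.candidates(spectrum.precursor_mz, z, tol_ppm):
            psm = score_psm(spectrum, cand, frag_tol_da)
            if best is None or (
                psm.ion_score,
                psm.matched_fragments,
                _neg_lex(psm.peptide.sequence),
            ) > (best.ion_score, best.matched_fragments, _neg_lex(best.peptide.sequence)):
                best = psm
    return best


class _neg_lex(str):
    """Orders lexicographically *smaller* strings as *greater* (for max-tuples)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def search_spectra(
    spectra: Iterable[Spectrum],
    index: PeptidomeIndex,
    tol_ppm: float = PRECURSOR_TOL_PPM,
    frag_tol_da: float = FRAGMENT_TOL_DA,
) -> list[PSM]:
    """One best PSM per spectrum (spectra with no candidate are dropped)."""
    out = []
    for s in spectra:
        psm = best_psm(s, index, tol_ppm, frag_tol_da)
        if psm is not None:
            out.append(psm)
    return out


def fdr_filter(
    psms: Sequence[PSM],
    score_cutoff: float = SCORE_CUTOFF,
    alpha: float = ALPHA,
) -> FDRResult:
    """Accept target PSMs with ion_score >= cutoff and chance p < alpha;
    estimate FDR from decoy PSMs passing the same filter.

    estimated_fdr = (#decoys accepted) / max(1, #targets accepted).
    """
    passing = [
        p for p in psms if p.ion_score >= score_cutoff and p.p_value < alpha
    ]
    targets = [p for p in passing if not p.is_decoy]
    decoys = [p for p in passing if p.is_decoy]
    fdr = len(decoys) / max(1, len(targets))
    return FDRResult(
        threshold=score_cutoff,
        alpha=alpha,
        accepted_psms=targets,
        n_targets_accepted=len(targets),
        n_decoys_accepted=len(decoys),
        estimated_fdr=fdr,
    )


def psm_table(psms: Sequence[PSM], accepted_ids: set[int] | None = None):
    """PSMs as a tidy table; ``accepted_ids`` marks accepted rows by id()."""
    import pandas as pd

    rows = []
    for p in psms:
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "sample_id": p.sample_id,
                "peptide": p.peptide.sequence,
                "mods": p.peptide.mods_label,
                "parent": p.peptide.parent_accession,
                "score": round(p.ion_score, 2),
                "matched": p.matched_fragments,
                "considered": p.considered_fragments,
                "decoy": p.is_decoy,
                "accepted": id(p) in accepted_ids if accepted_ids is not None else None,
            }
        )
    return pd.DataFrame(rows)
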