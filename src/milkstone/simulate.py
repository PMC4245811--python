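"""Ground-truthed synthetic cohorts for the milk-peptide pipeline.

Emulates the statistical structure the analysis assumes: MS/MS spectra of
true BLG peptides from a chosen species mixture (precursor mass error
within instrument tolerance, fragment jitter, peak dropout, uniform noise
peaks, age-dependent deamidation of N/Q), a decoy-like background
peptidome standing in for the bacterial/host oral proteome, and negative
controls (extraction blanks, fetuin standards) that contain no BLG.

Instrument errors default to SD = tolerance/3 so ~99.7% of true signals
fall inside the nominal 10 ppm / 0.07 Da search windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .masses import CARBAMIDOMETHYL, DEAMIDATION, mz_from_mass, peptide_mass
from .panel import Peptide, ProteinRecord, ReferencePanel, digest
from .scoring import Spectrum, theoretical_fragments

PRECURSOR_ERROR_SD_PPM = 10.0 / 3.0
FRAGMENT_ERROR_SD_DA = 0.07 / 3.0


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    region: str = ""
    dates: str = ""
    species_mix: tuple[tuple[str, float], ...] = ()  # (species, proportion)
    n_true_blg_spectra: int = 0
    background_spectra: int = 20
    deamidation_rate: float = 0.3
    is_control: str | None = None  # None | "blank" | "fetuin"
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.species_mix:
            total = sum(p for _, p in self.species_mix)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.sample_id}: mix proportions sum to {total}")
        if self.is_control and self.n_true_blg_spectra:
            raise ValueError(f"{self.sample_id}: controls must carry no BLG spectra")
        if not (0.0 <= self.deamidation_rate <= 1.0):
            raise ValueError("deamidation_rate outside [0, 1]")


@dataclass
class SimulationConfig:
    seed: int
    samples: list[SampleSpec] = field(default_factory=list)
    mass_error_sd_ppm: float = PRECURSOR_ERROR_SD_PPM
    fragment_error_sd_da: float = FRAGMENT_ERROR_SD_DA
    peak_dropout: float = 0.10
    noise_peaks: int = 10


@dataclass
class TruthRow:
    sample_id: str
    spectrum_id: str
    kind: str  # "blg" | "background"
    species: str
    peptide: str
    mods: str
    charge: int


def background_proteome(
    panel: ReferencePanel, rng: np.random.Generator, n_copies: int = 3
) -> list[ProteinRecord]:
    """Decoy-like background proteome: shuffled panel sequences standing in
    for the oral bacterial/host proteome (not a real proteome). Emitted
    alongside the cohort so the search can include it as its contaminant
    database, the way a real search runs against the full proteome."""
    records: list[ProteinRecord] = []
    i = 0
    for _ in range(n_copies):
        for rec in panel.records:
            seq = list(rec.sequence)
            rng.shuffle(seq)
            records.append(
                ProteinRecord(
                    accession=f"BG{i:03d}",
                    species=f"background_{i}",
                    lineage=("background", f"background_{i}"),
                    sequence="".join(seq),
                )
            )
            i += 1
    return records


def _background_peptidome(
    records: Sequence[ProteinRecord], panel: ReferencePanel
) -> list[Peptide]:
    peps: list[Peptide] = []
    for rec in records:
        peps.extend(
            p
            for p in digest(
                rec.sequence,
                max_missed=panel.max_missed,
                min_len=panel.min_len,
                max_len=panel.max_len,
                semi=False,
                parent_accession=rec.accession,
            )
            if panel.min_mass <= p.mono_mass <= panel.max_mass
        )
    return peps


def _apply_sample_mods(
    peptide: Peptide, deamidation_rate: float, rng: np.random.Generator
) -> Peptide:
    """Chemistry the instrument actually sees: every Cys is alkylated
    (carbamidomethyl, the fixed derivatization), and each N/Q site
    deamidates independently with the age-dependent rate."""
    mods_new: list[tuple[int, object]] = [
        (i, CARBAMIDOMETHYL) for i, aa in enumerate(peptide.sequence) if aa == "C"
    ]
    for i, aa in enumerate(peptide.sequence):
        if aa in "NQ" and rng.random() < deamidation_rate:
            mods_new.append((i, DEAMIDATION))
    if not mods_new:
        return peptide
    mods = tuple(sorted(peptide.mods + tuple(mods_new), key=lambda m: (m[0], m[1].name)))
    return Peptide(
        sequence=peptide.sequence,
        parent_accession=peptide.parent_accession,
        start=peptide.start,
        end=peptide.end,
        missed_cleavages=peptide.missed_cleavages,
        termini=peptide.termini,
        mods=mods,
        mono_mass=peptide_mass(peptide.sequence, mods),
        is_decoy=peptide.is_decoy,
    )


def _spectrum_from_peptide(
    peptide: Peptide,
    spectrum_id: str,
    sample_id: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[Spectrum, int]:
    charge = int(rng.choice([2, 3]))
    theo_mz = mz_from_mass(peptide.mono_mass, charge)
    prec = theo_mz * (1.0 + rng.normal(0.0, cfg.mass_error_sd_ppm) * 1e-6)

    frags = theoretical_fragments(peptide, max_frag_charge=1)
    peaks: list[tuple[float, float]] = []
    for _, mz in frags:
        if rng.random() < cfg.peak_dropout:
            continue
        obs = mz + rng.normal(0.0, cfg.fragment_error_sd_da)
        inten = float(rng.lognormal(mean=10.0, sigma=1.0))
        peaks.append((obs, inten))
    while len(peaks) < 2:  # keep the spectrum scoreable
        _, mz = frags[int(rng.integers(len(frags)))]
        peaks.append((mz + rng.normal(0.0, cfg.fragment_error_sd_da),
                      float(rng.lognormal(10.0, 1.0))))
    lo = min(m for m, _ in peaks)
    hi = max(m for m, _ in peaks)
    for _ in range(cfg.noise_peaks):
        peaks.append(
            (float(rng.uniform(lo, hi)), float(rng.lognormal(mean=8.0, sigma=1.0)))
        )
    return (
        Spectrum(
            spectrum_id=spectrum_id,
            precursor_mz=prec,
            charge=charge,
            peaks=peaks,
            sample_id=sample_id,
        ),
        charge,
    )


def simulate_sample(
    spec: SampleSpec,
    panel: ReferencePanel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    background: Sequence[Peptide] | None = None,
) -> tuple[list[Spectrum], list[TruthRow]]:
    """Generate one sample's spectra and matching ground-truth rows."""
    for sp, _ in spec.species_mix:
        if sp not in panel.species:
            raise ValueError(f"{spec.sample_id}: species {sp!r} not in panel")
    if background is None:
        background = _background_peptidome(background_proteome(panel, rng), panel)

    spectra: list[Spectrum] = []
    truth: list[TruthRow] = []

    if spec.n_true_blg_spectra:
        species = [s for s, _ in spec.species_mix]
        props = np.array([p for _, p in spec.species_mix])
        picks = rng.choice(len(species), size=spec.n_true_blg_spectra, p=props)
        for j, si in enumerate(picks):
            sp = species[int(si)]
            pool = panel.species_peptides(sp)
            pep = pool[int(rng.integers(len(pool)))]
            pep = _apply_sample_mods(pep, spec.deamidation_rate, rng)
            sid = f"{spec.sample_id}.blg.{j}"
            s, z = _spectrum_from_peptide(pep, sid, spec.sample_id, cfg, rng)
            spectra.append(s)
            truth.append(
                TruthRow(spec.sample_id, sid, "blg", sp, pep.sequence, pep.mods_label, z)
            )

    for j in range(spec.background_spectra):
        pep = background[int(rng.integers(len(background)))]
        pep = _apply_sample_mods(pep, spec.deamidation_rate, rng)
        sid = f"{spec.sample_id}.bg.{j}"
        s, z = _spectrum_from_peptide(pep, sid, spec.sample_id, cfg, rng)
        spectra.append(s)
        truth.append(
            TruthRow(spec.sample_id, sid, "background", "", pep.sequence, pep.mods_label, z)
        )
    return spectra, truth


def simulate_cohort(
    cfg: SimulationConfig, panel: ReferencePanel
) -> tuple[dict[str, list[Spectrum]], list[TruthRow], list[ProteinRecord]]:
    """Deterministically generate every sample in the config.

    Returns spectra grouped by sample, the full truth table, and the
    cohort's background proteome (drawn once), which callers should hand to
    the search as its contaminant database.
    """
    rng = np.random.default_rng(cfg.seed)
    bg_records = background_proteome(panel, rng)
    background = _background_peptidome(bg_records, panel)
    all_spectra: dict[str, list[Spectrum]] = {}
    all_truth: list[TruthRow] = []
    for spec in cfg.samples:
        s, t = simulate_sample(spec, panel, cfg, rng, background)
        all_spectra[spec.sample_id] = s
        all_truth.extend(t)
    return all_spectra, all_truth, bg_records


# ---------------------------------------------------------------------------
# file output


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with fixed formatting (byte-stable per seed)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.charge is not None:
                fh.write(f"CHARGE={s.charge}+\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


def write_cohort(
    cfg: SimulationConfig, panel: ReferencePanel, outdir: str | Path
) -> dict[str, Path]:
    """Materialise a cohort on disk: one MGF per sample, a truth TSV, a
    sample-metadata TSV and a JSON echo of the configuration."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra, truth, bg_records = simulate_cohort(cfg, panel)

    paths: dict[str, Path] = {}
    for sample_id, specs in spectra.items():
        p = outdir / f"{sample_id}.mgf"
        write_mgf(specs, p)
        paths[sample_id] = p

    bg_path = outdir / "background_proteins.fasta"
    with open(bg_path, "w") as fh:
        for rec in bg_records:
            fh.write(f">{rec.accession}|{rec.species}|lineage:{'>'.join(rec.lineage)}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    paths["background"] = bg_path

    truth_df = pd.DataFrame([asdict(t) for t in truth])
    truth_path = outdir / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    meta = pd.DataFrame(
        {
            "sample_id": s.sample_id,
            "region": s.region,
            "dates": s.dates,
            "pooled": s.pooled,
            "is_control": s.is_control or "",
        }
        for s in cfg.samples
    )
    meta_path = outdir / "samples.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    paths["samples"] = meta_path

    echo = {
        "seed": cfg.seed,
        "mass_error_sd_ppm": cfg.mass_error_sd_ppm,
        "fragment_error_sd_da": cfg.fragment_error_sd_da,
        "peak_dropout": cfg.peak_dropout,
        "noise_peaks": cfg.noise_peaks,
        "samples": [asdict(s) for s in cfg.samples],
    }
    cfg_path = outdir / "config.json"
    cfg_path.write_text(json.dumps(echo, indent=2, default=list) + "\n")
    paths["config"] = cfg_path
    return paths


# ---------------------------------------------------------------------------
# LP observations


def simulate_lp_points(
    n: int,
    seed: int,
    field=None,
    lon_range: tuple[float, float] = (-10.0, 40.0),
    lat_range: tuple[float, float] = (35.0, 65.0),
    sample_size_range: tuple[int, int] = (20, 200),
) -> list:
    """LP allele-frequency observations from a smooth latent field with
    binomial sampling noise (2N allele draws per site of N diploids).

    ``field`` maps (lon, lat) to a latent allele frequency; the default is
    a northward logistic cline, the textbook European LP pattern.
    """
    from .lpmap import LPPoint

    if n < 1:
        raise ValueError("n >= 1 required")
    if field is None:
        def field(lon, lat):  # noqa: ANN001
            return 0.75 / (1.0 + np.exp(-(lat - 48.0) / 4.0))

    rng = np.random.default_rng(seed)
    pts = []
    for _ in range(n):
        lon = float(rng.uniform(*lon_range))
        lat = float(rng.uniform(*lat_range))
        p = float(np.clip(field(lon, lat), 0.0, 1.0))
        size = int(rng.integers(sample_size_range[0], sample_size_range[1] + 1))
        k = int(rng.binomial(2 * size, p))
        pts.append(
            LPPoint(latitude=lat, longitude=lon, allele_freq=k / (2 * size), sample_size=size)
        )
    return pts
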