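"""End-to-end orchestration: panel build -> spectrum search -> FDR ->
taxonomy/coverage -> cohort summary, with a peptide-table entry mode that
skips the search so published identified-peptide tables can be re-analyzed
directly."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .assign import SampleResult, analyze_sample, results_table
from .cohort import cohort_table, summarize
from .data import default_panel_fasta
from .panel import ReferencePanel, load_fasta
from .scoring import (
    ALPHA,
    FRAGMENT_TOL_DA,
    PRECURSOR_TOL_PPM,
    SCORE_CUTOFF,
    PeptidomeIndex,
    fdr_filter,
    psm_table,
    read_mgf,
    search_spectra,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Search parameters default to the published protocol: 10 ppm
    precursor tolerance, 0.07 Da fragment tolerance, ion-score cutoff 25,
    significance threshold 0.05, two missed cleavages, semi-tryptic."""

    panel_fasta: Path | None = None  # None -> bundled synthetic panel
    background_fasta: Path | None = None  # contaminant/background database
    mgf_paths: list[Path] = field(default_factory=list)
    peptide_table: Path | None = None  # alternative entry mode
    sample_meta: Path | None = None  # sample_id/region/dates/pooled/is_control TSV
    out_dir: Path = Path("milkstone_out")
    tol_ppm: float = PRECURSOR_TOL_PPM
    frag_tol_da: float = FRAGMENT_TOL_DA
    score_cutoff: float = SCORE_CUTOFF
    alpha: float = ALPHA
    max_missed: int = 2
    deamidation_aware: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            k: str(v)
            for k, v in self.__dict__.items()
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def build_panel(cfg: PipelineConfig) -> ReferencePanel:
    fasta = cfg.panel_fasta or default_panel_fasta()
    records = load_fasta(fasta)
    if not records:
        raise RuntimeError(f"panel stage: no records in {fasta}")
    return ReferencePanel(
        records,
        max_missed=cfg.max_missed,
        deamidation_aware=cfg.deamidation_aware,
    )


def _load_meta(cfg: PipelineConfig) -> pd.DataFrame | None:
    if cfg.sample_meta is None:
        return None
    df = pd.read_csv(cfg.sample_meta, sep="\t", dtype={"sample_id": str})
    return df.set_index("sample_id")


def _meta_of(meta: pd.DataFrame | None, sample_id: str) -> dict:
    if meta is None or sample_id not in meta.index:
        return {"region": "", "dates": "", "pooled": False, "is_control": ""}
    row = meta.loc[sample_id]
    return {
        "region": str(row.get("region", "") or ""),
        "dates": str(row.get("dates", "") or ""),
        "pooled": bool(row.get("pooled", False)),
        "is_control": str(row.get("is_control", "") or "").replace("nan", ""),
    }


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the configured pipeline and write the report bundle.

    Returns a name -> path mapping of the written artifacts. Raises with a
    stage-named message on any stage failure.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    try:
        panel = build_panel(cfg)
    except Exception as exc:
        raise RuntimeError(f"panel stage: {exc}") from exc

    meta = _load_meta(cfg)
    per_sample_peptides: dict[str, dict[str, int]] = {}

    if cfg.peptide_table is not None:
        try:
            tbl = pd.read_csv(cfg.peptide_table, sep="\t", dtype={"sample_id": str})
        except Exception as exc:
            raise RuntimeError(f"assign stage: cannot read peptide table: {exc}") from exc
        for _, row in tbl.iterrows():
            per_sample_peptides.setdefault(str(row["sample_id"]), {})
            per_sample_peptides[str(row["sample_id"])][str(row["peptide_seq"])] = (
                per_sample_peptides[str(row["sample_id"])].get(str(row["peptide_seq"]), 0)
                + int(row.get("spectra_count", 1))
            )
        if meta is not None:
            for sid in meta.index:
                per_sample_peptides.setdefault(str(sid), {})
    else:
        if not cfg.mgf_paths:
            raise RuntimeError("search stage: no MGF inputs and no peptide table")
        try:
            bg_records = (
                load_fasta(cfg.background_fasta) if cfg.background_fasta else []
            )
            index = PeptidomeIndex.from_panel(panel, bg_records)
            all_psms = []
            for p in cfg.mgf_paths:
                spectra = read_mgf(p)
                all_psms.extend(
                    search_spectra(spectra, index, cfg.tol_ppm, cfg.frag_tol_da)
                )
        except FileNotFoundError as exc:
            raise RuntimeError(f"search stage: {exc}") from exc
        fdr = fdr_filter(all_psms, cfg.score_cutoff, cfg.alpha)

        accepted_ids = {id(p) for p in fdr.accepted_psms}
        psms_df = psm_table(all_psms, accepted_ids)
        paths["psms"] = out / "psms.tsv"
        psms_df.to_csv(paths["psms"], sep="\t", index=False)
        fdr_df = pd.DataFrame(
            [
                {
                    "score_cutoff": fdr.threshold,
                    "alpha": fdr.alpha,
                    "targets_accepted": fdr.n_targets_accepted,
                    "decoys_accepted": fdr.n_decoys_accepted,
                    "estimated_fdr": fdr.estimated_fdr,
                }
            ]
        )
        paths["fdr"] = out / "fdr_summary.tsv"
        fdr_df.to_csv(paths["fdr"], sep="\t", index=False)

        for p in cfg.mgf_paths:  # every searched sample appears, even if empty
            per_sample_peptides.setdefault(Path(p).stem, {})
        for psm in fdr.accepted_psms:
            d = per_sample_peptides.setdefault(psm.sample_id, {})
            d[psm.peptide.sequence] = d.get(psm.peptide.sequence, 0) + 1

    try:
        results: list[SampleResult] = []
        cov_rows = []
        for sample_id in sorted(per_sample_peptides):
            m = _meta_of(meta, sample_id)
            res = analyze_sample(
                sample_id,
                sorted(per_sample_peptides[sample_id].items()),
                panel,
                pooled=m["pooled"],
                region=m["region"],
                dates=m["dates"],
            )
            results.append(res)
            for s, e in sorted(set(res.coverage_intervals)):
                cov_rows.append(
                    {"sample_id": sample_id, "consensus_start": s, "consensus_end": e}
                )
    except Exception as exc:
        raise RuntimeError(f"assign stage: {exc}") from exc

    paths["samples"] = out / "sample_results.tsv"
    results_table(results).to_csv(paths["samples"], sep="\t", index=False)
    paths["coverage"] = out / "coverage_intervals.tsv"
    pd.DataFrame(
        cov_rows, columns=["sample_id", "consensus_start", "consensus_end"]
    ).to_csv(paths["coverage"], sep="\t", index=False)

    try:
        rows = summarize(results)
    except Exception as exc:
        raise RuntimeError(f"cohort stage: {exc}") from exc
    paths["cohort"] = out / "cohort_summary.tsv"
    cohort_table(rows).to_csv(paths["cohort"], sep="\t", index=False)

    log_path = out / "run.log"
    with open(log_path, "a") as fh:
        fh.write(
            json.dumps(
                {
                    "milkstone_version": __version__,
                    "config_hash": cfg.config_hash(),
                    "seed": cfg.seed,
                    "n_samples": len(results),
                    "outputs": {k: str(v) for k, v in paths.items()},
                }
            )
            + "\n"
        )
    paths["log"] = log_path
    return paths
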