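"""Multi-species beta-lactoglobulin (BLG) reference panel.

Builds the searchable reference peptidome for milk-protein detection:
ortholog sequences with taxonomic lineages, semi-tryptic in-silico
digestion with missed cleavages, modified-form enumeration, reversed-decoy
generation, a panel consensus sequence, and per-peptide taxonomic
diagnosticity (lowest-common-ancestor over the species that could have
produced the peptide).

Sequence equivalence rules reflect what mass spectrometry can and cannot
distinguish: Ile/Leu are isobaric and always collapsed; diagenetic
deamidation converts Asn->Asp and Gln->Glu, so when deamidation-aware
matching is on (the default for degraded samples) N/D and Q/E are treated
as equivalent too.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .masses import (
    DEFAULT_MODIFICATIONS,
    ModificationSpec,
    format_mods,
    peptide_mass,
)

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

# Ile/Leu are mass-identical; N/D and Q/E become indistinguishable once
# diagenetic deamidation is allowed for.
_IL_TABLE = str.maketrans("I", "L")
_IL_DEAM_TABLE = str.maketrans("IND", "LDD") | str.maketrans("QE", "EE")


def collapse(sequence: str, deamidation_aware: bool = True) -> str:
    """Map a sequence onto its mass-equivalence class representative."""
    if deamidation_aware:
        return sequence.translate(_IL_DEAM_TABLE)
    return sequence.translate(_IL_TABLE)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    species: str
    lineage: tuple[str, ...]  # root ... species
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if not self.lineage:
            raise ValueError(f"{self.accession}: empty lineage")
        if self.lineage[-1] != self.species:
            raise ValueError(
                f"{self.accession}: lineage must end at species "
                f"({self.lineage[-1]!r} != {self.species!r})"
            )
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.accession}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) digestion product of a panel protein."""

    sequence: str
    parent_accession: str
    start: int  # 0-based, half-open interval on the parent
    end: int
    missed_cleavages: int
    termini: str  # "tryptic" | "semi"
    mods: tuple[tuple[int, ModificationSpec], ...] = ()
    mono_mass: float = field(default=0.0, compare=False)
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("interval length does not match sequence length")
        if self.termini not in ("tryptic", "semi"):
            raise ValueError(f"bad termini {self.termini!r}")
        if self.mono_mass == 0.0:
            object.__setattr__(self, "mono_mass", peptide_mass(self.sequence, self.mods))

    @property
    def mods_label(self) -> str:
        return format_mods(self.mods)


class Taxonomy:
    """Rooted tree over the panel lineages with LCA queries."""

    def __init__(self, lineages: Iterable[Sequence[str]]):
        self.parent: dict[str, str | None] = {}
        self.root: str | None = None
        for lineage in lineages:
            self.add_lineage(lineage)

    def add_lineage(self, lineage: Sequence[str]) -> None:
        if not lineage:
            raise ValueError("empty lineage")
        if self.root is None:
            self.root = lineage[0]
            self.parent[self.root] = None
        elif lineage[0] != self.root:
            raise ValueError(
                f"lineage root {lineage[0]!r} conflicts with taxonomy root {self.root!r}"
            )
        for parent, child in zip(lineage, lineage[1:]):
            known = self.parent.get(child)
            if known is not None and known != parent:
                raise ValueError(f"taxon {child!r} has conflicting parents {known!r}/{parent!r}")
            self.parent[child] = parent

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.parent

    def path_to_root(self, taxon: str) -> list[str]:
        if taxon not in self.parent:
            raise KeyError(taxon)
        path = [taxon]
        while (up := self.parent[path[-1]]) is not None:
            path.append(up)
        return path

    def depth(self, taxon: str) -> int:
        return len(self.path_to_root(taxon)) - 1

    def lca(self, taxa: Iterable[str]) -> str:
        """Deepest node that is an ancestor-or-equal of every given taxon."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of empty set")
        common: list[str] | None = None
        for t in taxa:
            path = self.path_to_root(t)[::-1]  # root first
            if common is None:
                common = path
            else:
                keep = 0
                for a, b in zip(common, path):
                    if a != b:
                        break
                    keep += 1
                common = common[:keep]
        assert common  # roots agree by construction
        return common[-1]

    def is_ancestor_or_equal(self, ancestor: str, taxon: str) -> bool:
        return ancestor in self.path_to_root(taxon)


# ---------------------------------------------------------------------------
# digestion


def cleavage_sites(sequence: str) -> list[int]:
    """Positions i where trypsin cuts between i-1 and i (after K/R, not before P)."""
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ]


def digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int = 30,
    semi: bool = True,
    parent_accession: str = "",
    is_decoy: bool = False,
) -> list[Peptide]:
    """Semi- or fully-tryptic in-silico digest of one protein sequence.

    Cleavage is C-terminal to K/R unless the next residue is P (Keil rule).
    A fully tryptic peptide has both termini at cleavage sites or protein
    ends; ``semi=True`` adds peptides with exactly one non-tryptic terminus.
    ``missed_cleavages`` counts uncut K/R sites internal to the peptide and
    is capped at ``max_missed``. Peptides are deduplicated by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)}")
    if not sequence:
        return []

    n = len(sequence)
    sites = cleavage_sites(sequence)
    boundaries = [0] + sites + [n]
    site_set = set(boundaries)

    def internal_missed(s: int, e: int) -> int:
        return sum(1 for p in sites if s < p < e)

    out: dict[tuple[int, int], Peptide] = {}

    def consider(s: int, e: int, termini: str) -> None:
        if not (min_len <= e - s <= max_len):
            return
        mc = internal_missed(s, e)
        if mc > max_missed:
            return
        key = (s, e)
        if key in out:
            return
        out[key] = Peptide(
            sequence=sequence[s:e],
            parent_accession=parent_accession,
            start=s,
            end=e,
            missed_cleavages=mc,
            termini=termini,
            is_decoy=is_decoy,
        )

    for i, s in enumerate(boundaries[:-1]):
        for e in boundaries[i + 1 :]:
            consider(s, e, "tryptic")

    if semi:
        # one ragged terminus: tryptic N-terminus with free C-terminus, or
        # the mirror image; fully tryptic intervals were claimed above.
        for s in boundaries[:-1]:
            for e in range(s + min_len, min(s + max_len, n) + 1):
                if e not in site_set:
                    consider(s, e, "semi")
        for e in boundaries[1:]:
            for s in range(max(e - max_len, 0), e - min_len + 1):
                if s not in site_set:
                    consider(s, e, "semi")

    return sorted(out.values(), key=lambda p: (p.start, p.end))


# ---------------------------------------------------------------------------
# modified forms


def enumerate_modified_forms(
    peptide: Peptide,
    specs: Sequence[ModificationSpec] = DEFAULT_MODIFICATIONS,
    max_variable: int = 2,
) -> list[Peptide]:
    """All modification states of ``peptide`` with up to ``max_variable``
    variable modifications; fixed modifications are always applied.

    Pyroglutamate is offered only on an N-terminal Gln; acetylation only on
    the protein N-terminal peptide (start == 0). At most one modification
    per site.
    """
    if max_variable < 0:
        raise ValueError("max_variable must be >= 0")
    seq = peptide.sequence

    fixed: list[tuple[int, ModificationSpec]] = []
    site_options: dict[int, list[ModificationSpec]] = {}
    for spec in specs:
        if spec.mode == "fixed":
            fixed.extend((i, spec) for i, aa in enumerate(seq) if aa in spec.targets)
            continue
        if spec.targets == "peptide-nterm-Q":
            if seq[0] == "Q":
                site_options.setdefault(0, []).append(spec)
        elif spec.targets == "protein-nterm":
            if peptide.start == 0:
                site_options.setdefault(0, []).append(spec)
        else:
            for i, aa in enumerate(seq):
                if aa in spec.targets:
                    site_options.setdefault(i, []).append(spec)

    fixed_sites = {i for i, _ in fixed}
    sites = sorted(s for s in site_options if s not in fixed_sites)

    forms: list[Peptide] = []
    for k in range(min(max_variable, len(sites)) + 1):
        for chosen in itertools.combinations(sites, k):
            for picks in itertools.product(*(site_options[s] for s in chosen)):
                mods = tuple(sorted(fixed + list(zip(chosen, picks)), key=lambda m: (m[0], m[1].name)))
                forms.append(
                    replace(peptide, mods=mods, mono_mass=peptide_mass(seq, mods))
                )
    return forms


# ---------------------------------------------------------------------------
# FASTA IO


def load_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a panel FASTA with headers ``>accession|species|lineage:Root>...>Leaf``.

    Sequences are uppercased and trailing ``*`` stops stripped. An empty
    file yields an empty list; a malformed header raises naming the entry.
    """
    records: list[ProteinRecord] = []
    seen_species: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        parts = header.split("|")
        if len(parts) != 3 or not parts[2].startswith("lineage:"):
            raise ValueError(
                f"malformed panel header {header!r} "
                "(expected 'accession|species|lineage:Root>...>Leaf')"
            )
        accession, species = parts[0], parts[1]
        lineage = tuple(t.strip() for t in parts[2][len("lineage:") :].split(">"))
        if species in seen_species:
            raise ValueError(f"duplicate species {species!r} in panel")
        seen_species.add(species)
        seq = str(entry.seq).upper().rstrip("*")
        records.append(ProteinRecord(accession, species, lineage, seq))
    return records


# ---------------------------------------------------------------------------
# consensus


def _column_vote(columns: list[list[str | None]], order: list[str]) -> str:
    del order  # ties resolved by first occurrence below
    out = []
    for col in columns:
        counts: dict[str, int] = {}
        for aa in col:
            if aa is not None:
                counts[aa] = counts.get(aa, 0) + 1
        if not counts:
            continue
        best = max(counts.values())
        # tie -> earliest panel record's residue (first key reaching best)
        for aa in col:
            if aa is not None and counts[aa] == best:
                out.append(aa)
                break
    return "".join(out)


def build_consensus(records: Sequence[ProteinRecord]) -> str:
    """Majority-vote consensus over the panel, on the coordinates of the
    first record.

    Each record is globally aligned (BLOSUM62, gap open -11 / extend -1) to
    the first record; columns are reference positions, insertions relative
    to the reference are dropped, and ties go to the earlier panel record.
    """
    if not records:
        raise ValueError("empty panel")
    ref = records[0].sequence
    columns: list[list[str | None]] = [[aa] for aa in ref]

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"

    for rec in records[1:]:
        if rec.sequence == ref:
            for col, aa in zip(columns, ref):
                col.append(aa)
            continue
        aln = aligner.align(ref, rec.sequence)[0]
        placed: list[str | None] = [None] * len(ref)
        for (rs, re_), (qs, qe) in zip(*aln.aligned):
            for k in range(re_ - rs):
                placed[rs + k] = rec.sequence[qs + k]
        for col, aa in zip(columns, placed):
            col.append(aa)
    return _column_vote(columns, [r.accession for r in records])


# ---------------------------------------------------------------------------
# the panel


class ReferencePanel:
    """BLG ortholog panel with taxonomy, consensus, decoys and peptidome."""

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        max_missed: int = 2,
        min_len: int = 7,
        max_len: int = 30,
        semi: bool = True,
        min_mass: float = 600.0,
        max_mass: float = 3500.0,
        modifications: Sequence[ModificationSpec] = DEFAULT_MODIFICATIONS,
        max_variable_mods: int = 2,
        deamidation_aware: bool = True,
    ):
        if not records:
            raise ValueError("panel needs at least one record")
        self.records = list(records)
        self.taxonomy = Taxonomy(r.lineage for r in self.records)
        self.consensus = build_consensus(self.records)
        self.max_missed = max_missed
        self.min_len = min_len
        self.max_len = max_len
        self.semi = semi
        self.min_mass = min_mass
        self.max_mass = max_mass
        self.modifications = tuple(modifications)
        self.max_variable_mods = max_variable_mods
        self.deamidation_aware = deamidation_aware

        self.decoy_records = build_decoys(self.records)

        self._base_peptides: dict[str, list[Peptide]] = {}
        for rec in self.records + self.decoy_records:
            self._base_peptides[rec.accession] = self._digest_record(rec)

        # species -> set of collapsed peptide strings, for diagnosticity
        self._species_sets: dict[str, set[str]] = {
            rec.species: {
                collapse(p.sequence, self.deamidation_aware)
                for p in self._base_peptides[rec.accession]
            }
            for rec in self.records
        }
        self._forms: list[Peptide] | None = None

    # -- digestion ---------------------------------------------------------

    def _digest_record(self, rec: ProteinRecord) -> list[Peptide]:
        peps = digest(
            rec.sequence,
            max_missed=self.max_missed,
            min_len=self.min_len,
            max_len=self.max_len,
            semi=self.semi,
            parent_accession=rec.accession,
            is_decoy=rec.is_decoy,
        )
        return [p for p in peps if self.min_mass <= p.mono_mass <= self.max_mass]

    def base_peptides(self, include_decoys: bool = True) -> list[Peptide]:
        recs = self.records + (self.decoy_records if include_decoys else [])
        return [p for rec in recs for p in self._base_peptides[rec.accession]]

    def peptidome(self) -> list[Peptide]:
        """All modified forms of all base peptides (targets and decoys)."""
        if self._forms is None:
            self._forms = [
                form
                for p in self.base_peptides(include_decoys=True)
                for form in enumerate_modified_forms(
                    p, self.modifications, self.max_variable_mods
                )
            ]
        return self._forms

    def species_peptides(self, species: str) -> list[Peptide]:
        for rec in self.records:
            if rec.species == species:
                return list(self._base_peptides[rec.accession])
        raise KeyError(f"species {species!r} not in panel")

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    # -- diagnosticity -----------------------------------------------------

    def diagnostic_level(
        self, peptide_seq: str, deamidation_aware: bool | None = None
    ) -> str | None:
        """Lowest common ancestor of all panel species whose digestion
        peptidome contains ``peptide_seq`` under the equivalence rules;
        None if no species contains it."""
        aware = self.deamidation_aware if deamidation_aware is None else bool(deamidation_aware)
        key = collapse(peptide_seq, aware)
        if aware != self.deamidation_aware:
            carriers = [
                rec.species
                for rec in self.records
                if key
                in {
                    collapse(p.sequence, aware)
                    for p in self._base_peptides[rec.accession]
                }
            ]
        else:
            carriers = [sp for sp, peps in self._species_sets.items() if key in peps]
        if not carriers:
            return None
        return self.taxonomy.lca(carriers)


def build_decoys(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target record, flagged as decoy."""
    if not records:
        raise ValueError("panel non-empty required")
    return [
        ProteinRecord(
            accession=f"DECOY_{r.accession}",
            species=f"decoy_{r.species}",
            lineage=("decoys", f"decoy_{r.species}"),
            sequence=r.sequence[::-1],
            is_decoy=True,
        )
        for r in records
        if not r.is_decoy
    ]


def peptidome_table(panel: ReferencePanel) -> "pandas.DataFrame":  # noqa: F821
    """Panel peptidome as a tidy table (one row per modified form)."""
    import pandas as pd

    rows = []
    for p in panel.peptidome():
        rows.append(
            {
                "peptide": p.sequence,
                "parent": p.parent_accession,
                "start": p.start,
                "end": p.end,
                "missed": p.missed_cleavages,
                "termini": p.termini,
                "mods": p.mods_label,
                "mono_mass": round(p.mono_mass, 5),
                "decoy": p.is_decoy,
                "diagnostic_taxon": (
                    panel.diagnostic_level(p.sequence) if not p.is_decoy else ""
                ),
            }
        )
    return pd.DataFrame(rows)
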