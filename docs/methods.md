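# Methods

## The detection problem

β-lactoglobulin (BLG) is the dominant ruminant whey protein and is absent
from human milk and saliva, so any BLG peptide confidently identified in
human dental calculus is dietary. Identification works the way shotgun
proteomics searches do: tandem-MS peak lists are matched against an
in-silico digest of candidate proteins, matches are scored, and the score
distribution of reversed-sequence decoys estimates the false-discovery
rate. Because BLG varies among dairy species, each identified peptide also
carries taxonomic information: the set of panel species whose digest could
have produced it, summarized as their lowest common ancestor (LCA).

## Reference panel and digestion

A panel is a FASTA of BLG orthologs with headers
`accession|species|lineage:Root>…>Species`. Digestion is semi-tryptic:
trypsin cleaves C-terminal to K/R except before proline (the Keil rule);
fully tryptic peptides have both termini at cleavage sites or protein ends,
and semi-tryptic peptides have exactly one ragged terminus, reflecting
diagenetic truncation of ancient peptides. Up to two internal missed
cleavage sites are kept. Length and mass bounds default to 7–30 residues
and 600–3500 Da — the range instruments routinely detect; both are
configurable since the choice is conventional.

Modified forms enumerate up to two variable modifications per peptide
(deamidation of N/Q at +0.98402 Da, N-terminal Gln→pyroglutamate at
−17.02655 Da, Met oxidation and Pro hydroxylation at +15.99491 Da, protein
N-terminal acetyl at +42.01057 Da) on top of fixed carbamidomethyl-C
(+57.02146 Da). Monoisotopic residue masses come from pyteomics.

Decoys are whole-sequence reversals, one per target, digested identically —
the simplest reproducible decoy scheme; reversal preserves composition and
length statistics.

### Sequence equivalence

Ile and Leu are isobaric and always treated as equivalent. Diagenetic
deamidation converts Asn→Asp and Gln→Glu, so for degraded samples the
identified sequence cannot distinguish N from D or Q from E; the package
therefore applies N≡D and Q≡E by default wherever sequences are compared
(taxonomic diagnosticity, consensus mapping), with a flag to disable the
behaviour for fresh material. Reports record the diagnostic taxon computed
under the active equivalence.

### Consensus

The panel consensus is a majority vote over columns after globally aligning
every record to the first one (BLOSUM62, gap open −11 / extend −1,
insertions relative to the reference dropped); ties resolve to the earlier
panel record. With the bundled equal-length panel the alignment step is the
identity and the consensus is a plain column majority.

### The bundled synthetic panel

The shipped FASTA (`synthetic_blg_panel.fasta`) is a constructed stand-in,
not a database export: a bovine-type 162-residue base sequence plus five
species variants carrying substitutions arranged by clade — shared
Caprinae changes, a shared non-*Bos* change that makes one tryptic peptide
cattle-specific, per-species private substitutions spread across the
protein, and a heavily substituted horse outgroup. The construction
guarantees that Pecora-, Bovidae-, Bovinae-, Caprinae-, and species-level
diagnostic peptides all exist, with 36–56% of each dairy species'
detectable peptidome species-diagnostic, qualitatively mirroring the high
inter-species variability of real BLG. Real reanalyses should supply a
curated ortholog FASTA; all code paths are identical.

## Spectrum search and scoring

MGF peak lists are truncated to the 200 most intense peaks (the standard
peak-list conversion). Candidates are all modified forms whose theoretical
m/z at the spectrum's charge lies within ±10 ppm of the precursor; spectra
stating a charge are searched at that charge (2–5), charge-less spectra at
2 and 3. Fragment ladders are singly charged b- and y-ions; matching is
greedy nearest-peak within ±0.07 Da, each peak usable once.

The ion score is a documented binomial approximation on the Mascot-like
scale: with n theoretical fragments, k matched, and per-fragment chance
probability p, the score is `−10·log10 Pr(X ≥ k | n, p)`, floored at 0.
The chance probability per fragment is `n_peaks · w / span`, where `span`
is the observed m/z range. For the window `w` we use two ~1 Da lattice
units rather than the naive `2 × 0.07 Da`: peptide fragment masses cluster
on the residue-mass lattice with nearly identical mass defects, and
peptide-derived peaks arrive in complementary b/y pairs on that lattice, so
coincidences between unrelated peptide ladders are governed by the lattice
structure, not by the instrument tolerance. The naive window understates
chance matches by an order of magnitude and lets short spurious matches
(4–8 coinciding ions) clear the score cutoff; the lattice window restores
calibration while leaving genuine matches (which hit ~90% of their ladder)
with scores far above any threshold. `score_psm(...,
lattice_window_da=None)` recovers the naive model.

Acceptance is conjunctive — ion score ≥ 25 **and** chance probability
< 0.05 — keeping both published filter criteria meaningful; one best PSM is
retained per spectrum (ties: more matched fragments, then lexicographically
smaller peptide). The estimated FDR is `#decoys accepted / max(1, #targets
accepted)` at the same filter.

### Background competition

A search space containing only BLG gives non-BLG spectra nothing better to
match than BLG, inflating false positives — real searches run against the
full proteome, where a bacterial spectrum is claimed by its own peptide.
The search index therefore accepts an optional background/contaminant
FASTA (digested and decoyed identically); the synthetic generator emits its
background proteome for exactly this purpose, and real runs can pass any
contaminant database. BLG accounting is unaffected: only peptides with a
panel diagnostic taxon count toward positivity.

## Per-sample calls, coverage, cohorts

A sample's consensus taxon is the LCA of all its accepted diagnostic taxa
(so added peptides can only move the call toward the root); species-level
assignments populate `species_hits`, and two or more species set the
multi-species flag. A sample is BLG-positive with even a single accepted
spectrum — the weakest published positive is a single-spectrum individual —
and spectra counts are reported so users can apply stricter thresholds.
Coverage is `100 · |union of [start, end) intervals| / consensus length`,
computed on the panel consensus via leftmost exact match under the active
equivalence; species-variant peptides that differ from the majority
consensus do not map and are excluded with a logged warning, so per-sample
coverage is conservative. Pooled extracts (several individuals, one
sample) are first-class, counted once and flagged. Regional summaries
preserve input order and report samples, positives, total spectra and the
pooled note; `positive_fraction` reports `100 · Σ positives / Σ samples` to
one decimal.

The package also ships a transcription of the published survey's regional
summary (11 regions, 98 individuals; Eurasian subtotal 74 samples / 19
positive = 25.7%) as structured example data for the aggregation layer.

## Lactase-persistence surfaces

Observations are (lat, lon, combined causal-allele frequency p, sample
size); the five known causal variants are treated as allelic at one locus
and summed. Phenotype frequency under dominant inheritance and
Hardy–Weinberg is `1 − (1 − p)²`. The surface is a Nadaraya–Watson
estimate with Gaussian kernel, weights equal to sample size, and planar
lon/lat distances (a deliberate simplification; distances are distorted at
high latitude). Bandwidth selection walks a geometric ladder (0.25° × 2^(k/2))
and returns the smallest sigma at which every grid cell's relative kernel
mass exceeds a floor (default 10⁻⁶ of total weight) — the "lowest
non-overflowing" bandwidth for heterogeneous data. Cells below the floor
are flagged unreliable but still carry the ratio (nearest-point value if
the kernel mass underflows entirely), never NaN.

## Synthetic data generator

The generator emulates what the analysis assumes about real data:

- true spectra draw peptides uniformly from the chosen species' detectable
  digest; every Cys is carbamidomethylated (the experimental derivatization
  the search models as a fixed modification) and each N/Q site deamidates
  independently with the sample's deamidation rate (default 0.3, a
  moderately degraded ancient sample);
- precursor m/z error is Gaussian with SD = 10 ppm / 3 and fragment error
  Gaussian with SD = 0.07 Da / 3, so ~99.7% of true signals fall inside
  the nominal search windows — tolerances stay meaningful without modeling
  instrument physics;
- fragments drop out with probability 0.1, ten uniform noise peaks are
  added per spectrum, intensities are log-normal (the scorer ignores
  intensity; only the 200-peak cap consumes rank);
- the background proteome is three shuffled copies of each panel sequence —
  adequate to exercise chance-match behaviour, though it shares residue
  composition with BLG and therefore produces *more* near-isobaric
  confusable peptides than a real oral microbiome would, making it a
  conservative stressor; it does not reproduce real bacterial biology;
- controls (extraction blanks, fetuin standards) contain background spectra
  only;
- LP observations draw binomial allele counts (2N draws for N diploids)
  from a smooth latent field, by default a northward logistic cline.

Everything derives from a single seed; outputs are byte-stable.

What passing synthetic tests does **not** show: robustness to chimeric
spectra, isotope-envelope errors, retention-time artifacts, real bacterial
proteomes, or panel incompleteness (a consumer of a species missing from
the panel can only be called at a higher taxon, or missed).

## Problem sizes used in checks

The seeded end-to-end checks run 20 cohorts of 3 single-species samples
(12 true spectra each) plus two controls, and one survey-shaped cohort of
33 samples — sizes chosen so the whole suite exercises every stage in
about a minute while leaving the binomial sampling error on recovery and
FDR estimates well below the asserted margins.

## Known limitations

- The ion score is a calibrated approximation, not a reimplementation of a
  commercial search engine; absolute score values are not comparable to
  Mascot's.
- Coverage on the majority consensus undercounts species-variant regions.
- Planar-degree kernel smoothing distorts high-latitude distances.
- The bundled panel is synthetic; species calls on real data require a
  curated ortholog panel.
- Quantitative abundance inference from spectral counts is out of scope.
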