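# milkstone

Detection of ancient milk consumption from dental-calculus proteomics.

Dental calculus (mineralized dental plaque) preserves dietary proteins for
millennia. The whey protein β-lactoglobulin (BLG) is a specific biomarker of
milk consumption: humans do not produce it, it occurs only in milk, it
survives digestion and diagenesis unusually well, and enough of its residues
vary among dairy livestock that cattle (*Bos*), buffalo (*Bubalus*), sheep
(*Ovis*), goat (*Capra*), reindeer (*Rangifer*) and horse (*Equus*) can be
told apart from peptide sequence alone. `milkstone` implements the full
desk-side analysis for this biomarker, for archaeological scientists and
palaeoproteomicists:

- **reference panel** — multi-species BLG ortholog panel with taxonomic
  lineages; semi-tryptic in-silico digestion (cleavage after K/R, not before
  P; ≤2 missed cleavages; 7–30 residues, 600–3500 Da), enumeration of
  modified forms (fixed carbamidomethyl-C; variable deamidation N/Q,
  N-terminal pyroglutamate, Met oxidation, Pro hydroxylation, protein
  N-terminal acetyl), reversed decoys, a majority-vote consensus sequence,
  and each peptide's diagnostic taxon (the lowest common ancestor of all
  species whose digest contains it, with Ile/Leu always equivalent and
  N/D + Q/E equivalent under deamidation-aware matching);
- **spectrum search** — MGF peak lists (200 most intense peaks) matched to
  candidate peptides within ±10 ppm precursor tolerance; b/y fragment
  ladders matched greedily within ±0.07 Da; a binomial ion score on the
  `-10·log10 P` scale; acceptance at ion score ≥ 25 with chance probability
  < 0.05, and target–decoy false-discovery-rate reporting;
- **taxonomy & coverage** — per-sample consensus dairy-taxon calls,
  species-level flags, multi-species detection, and protein coverage as the
  union of peptide intervals on the panel consensus;
- **cohort summaries** — per-region tables (samples, BLG-positive
  individuals, spectra; pooled extracts counted once) and headline
  positivity fractions;
- **lactase-persistence maps** — conversion of combined causal-allele
  frequencies *p* (−13907\*G, −13910\*T, −13915\*G, −14009\*G, −14010\*C) to
  phenotype frequencies `1 − (1 − p)²` under dominant inheritance, and a
  sample-size-weighted Gaussian-kernel (Nadaraya–Watson) surface at the
  lowest bandwidth whose kernel mass covers every grid cell;
- **synthetic cohorts** — a ground-truthed generator (instrument mass error,
  peak dropout, noise peaks, age-dependent deamidation, a shuffled-sequence
  background proteome, extraction-blank and fetuin controls) so the whole
  pipeline is testable without any data downloads.

The bundled ortholog panel is a constructed, clade-structured approximation
(see `src/milkstone/data/synthetic_blg_panel.fasta` and
[docs/methods.md](docs/methods.md)); real analyses should substitute a
curated panel FASTA.

## Worked example

Simulate a small cohort (six individuals, three of them cattle-milk
consumers, plus a blank and a fetuin control), then run the full search:

```bash
milkstone simulate --seed 7 --n-samples 6 --n-positive 3 \
    --species Bos --true-spectra 12 --controls 2 --out-dir cohort
milkstone search cohort/*.mgf \
    --background-fasta cohort/background_proteins.fasta \
    --sample-meta cohort/samples.tsv --out-dir out
```

`out/sample_results.tsv` then contains:

```
sample_id  positive  consensus_taxon  species_hits  total_blg_spectra  coverage_pct
CTRL00     False                                    0                  0.0
CTRL01     False                                    0                  0.0
S000       True      Pecora           Bos           12                 43.2
S001       True      Pecora           Bos           12                 24.1
S002       True      Pecora           Bos           12                 38.3
S003       False                                    0                  0.0
...
```

Each planted consumer is recovered with all 12 milk spectra, carries
cattle-specific (*Bos*) peptides, and the consensus call is the ruminant
infraorder Pecora (conserved peptides shared across ruminants pull the
lowest common ancestor above genus level). Negatives and both controls stay
BLG-free. `out/fdr_summary.tsv` reports the target–decoy filter:

```
score_cutoff  alpha  targets_accepted  decoys_accepted  estimated_fdr
25.0          0.05   191               0                0.0
```

and `out/cohort_summary.tsv` aggregates per region (`Synthetic: 6 samples,
3 positive, 36 spectra; Controls: 2 samples, 0 positive`). The same reports
can be produced from an identified-peptide table without spectra
(`milkstone assign peptides.tsv`), and `milkstone lpmap lp_points.tsv`
smooths an allele-frequency table into a phenotype surface.

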