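# mppqtl

Mixed-model QTL mapping toolkit for 8-founder multiparental mouse
populations (Collaborative Cross / Diversity Outbred style data), as a
Python library plus CLI.

It covers the full analysis chain on a self-describing on-disk "study
bundle":

- **data_model** — domain types (genotype probabilities, marker map, trait
  matrices, covariates, founder SNPs) with validation, a directory bundle
  format (CSV/TSV/JSON metadata + HDF5 probability arrays), and JSON/CSV
  result export.
- **kinship** — genetic relationship matrices from founder-dosage
  probabilities, including the leave-one-chromosome-out (LOCO) family.
- **scan** — REML null fits (eigen-rotated mixed model) and genome-wide
  LOD scans, additive and locus-by-factor interactive; reduces to
  Haley–Knott-style regression with kinship disabled.
- **effects** — per-marker founder allele effects as fixed coefficients or
  shrunken BLUPs (per-marker REML variance ratio).
- **snps** — strain-distribution-pattern (SDP) collapse of haplotype
  probabilities to biallelic dosages and regional variant association with
  (nearest marker, SDP) deduplication.
- **mediation** — LOD-drop mediation: retest a locus conditioning
  one-by-one on candidate -omic mediators (kinship excluded, per-mediator
  complete cases and null refits).
- **summaries** — peak calling with support intervals, local/distal
  transcriptome maps, hotspot counts, covariate-adjusted correlations,
  profile summaries.
- **simulate** — DO-style synthetic studies: Markov founder mosaics,
  founder SNP tables, traits with planted QTL/covariate/polygenic
  architectures and mediation chains, all seed-deterministic.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(oracle equivalence, planted-QTL recovery, BLUP shrinkage, mediation
recovery, SDP machinery, invariance suite).

## CLI

Everything is reachable through one entry point:

```sh
mppqtl --show-config                      # print defaults
mppqtl --config sim.json simulate --out study/
mppqtl scan     --bundle study/ --trait gene1 --out scan.csv
mppqtl scan     --bundle study/ --trait gene1 --intcovar sex --out delta.csv
mppqtl effects  --bundle study/ --trait gene1 --chr 1 --blup --out eff.csv
mppqtl snpassoc --bundle study/ --trait gene1 --region 1:30-70 --out snps.json
mppqtl mediate  --bundle study/ --trait gene1 --chr 1 --marker c1_m0016 \
                --against sim --out med.csv
mppqtl peaks    --bundle study/ --trait gene1 --threshold 7 --out peaks.csv
mppqtl tmap     --bundle study/ --out tmap.csv
mppqtl correlate --bundle study/ --trait gene1 --adjust sex --out corr.csv
mppqtl profile  --bundle study/ --trait gene1 --factors sex --out prof.csv
```

Exit codes: 0 success, 1 runtime failure (one-line diagnostic), 2 usage
error. Outputs are CSV or JSON depending on the `--out` extension; results
are byte-identical across reruns with the same inputs and seeds.

A minimal simulation config:

```json
{
  "simulate": {
    "seed": 42,
    "n_individuals": 200,
    "chromosomes": [{"name": "1", "n_markers": 101}, {"name": "2", "n_markers": 101}],
    "traits": [
      {"trait_id": "gene1",
       "qtls": [{"chrom": "1", "marker_index": 50, "var_frac": 0.4, "sdp": 34}],
       "h2": 0.2,
       "annotation": ["2", 40.0]}
    ],
    "snp_density_per_Mbp": 1.0
  }
}
```

## Bundle format

A bundle directory contains `control.json` naming all components: a marker
map CSV (`marker_id, chromosome, pos_cM, pos_Mbp`), one HDF5 file per
chromosome with the `(individuals, 8, markers)` probability array plus id
labels, covariate and trait CSVs (first column = individual id; empty or
`.` cells are missing), optional per-dataset annotation CSVs
(`trait_id, symbol, chromosome, midpoint_Mbp`), and an optional founder
SNP TSV (`snp_id, chr, pos_Mbp, ref, alt, sdp, csq`; `sdp` is the 8-bit
carrier pattern, bit 0 = A/J … bit 7 = WSB/EiJ). Individuals present in
only some components are intersected (warning at ≥50% overlap, error
below). R data objects (RData/RDS) are not parsed; export such data to
these CSV/TSV forms with a few lines of R (`write.csv`, `rhdf5`).
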