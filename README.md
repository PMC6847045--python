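# pdcovar

Protein–DNA covariation analysis and substrate-depletion profiling for
meganuclease (LAGLIDADG homing endonuclease) families.

Meganucleases recognize long (14–22 bp) DNA target sites, and the protein
residues that read out each base tend to vary together with that base across
the family. `pdcovar` implements the two computational arms of this kind of
study:

1. **Covariation.** Each family member's protein sequence is concatenated
   with its own target site into one alignment row. Mutual information (MI,
   in bits) is computed between every pair of alignment columns, corrected
   with the average-product correction (APC), and Z-standardized over the
   whole pair pool:

   - `MI(i, j) = Σ p(x, y) · log2 [ p(x, y) / (p(x) · p(y)) ]`
   - `APC(i, j) = MĪ(i) · MĪ(j) / MĪ`, `MIp = MI − APC`
   - `Zpx = (MIp − mean(MIp)) / sd(MIp)`

   High-Zpx protein–DNA pairs are candidate specificity contacts. Their
   significance is assessed with a permutation null: the DNA target sites
   are shuffled relative to the proteins, the alignment is rescored, and
   the observed Zpx is compared with the shuffled distribution
   (empirical `p = (1 + #{null ≥ observed}) / (n + 1)`).

2. **Substrate-depletion kinetics.** A library of target-site substrates
   (all 256 variants of the central 4 bases, flanked by constant sequence)
   is cleaved in vitro and sequenced over a timecourse. Reads are
   demultiplexed by exact barcode match, cores are extracted by flank
   matching (≤1 mismatch per flank), and counts are transformed per sample
   with the centered log-ratio (CLR). The per-substrate depletion rate
   `k_rel` is the pooled OLS slope of CLR versus time. Two enzymes are
   compared substrate-by-substrate: a point `(k_A, k_B)` outside an
   axis-aligned ellipse (semi-axes `n_sd · σ` per enzyme, centered on the
   identity-matched mean) is called differential.

Synthetic generators for both data types — alignments with *planted*
covarying pairs and FASTQ depletion timecourses with known rates — are part
of the package and are used to validate the statistical pipeline end to end.

## Worked example

```python
from pdcovar import (
    FamilyConfig, PlantedPair, simulate_family,
    score_pairs, top_pairs, null_distribution, empirical_p,
)

fam = simulate_family(FamilyConfig(planted_pairs=(PlantedPair(10, 3, 0.9),),
                                   seed=20240101))
table = score_pairs(fam.alignment)          # 3,655 scoreable pairs
best = top_pairs(table, 1).iloc[0]          # pos_i='10', pos_j='+3', zpx≈17.7

nd = null_distribution(fam.alignment, ("10", "+3"), 1000, "assignment",
                       seed=20240103)
empirical_p(nd)                             # 1/1001 ≈ 0.000999
```

The planted protein-position-10 / DNA-position-+3 pair scores Zpx ≈ 17.7
(next-best pair ≈ 7.7) and exceeds all 1,000 shuffled scores.

## Analysis pipeline

Numbered scripts under `analysis/` run the full study on simulated data and
write tables under `results/`:

| script | output |
| --- | --- |
| `01_simulate_family.py` | 28-member concatenated alignment + truth record |
| `02_score_covariation.py` | `pair_scores.tsv` (MI/APC/MIp/Zpx per pair) |
| `03_null_distribution.py` | 1,000-shuffle null for the top protein–DNA pair |
| `04_simulate_depletion.py` | count tables for a parent and a variant enzyme |
| `05_fit_rates.py` | per-substrate `k_rel` fits (truth recovery r ≈ 0.9998) |
| `06_compare_enzymes.py` | differential substrates + base-preference matrix |

In the shipped demo the variant cleaves substrates with G at position +3
faster by 0.15/min; the comparison flags 63 of those 64 substrates (side B,
no false positives, wild-type CAAC unflagged) and the preference matrix of
the flagged set shows G at +3 with probability 1.0.

A command-line interface mirrors the scripts: see `pdcovar --help`
(`build-alignment`, `score`, `null`, `counts`, `rates`, `compare`,
`simulate`).

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities of the pipeline — substrate-library
enumeration, MI agreement with a brute-force oracle, Zpx standardization,
planted-pair recovery and decoy p-value calibration over 200 simulated
families, shuffle-null significance of a coupled pair, kinetic-rate
recovery, differential false positives under equal rates, and FASTQ
round-trip conservation — and writes them as JSON
(`{"name": {"value": ..., "n": ...}}`).

See `docs/methods.md` for the statistical methods, parameter defaults and
known limitations.
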