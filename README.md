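# transpred

Classification of protein sequences as transporter (T) or non-transporter
(NT) by a stacked ensemble of six base classifiers:

- **Three RBF-SVM models** over *psi-composition* features — the mean of a
  composition descriptor (AAC, dipeptide PAAC, or pseudo amino acid
  composition PseAAC) taken over the query sequence and the gap-free
  aligned regions of its PSI-BLAST homologs.
- **Three homology-transfer rules** — BLAST against a curated transporter
  database, labeling T when a hit passes one of three threshold profiles
  (`TCDB_exact`, `TCDB_high`, `TCDB_med`).

The six hard labels are aggregated by a gradient-boosting meta-classifier
trained on cross-validated base predictions (stacked generalization), so
the meta-feature row for each training instance comes only from models
that never saw it.

## Layout

| module | role |
| --- | --- |
| `transpred.seqio` | FASTA I/O, 20-letter sanitation, labeled datasets |
| `transpred.descriptors` | AAC / PAAC / PseAAC + standardized property tables |
| `transpred.homologs` | (PSI-)BLAST homolog collection, psi-/blast-composition |
| `transpred.tcdb_transfer` | tabular hit parsing, threshold profiles, rule predictions |
| `transpred.base_models` | SVM grid-search training and prediction |
| `transpred.stacking` | meta-feature generation, GBM meta-classifier, final prediction |
| `transpred.evaluation` | sensitivity/specificity/accuracy/MCC, repeated 10-fold CV, prediction correlation |
| `transpred.synthetic` | seeded generators for sequences, homolog sets, and hit tables |
| `transpred.cli` | `transpred` command-line entry point |

Homolog search is an interface with two backends: an external BLAST+
subprocess (`psiblast` / `blastp` on PATH, database formatted with
`makeblastdb`) and an in-memory stub fed by tabular fixture files. All
unit tests run against the stub; live-search integration tests are
skipped automatically when BLAST+ is absent.

## CLI

```sh
# generate a seeded synthetic fixture set (FASTA + labels + hit table)
transpred simulate --seed 7 --n-per-class 50 --out-dir sim/

# train the six-base stacked ensemble
transpred train sim/sequences.fasta sim/labels.tsv \
    --tcdb-hits sim/tcdb_hits.tsv --simulate-homologs \
    --seed 7 --out model.joblib

# predict: six base votes + final ensemble label per query
transpred predict sim/sequences.fasta --model model.joblib \
    --tcdb-hits sim/tcdb_hits.tsv --out predictions.tsv

# score predictions against a label table
transpred evaluate predictions.tsv sim/labels.tsv

# descriptor tables and per-profile homology calls
transpred features sim/sequences.fasta --kind PseAAC --out features.tsv
transpred homology sim/sequences.fasta --hits sim/tcdb_hits.tsv --out ath.tsv
```

All tables are tab-delimited with a `#`-prefixed provenance header
(version, config hash, seed). One master seed drives every source of
randomness, so identical inputs and seed reproduce identical outputs
byte for byte.

## Notes

- Descriptor component order is fixed and documented: `AAC_A`..`AAC_Y`
  alphabetically; `PAAC_AA`..`PAAC_YY` row-major; PseAAC is 20
  composition terms then `theta1`..`theta<lambda>`.
- PseAAC defaults: lambda 30, omega 0.05; sequences with L <= lambda are
  an error unless clamp mode is enabled (lambda reduced to L-1, tail
  zero-padded to the declared length).
- Nonstandard residues (B, J, O, U, X, Z, gaps, `*`) are deleted during
  sanitation, not remapped; lengths are post-filter.
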