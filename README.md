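# lectern

Peptide database search for tandem mass spectrometry with pluggable PSM
score functions, peptide-level target-decoy FDR, and a ground-truthed
spectrum simulator.

`lectern` is aimed at people studying *score functions* for database
search: it runs the whole chain — in-silico tryptic digestion with
modifications, shuffled mass-preserving decoys, candidate retrieval by
precursor ppm window, scoring, and double-competition FDR estimation —
with the scorer as a swappable component, so different score functions can
be compared on byte-identical candidate lists.

Four scorers are built in:

- **teacher-forced autoregressive score**: a sequence model emits
  P(next residue | spectrum, prefix); the candidate's own sequence is fed
  back position by position (teacher forcing, no decoding) and the PSM
  score is the log of the geometric mean of the per-position
  probabilities, `(1/n)·Σ log x_i`. The geometric mean penalizes
  low-confidence positions far more than the arithmetic mean (also
  provided, for ablation) — the property that makes the score usable for
  ranking wrong-but-plausible candidates. A deterministic fragment-ion
  evidence model implements the contract out of the box; trained models
  plug in via a registry.
- **XCorr**: background-corrected cross-correlation of binned spectra.
- **Hyperscore**: `ln(n_b!·n_y!·ΣI_b·ΣI_y)` over matched b/y ions.
- **Andromeda**: binomial significance `−10·log10 P(X ≥ k)`,
  `X ~ Binomial(n, q/100)`, maximized over the top-q peak filter.

FDR is estimated by peptide-level target-decoy competition: per-spectrum
competition, per-peptide collapse, head-to-head target-vs-paired-decoy
competition, then `FDR_k = min(1, (D_k+1)/T_k)` down the ranked list with
acceptance at the largest k strictly below α (default 0.01), plus
q-values, the target match percentage (TMP), and precursor-m/z quartile
stratification.

## Worked example

Simulate a ground-truthed dataset, search it, and compare scorers:

```sh
lectern simulate --out demo --n-proteins 15 --protein-length 250 \
    --n-spectra 60 --seed 13
lectern run --fasta demo/proteome.fasta --mgf demo/spectra.mgf \
    --out demo/out --seed 13
```

which prints

```
spectra=60 with_candidates=60 psms=60 tmp=1.0000
detections at alpha=0.01: 0
```

All 60 spectra received candidates, every spectrum-level winner was a
target (TMP = 1.0), and yet detections at 1% FDR are 0: with only ~60
surviving peptides the estimate `(D_k+1)/T_k` can never drop below
1/60 ≈ 0.017, so nothing clears α = 0.01 — the +1-corrected estimator is
deliberately conservative at small scale. The same search at
`--alpha 0.02` accepts all 60. `demo/out/` contains `psms.mztab` (top PSM
per spectrum), `detections.tsv` (peptide, score, label, FDR, q-value),
`psms.pin` (Percolator input), and `search.log`.

Comparing scorers on identical candidate lists:

```sh
lectern compare --fasta demo/proteome.fasta --mgf demo/spectra.mgf \
    --out demo/cmp --scorers evidence,xcorr,random
```

tabulates detections across FDR thresholds 0.001–0.1 per scorer; on this
fixture the evidence scorer and XCorr each hold TMP = 1.0 while the
random baseline sits at TMP ≈ 0.6 with zero detections everywhere.

The same machinery is available as a library:

```python
from lectern import (SearchConfig, build_database, search_spectra)
from lectern.pipeline import make_scorer
from lectern.simulate import SimulationParams, simulate_proteome, simulate_spectra

params = SimulationParams(seed=1)          # 50 proteins, 200 spectra,
records = simulate_proteome(params)        # coverage 0.9, 5 ppm jitter
db = build_database(records, decoy_seed=1)
spectra, truth = simulate_spectra(records, params)
cfg = SearchConfig(seed=1)
result = search_spectra(db, spectra, make_scorer(cfg), cfg)
print(result.tmp.tmp, len(result.accepted))   # -> 1.0 200
```

## Layout

| module                 | contents                                             |
| ---------------------- | ---------------------------------------------------- |
| `lectern.digest`       | FASTA parsing, digestion, modified forms, decoys, mass index |
| `lectern.spectra`      | MGF I/O, binning, top-q filtering, mzTab/PIN writers |
| `lectern.classic`      | theoretical fragments, XCorr, Hyperscore, Andromeda  |
| `lectern.learned`      | teacher forcing, aggregation, evidence model, registry |
| `lectern.tdc`          | competitions, FDR/q-values, TMP, stratification      |
| `lectern.pipeline`     | end-to-end orchestration, scorer comparison          |
| `lectern.simulate`     | synthetic proteomes, signal and null spectra         |

See `docs/methods.md` for the model, its assumptions, and what the
synthetic benchmarks do and do not demonstrate.
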