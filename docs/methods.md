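# Methods

## The problem

A tandem-MS database search assigns to each observed MS2 spectrum the
peptide, out of a database of candidates whose masses fit the precursor,
that most plausibly generated it, and then controls the error rate of the
resulting peptide list. `lectern` implements the full chain — digestion,
candidate indexing, scoring, and peptide-level target-decoy FDR — with the
score function as a pluggable component, so that a learned autoregressive
scorer can be compared against the classic hand-designed scores on an
identical footing.

## Search space

Proteins are digested with a configurable cleavage rule, by default
trypsin with proline suppression (`[RK]|{P}`): cleavage after K or R
except before P, with up to one missed cleavage. Peptides of 6–50
residues are kept (common engine defaults; bounds are configurable).
Modified forms are enumerated from a scheme that defaults to static
carbamidomethylation of cysteine (C+57.02146 Da), variable methionine
oxidation (M+15.994915) and asparagine/glutamine deamidation (+0.984016),
and four mutually exclusive N-terminal deltas (+42.010565, +43.005814,
−17.026549, +25.980265); at most three variable modifications per peptide,
with an applied N-terminal modification counting toward that budget.
Masses are monoisotopic; neutral peptide mass is the residue sum plus
modification deltas plus water (18.0105646863 Da).

Each unique modified target peptide is paired with one decoy: a seeded
permutation of its residues (modifications traveling with their residues)
that fixes the C-terminal residue, preserving tryptic character and
leaving the mass exactly unchanged. Up to 20 redraws avoid reproducing
the target; unshufflable peptides (homopolymers, length ≤ 2) are flagged
so the downstream pair competition can drop them, and a decoy that would
duplicate another peptide's sequence string is re-seeded (then flagged),
keeping the target↔decoy pairing a bijection. Targets and decoys are
indexed jointly by neutral mass; the candidates for a spectrum are those
inside the ±20 ppm window around the precursor-derived neutral mass
M = z·(m/z − proton).

## Score functions

**Teacher-forced autoregressive score.** A sequence model defines
conditional distributions P(next token | spectrum, prefix) over an
alphabet of residue tokens (modified residues are distinct tokens,
N-terminal modifications are prefix tokens) plus a stop token. A
candidate is scored without any decoding: its own tokens are fed back as
the prefix at each position (teacher forcing), giving per-position
probabilities x_1..x_n for the true tokens, and the PSM score is
(1/n)·Σ log x_i — the log of the geometric mean. Relative to the
arithmetic mean (1/n)·Σ x_i (provided for ablation), the geometric mean
punishes a candidate sharply for even one low-confidence position, which
matters in database search where most candidates are wrong and
calibration across good and bad matches drives both ranking and FDR
behavior. Probabilities are floored at 1e-12 so scores stay finite; the
stop token is not part of the n scored positions.

The built-in `EvidenceModel` realizes this contract deterministically and
without training: the evidence for appending token a (mass m_a) to a
prefix of mass m_p is the summed max-normalized intensity of observed
peaks within the fragment tolerance of the extended prefix's b-ion
(m_p + m_a + proton) or of its complementary y-ion
(M − m_p − m_a + proton); the stop token receives a bonus of 1 once the
prefix mass matches the precursor within tolerance and −50 otherwise; the
conditional is softmax(β·evidence) with β = 5. β was set so that a
single clean fragment peak dominates the distribution while evidence-free
positions fall back to a near-uniform prior; the same fragment tolerance
as the search (20 ppm) is used. Any genuinely trained model can be
plugged in through the model registry; the evidence model exists so the
entire search, competition, and FDR machinery is exercised end to end by
fast, deterministic code.

**XCorr.** The observed spectrum is binned at 1.0005079 Da, square-root
transformed, and normalized in 10 equal m/z regions to a maximum of 50.
The theoretical spectrum holds constant-intensity peaks (50 for b/y, 10
for a-ions and ammonia/water losses). The score is ⟨u,v⟩ minus the mean
of ⟨u shifted by r, v⟩ over offsets r = −75..75 excluding 0 (150
offsets): the correlation at the true alignment corrected by the
background correlation. The r = 0 term is excluded because including it
would subtract part of the signal itself and make the normalizer
inconsistent with the 1/150 factor.

**Hyperscore.** With n_b matched b-ions and n_y matched y-ions and their
intensities normalized by the spectrum's maximum,
score = ln(n_b!·n_y!·ΣI_b·ΣI_y), computed via log-gamma; 0 when either
series is unmatched. Natural log is used.

**Andromeda.** For each q in 1..10 the spectrum is filtered to its q most
intense peaks per 100 m/z; with n theoretical peaks of which k match
within tolerance, the candidate score is −10·log10 P(X ≥ k) for
X ~ Binomial(n, q/100), and the maximum over q is returned (ties to the
smaller q). The tail-probability form is the original score's
convention; a bare-pmf variant (`mode="pmf"`) maximizing
C(n,k)(q/100)^k(1−q/100)^(n−k) is provided for comparison.

**Peak matching.** A theoretical fragment at m/z m matches an observed
peak within m·tol·1e-6; each observed peak supports at most one fragment
per ion series, closest pairing first.

## Target-decoy competition and FDR

The peptide-level double-competition procedure: (1) per spectrum, the
top-scoring candidate (target or decoy) becomes its PSM; (2) per peptide,
only the best PSM survives; (3) each target competes against its paired
decoy, an unmatched side losing automatically; (4) survivors are ranked
by score and FDR at rank k is min(1, (D_k+1)/T_k) with D_k, T_k the decoy
and target counts among the top k (FDR = 1 while T_k = 0). The accepted
set at level α is the targets within the largest k whose estimate is
strictly below α (default α = 0.01). q-values are the running minimum of
the FDR over worse thresholds, added for reporting; the acceptance rule
itself uses the raw estimate. Every exact tie, at every stage, resolves
toward the decoy — the conservative direction for FDR control.

The target match percentage, TMP = T/(T+D) over spectrum-level PSMs, is
reported as a calibration-free companion: it measures only within-spectrum
ranking and so can be high even when scores are incomparable across
spectra. PSM lists can be stratified into the empirical bottom (≤ Q1) and
top (≥ Q3) precursor-m/z quartiles for separate competition, which
isolates the short-peptide regime where learned scores tend to be
overconfident.

One interaction is worth stating plainly: with the evidence model,
candidates having zero fragment evidence at every position receive
identical scores (a uniform softmax at each step), and on null data the
tie-to-decoy rule then deflates TMP below 1/2 (≈0.36 observed) even
though targets and decoys are exchangeable. This is a deliberate bias in
the conservative direction and does not affect FDR control; the package's
exchangeability check therefore uses the tie-free random baseline scorer
(TMP ≈ 0.50 on null data). A trained model, which outputs distinct
probabilities everywhere, would not exhibit the tie mass.

## Synthetic data

The simulator generates proteins uniformly over the 20 residues (default
50 proteins × 300 residues), samples distinct tryptic peptides (static
modifications only), and emits per peptide: singly charged b/y fragment
peaks each retained with probability f (default 0.9), log-normal(0, 0.5)
intensities, Gaussian m/z jitter (default 5 ppm), 20 uniform noise peaks
with intensities uniform on (0, median signal), and a precursor m/z
back-computed from the peptide mass at charge 2 or 3 with jitter inside
half the precursor tolerance. The null generator instead draws random
peptides (length 7–15, ending K/R) rejection-sampled to be absent from
the database's digest, making targets and decoys exchangeable.

What the simulator does not emulate: fragmentation intensity structure
(real b/y intensities are sequence-dependent, not i.i.d.), multiply
charged fragments, isotope envelopes, co-isolated chimeric spectra, and
retention time. Passing tests therefore demonstrate the correctness of
the machinery — formulas, competitions, error control, determinism, and
the qualitative ordering of scorers under controllable signal — not
real-data detection counts, which depend on a trained model and real
spectra.

## Numerical and design choices

- Residue masses from the standard monoisotopic table; proton
  1.00727646688 Da; all tolerances relative (ppm).
- Candidate retrieval by binary search over a mass-sorted array; closed
  intervals at both ends.
- Deterministic ordering everywhere: score descending, then decoy-first,
  then lexicographic modified sequence (and spectrum id), so reruns are
  byte-identical; decoy permutation seeds derive from a CRC of the
  modified sequence XORed with the configured decoy seed.
- Per-spectrum candidate lists are truncated to the top 20 scores for
  reporting and competition.
- mzTab output is minimal (MTD + PSM sections, scores at 6 decimals);
  the Percolator PIN export carries score, precursor m/z, and one-hot
  charge features only. Spectra lacking a charge annotation are skipped
  with a logged count, never guessed.
- Desk-scale problem sizes throughout the tests and the reproduction
  script (50-protein databases, 200–500 spectra, 25–50 null repetitions)
  keep full runs in the minutes range while leaving the statistics —
  binomial error on rates, the +1-corrected FDR estimate — interpretable.

## Known limitations

- The evidence model is a stand-in realization of the sequence-model
  contract, not a trained predictor; absolute score values are not
  comparable to any trained system's.
- Decoys by shuffling only (no reversal option); no semi-enzymatic or
  nonspecific digestion; no isotope-error precursor windows; no
  protein-level inference; Percolator itself is not run (only its input
  file is exported).
- At small survivor counts the (D_k+1)/T_k estimate cannot fall below
  1/T, so fewer than ~1/α surviving targets yields zero detections at
  level α by construction.
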