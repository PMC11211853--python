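"""Ground-truthed synthetic proteomes and MS2 spectra.

The simulator emulates the essentials of a data-dependent-acquisition MS2
run at desk scale: tryptic peptides drawn from random proteins, singly
charged b/y fragment peaks with log-normal intensities, per-peak dropout
(1 - fragment_coverage), Gaussian m/z jitter in ppm, uniform chemical-noise
peaks, and precursor m/z back-computed from the peptide mass and charge
with jitter inside half the precursor tolerance.  Every spectrum comes with
its generating peptide in a truth table, so ranking, TMP, and FDR behavior
can be measured against known answers.  A null generator draws peptides
verified absent from a database's digest, making targets and decoys
exchangeable — the condition under which FDR control can be audited.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .digest import (
    CleavageRule,
    FastaRecord,
    ModificationScheme,
    Peptide,
    TRYPSIN,
    default_modification_scheme,
    digest,
    enumerate_modified_forms,
    sequence_mass,
)
from .masses import CANONICAL, PROTON
from .spectra import Spectrum, write_mgf


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of a simulated run.

    fragment_coverage is the per-fragment retention probability; noise
    peaks are uniform over the observed m/z range with intensities uniform
    on (0, median signal intensity); m/z jitter is Gaussian with the given
    ppm standard deviation.  Precursor charges are drawn uniformly from
    ``charges``.
    """

    n_proteins: int = 50
    protein_length: int = 300
    n_spectra: int = 200
    fragment_coverage: float = 0.9
    noise_peaks: int = 20
    mz_jitter_ppm: float = 5.0
    intensity_mu: float = 0.0
    intensity_sigma: float = 0.5
    charges: tuple[int, ...] = (2, 3)
    precursor_tol_ppm: float = 20.0
    min_len: int = 6
    max_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_coverage <= 1.0:
            raise ValueError("fragment_coverage must lie in [0, 1]")
        if min(self.n_proteins, self.protein_length, self.n_spectra, self.noise_peaks) < 0:
            raise ValueError("counts must be non-negative")


def simulate_proteome(p: SimulationParams) -> list[FastaRecord]:
    """Random proteins with residues uniform over the 20-letter alphabet."""
    rng = np.random.default_rng(p.seed)
    letters = np.array(list(CANONICAL))
    return [
        FastaRecord(
            id=f"sim|P{i:04d}",
            description=f"sim|P{i:04d} synthetic protein {i}",
            sequence="".join(rng.choice(letters, size=p.protein_length)),
        )
        for i in range(p.n_proteins)
    ]


def write_fasta(records: list[FastaRecord], path) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.description}\n")
            for i in range(0, len(rec.sequence), 60):
                out.write(rec.sequence[i : i + 60] + "\n")


def _spectrum_from_peptide(
    pep: Peptide, sid: str, p: SimulationParams, rng: np.random.Generator
) -> Spectrum:
    """Fragment a peptide into a noisy spectrum under the simulation model."""
    from .classic import theoretical_fragments  # local import avoids a cycle

    frags = theoretical_fragments(pep, series={"b", "y"}, max_frag_charge=1)
    keep = rng.random(len(frags)) < p.fragment_coverage
    mz = frags.mz[keep]
    if p.mz_jitter_ppm > 0 and len(mz):
        mz = mz * (1 + rng.normal(0.0, p.mz_jitter_ppm * 1e-6, size=len(mz)))
    intensity = rng.lognormal(p.intensity_mu, p.intensity_sigma, size=len(mz))

    if p.noise_peaks > 0:
        lo = 100.0
        hi = max(float(frags.mz.max()) * 1.05, 500.0)
        noise_mz = rng.uniform(lo, hi, size=p.noise_peaks)
        ceiling = float(np.median(intensity)) if len(intensity) else 1.0
        noise_int = rng.uniform(0.0, ceiling, size=p.noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        intensity = np.concatenate([intensity, noise_int])

    charge = int(rng.choice(p.charges))
    precursor = (pep.neutral_mass + charge * PROTON) / charge
    half_tol = 0.5 * p.precursor_tol_ppm * 1e-6
    precursor *= 1 + rng.uniform(-half_tol, half_tol)
    return Spectrum(
        spectrum_id=sid, precursor_mz=precursor, charge=charge, mz=mz, intensity=intensity
    )


def _static_forms(
    sequences: list[tuple[str, int]],
    scheme: ModificationScheme,
    p: SimulationParams,
) -> list[Peptide]:
    """Length-filtered static-only peptide forms (the generating species)."""
    static_only = ModificationScheme(static_mods=dict(scheme.static_mods), max_variable=0)
    forms: list[Peptide] = []
    seen: set[str] = set()
    for seq, missed in sequences:
        if not (p.min_len <= len(seq) <= p.max_len) or seq in seen:
            continue
        seen.add(seq)
        forms.extend(enumerate_modified_forms(seq, static_only, missed))
    return forms


def simulate_spectra(
    records: list[FastaRecord],
    p: SimulationParams,
    rule: CleavageRule = TRYPSIN,
    scheme: ModificationScheme | None = None,
) -> tuple[list[Spectrum], dict[str, Peptide]]:
    """Spectra generated from peptides of the given proteome, plus the truth.

    Peptides are sampled without replacement from the distinct tryptic
    peptides of the proteome (carrying static modifications only).  Raises
    if the digest yields fewer valid peptides than ``n_spectra``.
    """
    if scheme is None:
        scheme = default_modification_scheme()
    rng = np.random.default_rng(p.seed + 1)
    pool = _static_forms(
        [sm for rec in records for sm in digest(rec.sequence, rule)], scheme, p
    )
    if len(pool) < p.n_spectra:
        raise ValueError(
            f"digest yields only {len(pool)} usable peptides; need {p.n_spectra}"
        )
    chosen = rng.choice(len(pool), size=p.n_spectra, replace=False)
    spectra: list[Spectrum] = []
    truth: dict[str, Peptide] = {}
    for i, j in enumerate(chosen):
        pep = pool[int(j)]
        sid = f"sim_scan_{i:05d}"
        spectra.append(_spectrum_from_peptide(pep, sid, p, rng))
        truth[sid] = pep
    return spectra, truth


def null_spectra(
    p: SimulationParams,
    excluded: list[FastaRecord],
    rule: CleavageRule = TRYPSIN,
    scheme: ModificationScheme | None = None,
) -> tuple[list[Spectrum], dict[str, Peptide]]:
    """Spectra from random tryptic-looking peptides absent from a proteome.

    Each generating peptide ends in K or R and is rejection-sampled until
    its bare sequence does not occur among the proteome's digest products,
    so no database target can be the true generator.
    """
    if scheme is None:
        scheme = default_modification_scheme()
    rng = np.random.default_rng(p.seed + 2)
    forbidden = {
        seq for rec in excluded for seq, _ in digest(rec.sequence, rule)
    }
    static_only = ModificationScheme(static_mods=dict(scheme.static_mods), max_variable=0)
    letters = list(CANONICAL)
    spectra: list[Spectrum] = []
    truth: dict[str, Peptide] = {}
    hi_len = min(p.max_len, 15)
    for i in range(p.n_spectra):
        while True:
            length = int(rng.integers(max(p.min_len, 7), hi_len + 1))
            body = "".join(rng.choice(letters) for _ in range(length - 1))
            seq = body + ("K" if rng.random() < 0.5 else "R")
            if seq not in forbidden:
                break
        pep = enumerate_modified_forms(seq, static_only)[0]
        sid = f"null_scan_{i:05d}"
        spectra.append(_spectrum_from_peptide(pep, sid, p, rng))
        truth[sid] = pep
    return spectra, truth


def write_truth_table(truth: dict[str, Peptide], path) -> None:
    """Tab-separated (spectrum_id, bare sequence, modified sequence)."""
    with open(path, "w") as out:
        out.write("spectrum_id\tpeptide\tmodified_peptide\n")
        for sid in sorted(truth):
            pep = truth[sid]
            out.write(f"{sid}\t{pep.sequence}\t{pep.modified_sequence}\n")


def simulate_to_files(
    p: SimulationParams,
    fasta_path,
    mgf_path,
    truth_path,
    rule: CleavageRule = TRYPSIN,
    scheme: ModificationScheme | None = None,
) -> None:
    """One-call file-based simulation: FASTA + MGF + truth table."""
    records = simulate_proteome(p)
    write_fasta(records, fasta_path)
    spectra, truth = simulate_spectra(records, p, rule, scheme)
    write_mgf(spectra, mgf_path)
    write_truth_table(truth, truth_path)
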