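"""End-to-end database search orchestration.

digest -> index -> read spectra -> candidate query (ppm window) -> score ->
spectrum competition -> peptide collapse -> pair competition -> FDR ->
reports (mzTab, detection table, Percolator PIN, log).  All scorers run
behind one small interface so that the comparison mode can score the exact
same candidate lists with each score function.
"""
from __future__ import annotations

import logging
import os
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import classic, learned, tdc
from .digest import (
    CleavageRule,
    ModificationScheme,
    Peptide,
    PeptideDatabase,
    build_database,
    default_modification_scheme,
    precursor_window,
    read_fasta,
)
from .spectra import Spectrum, read_mgf, write_mztab, write_pin

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """All knobs of a search run, with the standard defaults.

    Tolerances are ppm; the cleavage rule string uses the
    ``[cut]|{suppress}`` notation; the modification scheme defaults to
    carbamidomethyl-C (static), oxidized M, deamidated N/Q, and the four
    N-terminal deltas.
    """

    fasta: str | None = None
    mgf: str | None = None
    out_dir: str | None = None
    precursor_tol_ppm: float = 20.0
    fragment_tol_ppm: float = 20.0
    cleavage_rule: str = "[RK]|{P}"
    max_missed: int = 1
    min_len: int = 6
    max_len: int = 50
    scheme: ModificationScheme = field(default_factory=default_modification_scheme)
    scorer: str = "evidence"
    aggregate: str = "geometric"
    alpha: float = 0.01
    decoy_seed: int = 0
    seed: int = 0
    top_k_report: int = 20

    def validate(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.aggregate not in learned.AGGREGATES:
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.min_len < 2 or self.max_len < self.min_len:
            raise ValueError("invalid peptide length bounds")

    @property
    def rule(self) -> CleavageRule:
        return CleavageRule.from_string(self.cleavage_rule, self.max_missed)

    @classmethod
    def from_yaml(cls, path) -> "SearchConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        scheme_data = data.pop("scheme", None)
        cfg = cls(**data)
        if scheme_data is not None:
            cfg.scheme = ModificationScheme(
                static_mods=dict(scheme_data.get("static_mods", {})),
                variable_mods=dict(scheme_data.get("variable_mods", {})),
                nterm_mods=tuple(scheme_data.get("nterm_mods", ())),
                max_variable=int(scheme_data.get("max_variable", 3)),
            )
        return cfg


# ---------------------------------------------------------------------------
# Scorer interface
# ---------------------------------------------------------------------------

class Scorer:
    """Scores a spectrum against a list of candidate peptides."""

    name: str = "scorer"

    def score_candidates(self, s: Spectrum, candidates: Sequence[Peptide]) -> list[float]:
        raise NotImplementedError


class LearnedScorer(Scorer):
    """Teacher-forced sequence-model scoring with a configurable aggregate."""

    def __init__(self, model: learned.SequenceModel | None = None, aggregate: str = "geometric"):
        self.model = model or learned.EvidenceModel()
        self.aggregate_name = aggregate
        self._aggregate = learned.AGGREGATES[aggregate]
        self.name = f"evidence-{aggregate}"

    def score_candidates(self, s: Spectrum, candidates: Sequence[Peptide]) -> list[float]:
        return [
            self._aggregate(learned.teacher_force(self.model, s, pep)) for pep in candidates
        ]


class XCorrScorer(Scorer):
    name = "xcorr"

    def score_candidates(self, s: Spectrum, candidates: Sequence[Peptide]) -> list[float]:
        return [classic.xcorr_psm(s, pep) for pep in candidates]


class HyperscoreScorer(Scorer):
    name = "hyperscore"

    def __init__(self, fragment_tol_ppm: float = 20.0):
        self.tol = fragment_tol_ppm

    def score_candidates(self, s: Spectrum, candidates: Sequence[Peptide]) -> list[float]:
        return [classic.hyperscore_psm(s, pep, self.tol) for pep in candidates]


class AndromedaScorer(Scorer):
    name = "andromeda"

    def __init__(self, fragment_tol_ppm: float = 20.0, q_max: int = 10, mode: str = "tail"):
        self.tol = fragment_tol_ppm
        self.q_max = q_max
        self.mode = mode

    def score_candidates(self, s: Spectrum, candidates: Sequence[Peptide]) -> list[float]:
        return [
            classic.andromeda_psm(s, pep, self.tol, self.q_max, self.mode) for pep in candidates
        ]


class RandomScorer(Scorer):
    """Seeded uniform scores, independent of spectrum content — the no-skill
    baseline against which real scorers are compared."""

    name = "random"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def score_candidates(self, s: Spectrum, candidates: Sequence[Peptide]) -> list[float]:
        out = []
        for pep in candidates:
            h = zlib.crc32(f"{self.seed}|{s.spectrum_id}|{pep.modified_sequence}".encode())
            out.append(h / 0xFFFFFFFF)
        return out


def make_scorer(cfg: SearchConfig) -> Scorer:
    if cfg.scorer == "evidence" or cfg.scorer.startswith("plugin:"):
        name = cfg.scorer.split(":", 1)[1] if ":" in cfg.scorer else "evidence"
        factory = learned.MODEL_REGISTRY[name]
        model = factory(fragment_tol_ppm=cfg.fragment_tol_ppm, precursor_tol_ppm=cfg.precursor_tol_ppm)
        return LearnedScorer(model, cfg.aggregate)
    if cfg.scorer == "xcorr":
        return XCorrScorer()
    if cfg.scorer == "hyperscore":
        return HyperscoreScorer(cfg.fragment_tol_ppm)
    if cfg.scorer == "andromeda":
        return AndromedaScorer(cfg.fragment_tol_ppm)
    if cfg.scorer == "random":
        return RandomScorer(cfg.seed)
    raise ValueError(f"unknown scorer {cfg.scorer!r}")


# ---------------------------------------------------------------------------
# Core search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    """Everything a search run computes, before/independent of file output."""

    psms: list[tdc.PSM]  # one per spectrum with >= 1 candidate
    detections: pd.DataFrame  # ranked peptide-level list with FDR/q-values
    accepted: list[tdc.PSM]  # target peptides accepted at alpha
    tmp: tdc.TmpResult | None
    n_spectra: int
    n_with_candidates: int
    top_candidates: dict[str, list[tuple[Peptide, float]]]  # per spectrum, top-k


def candidate_lists(
    db: PeptideDatabase, spectra: Sequence[Spectrum], precursor_tol_ppm: float
) -> dict[str, list[Peptide]]:
    """Mass-window candidate peptides (targets and decoys jointly) per spectrum."""
    out: dict[str, list[Peptide]] = {}
    for s in spectra:
        window = precursor_window(s.precursor_mz, s.charge, precursor_tol_ppm)
        out[s.spectrum_id] = db.index.query(*window)
    return out


def search_spectra(
    db: PeptideDatabase,
    spectra: Sequence[Spectrum],
    scorer: Scorer,
    cfg: SearchConfig,
    candidates: dict[str, list[Peptide]] | None = None,
) -> SearchResult:
    """Score spectra against the database and run the full TDC cascade."""
    cfg.validate()
    if candidates is None:
        candidates = candidate_lists(db, spectra, cfg.precursor_tol_ppm)

    per_spectrum: list[list[tdc.PSM]] = []
    top_candidates: dict[str, list[tuple[Peptide, float]]] = {}
    n_with = 0
    for s in spectra:
        cands = candidates.get(s.spectrum_id, [])
        if not cands:
            continue
        n_with += 1
        scores = scorer.score_candidates(s, cands)
        ranked = sorted(
            zip(cands, scores),
            key=lambda t: (-t[1], not t[0].is_decoy, t[0].modified_sequence),
        )[: cfg.top_k_report]
        top_candidates[s.spectrum_id] = ranked
        per_spectrum.append(
            [
                tdc.PSM(
                    spectrum_id=s.spectrum_id,
                    peptide=pep,
                    score=score,
                    is_decoy=pep.is_decoy,
                    precursor_mz=s.precursor_mz,
                    charge=s.charge,
                )
                for pep, score in ranked
            ]
        )

    psms = tdc.spectrum_competition(per_spectrum)
    best = tdc.peptide_collapse(psms)
    survivors = tdc.pair_competition(best, db.pairing, db.collisions)
    detections, accepted = tdc.estimate_fdr(survivors, cfg.alpha)
    tmp_result = tdc.tmp(psms) if psms else None
    return SearchResult(
        psms=psms,
        detections=detections,
        accepted=accepted,
        tmp=tmp_result,
        n_spectra=len(spectra),
        n_with_candidates=n_with,
        top_candidates=top_candidates,
    )


def write_detection_report(detections: pd.DataFrame, path) -> None:
    """Stable tab-separated detection list (fixed float formatting so that
    identical runs produce byte-identical files)."""
    frame = detections.copy()
    frame["label"] = np.where(frame["is_decoy"], "decoy", "target")
    frame = frame[["peptide", "score", "label", "fdr", "q_value"]]
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_search(cfg: SearchConfig) -> SearchResult:
    """File-based entry point: read inputs, search, and write all reports."""
    cfg.validate()
    if not cfg.fasta or not cfg.mgf or not cfg.out_dir:
        raise ValueError("fasta, mgf, and out_dir are required for run_search")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "search.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("lectern")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        records = read_fasta(cfg.fasta)
        db = build_database(
            records,
            rule=cfg.rule,
            scheme=cfg.scheme,
            min_len=cfg.min_len,
            max_len=cfg.max_len,
            decoy_seed=cfg.decoy_seed,
        )
        logger.info(
            "database: %d targets, %d decoys, %d collisions",
            len(db.targets),
            len(db.decoys),
            len(db.collisions),
        )
        spectra = read_mgf(cfg.mgf)
        scorer = make_scorer(cfg)
        result = search_spectra(db, spectra, scorer, cfg)

        write_mztab(result.psms, out / "psms.mztab")
        write_detection_report(result.detections, out / "detections.tsv")
        write_pin(result.psms, out / "psms.pin")
        logger.info(
            "spectra read: %d; with candidates: %d; PSMs: %d (T=%d, D=%d); "
            "TMP: %s; detections at alpha=%g: %d",
            result.n_spectra,
            result.n_with_candidates,
            len(result.psms),
            result.tmp.n_target if result.tmp else 0,
            result.tmp.n_decoy if result.tmp else 0,
            f"{result.tmp.tmp:.4f}" if result.tmp else "n/a",
            cfg.alpha,
            len(result.accepted),
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return result


# ---------------------------------------------------------------------------
# Scorer comparison
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = (0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1)


def compare_scorers(
    db: PeptideDatabase,
    spectra: Sequence[Spectrum],
    scorers: Sequence[Scorer],
    cfg: SearchConfig,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Detections-vs-FDR-threshold curves with identical candidates per scorer.

    The candidate list for every spectrum is computed once and shared, so
    differences between rows reflect the score functions alone.  Returns a
    row per (scorer, threshold) with the detection count, plus the TMP.
    """
    if len(scorers) < 2:
        raise ValueError("need at least two scorers to compare")
    candidates = candidate_lists(db, spectra, cfg.precursor_tol_ppm)
    rows = []
    for scorer in scorers:
        result = search_spectra(db, spectra, scorer, cfg, candidates=candidates)
        for alpha in thresholds:
            _, accepted = tdc.estimate_fdr(
                tdc.pair_competition(
                    tdc.peptide_collapse(result.psms), db.pairing, db.collisions
                ),
                alpha,
            )
            rows.append(
                {
                    "scorer": scorer.name,
                    "alpha": alpha,
                    "detections": len(accepted),
                    "tmp": result.tmp.tmp if result.tmp else float("nan"),
                }
            )
    return pd.DataFrame(rows)
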