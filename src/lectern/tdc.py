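"""Peptide-level target-decoy competition (TDC) FDR estimation.

The double-competition procedure: (1) per spectrum, targets and decoys
compete and only the top-scoring candidate survives as the spectrum's PSM;
(2) per peptide, only its best PSM survives; (3) each target competes
head-to-head against its paired decoy, an unmatched side losing
automatically; (4) the survivors are ranked by score and the FDR at rank k
is estimated as min(1, (D_k + 1) / T_k), where D_k and T_k count decoys and
targets among the top k.  The accepted set at level alpha is the targets in
the longest prefix whose estimate stays below alpha.  Every tie in every
competition is broken toward the decoy (the conservative direction).

The target match percentage (TMP), T / (T + D) over spectrum-level PSMs,
is reported as a calibration-free companion measure.
"""
from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import Peptide

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSM:
    """One spectrum paired with one candidate peptide and one score."""

    spectrum_id: str
    peptide: Peptide
    score: float
    is_decoy: bool
    precursor_mz: float
    charge: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite PSM score for {self.spectrum_id}")


@dataclass(frozen=True)
class TmpResult:
    """Target match percentage: the share of spectra assigned a target."""

    n_target: int
    n_decoy: int

    @property
    def tmp(self) -> float:
        return self.n_target / (self.n_target + self.n_decoy)


def _winner(psms: Sequence[PSM]) -> PSM:
    return min(
        psms,
        key=lambda p: (-p.score, not p.is_decoy, p.peptide.modified_sequence, p.spectrum_id),
    )


def spectrum_competition(per_spectrum: Iterable[Sequence[PSM]]) -> list[PSM]:
    """First competition: keep the single best candidate per spectrum.

    Spectra with empty candidate lists contribute nothing.  Exact ties go
    to the decoy, then to the lexicographically smaller sequence.
    """
    return [_winner(group) for group in per_spectrum if len(group)]


def peptide_collapse(psms: Sequence[PSM]) -> dict[tuple[str, bool], PSM]:
    """Second step: keep the top-scoring PSM per distinct peptide.

    Peptides are keyed by (modified sequence, decoy flag) so a rare decoy
    whose shuffled string collides with an unrelated target stays separate.
    """
    best: dict[tuple[str, bool], PSM] = {}
    for p in psms:
        key = (p.peptide.modified_sequence, p.is_decoy)
        if key not in best or _winner([p, best[key]]) is p:
            best[key] = p
    return best


def pair_competition(
    best: Mapping[tuple[str, bool], PSM],
    pairing: Mapping[str, str],
    collisions: frozenset[str] | set[str] = frozenset(),
) -> list[PSM]:
    """Third competition: each target against its own paired decoy.

    A side not matched to any spectrum automatically loses; if neither side
    was matched the pair vanishes.  Pairs flagged as shuffle collisions are
    dropped with a logged count.  A matched peptide absent from the pairing
    is an error (the pairing must be the generation-time bijection).
    """
    known_targets = set(pairing.keys())
    known_decoys = set(pairing.values())
    for (seq, is_decoy) in best:
        if (seq not in known_decoys) if is_decoy else (seq not in known_targets):
            raise KeyError(f"peptide {seq!r} has no pairing entry")

    survivors: list[PSM] = []
    n_dropped = 0
    for target_seq, decoy_seq in pairing.items():
        pt = best.get((target_seq, False))
        pd_ = best.get((decoy_seq, True))
        if pt is None and pd_ is None:
            continue
        if target_seq in collisions:
            n_dropped += 1
            continue
        if pt is None:
            survivors.append(pd_)
        elif pd_ is None:
            survivors.append(pt)
        else:
            survivors.append(_winner([pt, pd_]))
    if n_dropped:
        logger.info("dropped %d matched pairs flagged as decoy collisions", n_dropped)
    return survivors


def rank_order(psms: Sequence[PSM]) -> list[PSM]:
    """Deterministic best-first ordering: score desc, ties decoy-first then
    by modified sequence."""
    return sorted(
        psms,
        key=lambda p: (-p.score, not p.is_decoy, p.peptide.modified_sequence, p.spectrum_id),
    )


def estimate_fdr(survivors: Sequence[PSM], alpha: float = 0.01) -> tuple[pd.DataFrame, list[PSM]]:
    """Rank survivors, estimate FDR at every rank, and threshold at alpha.

    FDR_k = min(1, (D_k + 1)/T_k) with the convention FDR_k = 1 while no
    target has been seen.  q-values are the running minimum of FDR over
    worse thresholds.  The accepted set is the targets within the largest k
    such that (D_k + 1)/T_k < alpha (strict), or empty if no such k.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ranked = rank_order(survivors)
    n = len(ranked)
    frame = pd.DataFrame(
        {
            "peptide": [p.peptide.modified_sequence for p in ranked],
            "score": [p.score for p in ranked],
            "is_decoy": [p.is_decoy for p in ranked],
        }
    )
    if n == 0:
        frame["T_k"] = frame["D_k"] = np.array([], dtype=int)
        frame["fdr"] = frame["q_value"] = np.array([], dtype=float)
        return frame, []

    decoy = frame["is_decoy"].to_numpy()
    D = np.cumsum(decoy)
    T = np.cumsum(~decoy)
    with np.errstate(divide="ignore"):
        raw = np.where(T > 0, (D + 1) / np.maximum(T, 1), np.inf)
    fdr = np.minimum(raw, 1.0)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    frame["T_k"] = T
    frame["D_k"] = D
    frame["fdr"] = fdr
    frame["q_value"] = q

    passing = np.nonzero((T > 0) & (raw < alpha))[0]
    if len(passing) == 0:
        return frame, []
    k_star = int(passing[-1]) + 1  # 1-based rank
    accepted = [p for p in ranked[:k_star] if not p.is_decoy]
    return frame, accepted


def tmp(psms: Sequence[PSM]) -> TmpResult:
    """Target match percentage over spectrum-level PSMs."""
    if len(psms) == 0:
        raise ValueError("TMP is undefined for an empty PSM list")
    n_decoy = sum(p.is_decoy for p in psms)
    return TmpResult(n_target=len(psms) - n_decoy, n_decoy=n_decoy)


def stratify_by_precursor(psms: Sequence[PSM], quartile: str) -> list[PSM]:
    """PSMs whose precursor m/z falls in the bottom (<= Q1) or top (>= Q3)
    empirical quartile of the input's precursor m/z distribution."""
    if quartile not in ("lower", "upper"):
        raise ValueError("quartile must be 'lower' or 'upper'")
    if len(psms) < 4:
        raise ValueError("need at least 4 PSMs to form quartiles")
    mzs = np.array([p.precursor_mz for p in psms])
    if quartile == "lower":
        cut = np.quantile(mzs, 0.25)
        return [p for p in psms if p.precursor_mz <= cut]
    cut = np.quantile(mzs, 0.75)
    return [p for p in psms if p.precursor_mz >= cut]
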