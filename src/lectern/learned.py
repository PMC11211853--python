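"""Teacher-forced autoregressive PSM scoring.

A :class:`SequenceModel` assigns, for a spectrum and a peptide prefix, a
probability distribution over the next token (residues, modified residues,
N-terminal modifications, and a stop token).  Scoring a peptide-spectrum
match never decodes: the known candidate sequence is fed in position by
position ("teacher forcing") and the probability the model assigned to each
true token is recorded.  The per-position probabilities x_1..x_n are
aggregated into a single PSM score by the mean of their logs — the log of
the geometric mean — which penalizes peptides with even a few low-confidence
positions much more severely than the arithmetic mean does.

The built-in :class:`EvidenceModel` is a deterministic, training-free model
of the same contract: the evidence for each candidate next residue is the
summed normalized intensity of observed peaks near the b-ion of the extended
prefix and near its complementary y-ion, passed through a softmax.  It lets
every part of the search and FDR machinery run and be tested end to end; a
genuinely trained autoregressive model can be plugged in through the model
registry.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from .digest import ModificationScheme, Peptide, default_modification_scheme
from .masses import AA_MASS, PROTON, WATER, format_delta
from .spectra import Spectrum

#: Probability floor applied before taking logs, keeping scores finite.
PROB_FLOOR = 1e-12

STOP_TOKEN = "$"

#: Evidence assigned to the stop token when the prefix mass is inconsistent
#: with the precursor (effectively excluding it from the softmax).
_STOP_PENALTY = -50.0


@dataclass(frozen=True)
class Alphabet:
    """Token vocabulary: residues (with static/variable mods folded into the
    token), N-terminal modification prefix tokens, and a stop token."""

    tokens: tuple[str, ...]
    masses: tuple[float, ...]  # stop token has mass 0

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.masses):
            raise ValueError("tokens and masses must be parallel")

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    @property
    def stop_index(self) -> int:
        return self.tokens.index(STOP_TOKEN)

    @classmethod
    def from_scheme(cls, scheme: ModificationScheme | None = None) -> "Alphabet":
        if scheme is None:
            scheme = default_modification_scheme()
        tokens: list[str] = []
        masses: list[float] = []
        for aa, base in sorted(AA_MASS.items()):
            static = scheme.static_mods.get(aa, 0.0)
            tokens.append(residue_token(aa, static))
            masses.append(base + static)
            if aa in scheme.variable_mods:
                delta = static + scheme.variable_mods[aa]
                tokens.append(residue_token(aa, delta))
                masses.append(base + delta)
        for delta in scheme.nterm_mods:
            tokens.append(nterm_token(delta))
            masses.append(delta)
        tokens.append(STOP_TOKEN)
        masses.append(0.0)
        return cls(tuple(tokens), tuple(masses))


def residue_token(aa: str, delta: float) -> str:
    return aa if delta == 0.0 else f"{aa}[{format_delta(delta)}]"


def nterm_token(delta: float) -> str:
    return f"[{format_delta(delta)}]-"


def tokenize(pep: Peptide) -> list[str]:
    """Token sequence of a peptide: optional N-terminal token, then one
    token per residue (modified residues are distinct tokens)."""
    tokens: list[str] = []
    if pep.nterm_delta is not None:
        tokens.append(nterm_token(pep.nterm_delta))
    tokens.extend(residue_token(aa, d) for aa, d in zip(pep.sequence, pep.mod_deltas))
    return tokens


class SequenceModel(Protocol):
    """Contract for a conditional next-token model over peptide sequences."""

    alphabet: Alphabet

    def conditional(self, spectrum: Spectrum, prefix: Sequence[str]) -> np.ndarray:
        """Probability over the alphabet of the next token given the spectrum
        and the prefix tokens.  Must be non-negative, sum to 1, and be
        deterministic for fixed inputs."""
        ...


# ---------------------------------------------------------------------------
# Teacher forcing and aggregation
# ---------------------------------------------------------------------------

def teacher_force(model: SequenceModel, s: Spectrum, pep: Peptide) -> np.ndarray:
    """Per-position probabilities of the true tokens under the model.

    The candidate's own tokens are fed as the prefix at every step; no
    decoding occurs.  Probabilities are floored at 1e-12.
    """
    tokens = tokenize(pep)
    index = model.alphabet.index
    x = np.empty(len(tokens))
    for i, tok in enumerate(tokens):
        if tok not in index:
            raise KeyError(f"token {tok!r} not in model alphabet")
        p = model.conditional(s, tokens[:i])
        x[i] = max(float(p[index[tok]]), PROB_FLOOR)
    return x


def aggregate_geometric(x: np.ndarray) -> float:
    """Mean of log probabilities: the log of the geometric mean of x."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot aggregate an empty score vector")
    return float(np.mean(np.log(x)))


def aggregate_arithmetic(x: np.ndarray) -> float:
    """Arithmetic mean of the per-position probabilities (ablation variant)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot aggregate an empty score vector")
    return float(np.mean(x))


AGGREGATES: dict[str, Callable[[np.ndarray], float]] = {
    "geometric": aggregate_geometric,
    "arithmetic": aggregate_arithmetic,
}


# ---------------------------------------------------------------------------
# The built-in evidence model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvidenceModelParams:
    """Tunables of the fragment-evidence sequence model.

    ``beta`` is the softmax sharpness over per-token evidence;
    ``stop_bonus`` the evidence granted to the stop token once the prefix
    mass is consistent with the precursor.
    """

    fragment_tol_ppm: float = 20.0
    beta: float = 5.0
    stop_bonus: float = 1.0
    precursor_tol_ppm: float = 20.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


class EvidenceModel:
    """Deterministic next-token model driven by fragment-ion evidence.

    For candidate token a with mass m_a appended to a prefix of mass m_p,
    the singly-charged b-ion of the extended prefix sits at
    m_p + m_a + proton and its complementary y-ion at
    M - m_p - m_a + proton, where M is the precursor-derived neutral mass.
    The token's evidence is the summed max-normalized intensity of observed
    peaks within the fragment tolerance of either ion; the stop token gets
    ``stop_bonus`` when the prefix already accounts for the full precursor
    mass (within the precursor tolerance) and a large negative constant
    otherwise.  The conditional distribution is softmax(beta * evidence).
    """

    def __init__(self, params: EvidenceModelParams | None = None, alphabet: Alphabet | None = None):
        self.params = params or EvidenceModelParams()
        self.alphabet = alphabet or Alphabet.from_scheme()
        self._token_masses = np.array(self.alphabet.masses)
        self._index = self.alphabet.index
        self._stop = self.alphabet.stop_index
        self._cache_key: int | None = None
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    def _normalized(self, s: Spectrum) -> tuple[np.ndarray, np.ndarray]:
        # (sorted m/z, cumulative normalized intensity) cached per spectrum
        if self._cache_key != id(s) or self._cache is None:
            if len(s) and s.intensity.max() > 0:
                norm = s.intensity / s.intensity.max()
            else:
                norm = np.zeros(len(s))
            self._cache = (s.mz, np.concatenate(([0.0], np.cumsum(norm))))
            self._cache_key = id(s)
        return self._cache

    def conditional(self, spectrum: Spectrum, prefix: Sequence[str]) -> np.ndarray:
        p = self.params
        index = self._index
        prefix_mass = sum(self._token_masses[index[t]] for t in prefix)
        neutral = spectrum.charge * (spectrum.precursor_mz - PROTON)

        b_mz = prefix_mass + self._token_masses + PROTON
        y_mz = neutral - prefix_mass - self._token_masses + PROTON

        mz, cum = self._normalized(spectrum)
        evidence = np.zeros(len(self._token_masses))
        for ion_mz in (b_mz, y_mz):
            tol = np.abs(ion_mz) * p.fragment_tol_ppm * 1e-6
            lo = np.searchsorted(mz, ion_mz - tol, side="left")
            hi = np.searchsorted(mz, ion_mz + tol, side="right")
            evidence += cum[hi] - cum[lo]

        if abs(prefix_mass + WATER - neutral) <= neutral * p.precursor_tol_ppm * 1e-6:
            evidence[self._stop] = p.stop_bonus
        else:
            evidence[self._stop] = _STOP_PENALTY

        z = p.beta * evidence
        z -= z.max()
        w = np.exp(z)
        return w / w.sum()


# ---------------------------------------------------------------------------
# Candidate scoring and the model registry
# ---------------------------------------------------------------------------

def score_candidates(
    model: SequenceModel,
    s: Spectrum,
    candidates: Sequence[Peptide],
    aggregate: Callable[[np.ndarray], float] = aggregate_geometric,
) -> list[tuple[Peptide, float]]:
    """Teacher-force and aggregate every candidate; sort best-first.

    Ties are broken decoy-first, then by lexicographic modified sequence,
    so orderings are deterministic.
    """
    scored = [(pep, aggregate(teacher_force(model, s, pep))) for pep in candidates]
    scored.sort(key=lambda t: (-t[1], not t[0].is_decoy, t[0].modified_sequence))
    return scored


MODEL_REGISTRY: dict[str, Callable[..., SequenceModel]] = {}


def register_model(name: str):
    """Decorator registering a SequenceModel factory under a config name."""

    def wrap(factory: Callable[..., SequenceModel]):
        MODEL_REGISTRY[name] = factory
        return factory

    return wrap


@register_model("evidence")
def _evidence_factory(**kwargs) -> SequenceModel:
    params = EvidenceModelParams(**{k: v for k, v in kwargs.items() if v is not None})
    return EvidenceModel(params)
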