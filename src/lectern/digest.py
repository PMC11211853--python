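"""In-silico proteolytic digestion, modified-form enumeration, decoys, and
the precursor-mass candidate index.

The search space is built in four steps: parse a protein FASTA, digest each
protein under a cleavage rule (default trypsin with proline suppression,
``[RK]|{P}``), enumerate modified peptide forms under a modification scheme,
and pair every unique target form with a shuffled decoy of identical mass.
Targets and decoys are indexed jointly by neutral monoisotopic mass so that
candidates for a spectrum are retrieved by a ppm window around its
precursor-derived neutral mass.
"""
from __future__ import annotations

import itertools
import logging
import re
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

from .masses import AA_MASS, AMBIGUOUS, PROTON, WATER, format_delta

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageRule:
    """Enzymatic cleavage specificity.

    Cleavage occurs after any residue in ``cut_after`` unless the next
    residue is in ``suppress_before``.  ``max_missed`` bounds the number of
    internal (uncut) sites a reported peptide may span.
    """

    cut_after: frozenset[str]
    suppress_before: frozenset[str]
    max_missed: int = 1

    def __post_init__(self) -> None:
        for letters in (self.cut_after, self.suppress_before):
            bad = set(letters) - set(AA_MASS)
            if bad:
                raise ValueError(f"cleavage rule uses non-canonical residues: {sorted(bad)}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    @classmethod
    def from_string(cls, text: str, max_missed: int = 1) -> "CleavageRule":
        """Parse a ``[RK]|{P}``-style rule string."""
        m = re.fullmatch(r"\[([A-Z]+)\]\|(?:\{([A-Z]*)\})?", text.strip())
        if m is None:
            raise ValueError(f"unrecognized cleavage rule string: {text!r}")
        return cls(
            cut_after=frozenset(m.group(1)),
            suppress_before=frozenset(m.group(2) or ""),
            max_missed=max_missed,
        )


#: Trypsin with proline suppression, the default rule.
TRYPSIN = CleavageRule(frozenset("RK"), frozenset("P"), max_missed=1)


@dataclass(frozen=True)
class ModificationScheme:
    """Static and variable modifications applied when enumerating peptide forms.

    ``static_mods`` apply unconditionally to every occurrence of a residue.
    ``variable_mods`` may or may not be present at each matching site;
    ``nterm_mods`` lists peptide N-terminal mass deltas of which at most one
    may be applied.  An applied N-terminal modification counts toward
    ``max_variable``.
    """

    static_mods: dict[str, float] = field(default_factory=dict)
    variable_mods: dict[str, float] = field(default_factory=dict)
    nterm_mods: tuple[float, ...] = ()
    max_variable: int = 3


def default_modification_scheme() -> ModificationScheme:
    """The search defaults: carbamidomethyl-C (static), oxidized M and
    deamidated N/Q (variable), and four N-terminal deltas (acetylation,
    carbamylation, ammonia loss, carbamylation minus ammonia)."""
    return ModificationScheme(
        static_mods={"C": 57.02146},
        variable_mods={"M": 15.994915, "N": 0.984016, "Q": 0.984016},
        nterm_mods=(42.010565, 43.005814, -17.026549, 25.980265),
        max_variable=3,
    )


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) peptide with its neutral monoisotopic mass.

    ``mod_deltas`` carries one mass delta per residue position (zero where
    unmodified; static deltas are already folded in), plus an optional
    N-terminal delta.  Decoys record the modified-sequence string of the
    target they were shuffled from, and a ``collision`` flag when shuffling
    could not avoid reproducing the target sequence.
    """

    sequence: str
    mod_deltas: tuple[float, ...]
    nterm_delta: float | None
    neutral_mass: float
    is_decoy: bool = False
    source_target: str | None = None
    collision: bool = False
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if len(self.mod_deltas) != len(self.sequence):
            raise ValueError("mod_deltas length must equal sequence length")

    @property
    def modified_sequence(self) -> str:
        """Canonical string identity, e.g. ``[+42.010565]-AC[+57.02146]MK``."""
        parts: list[str] = []
        if self.nterm_delta is not None:
            parts.append(f"[{format_delta(self.nterm_delta)}]-")
        for aa, d in zip(self.sequence, self.mod_deltas):
            parts.append(aa if d == 0.0 else f"{aa}[{format_delta(d)}]")
        return "".join(parts)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[FastaRecord]:
    """Read protein records from a FASTA file, in file order.

    Lowercase residues are uppercased with a warning.  A non-empty file that
    does not begin with a ``>`` header is rejected with the offending line
    number.  Ambiguity codes are tolerated here; peptides containing them
    are dropped during database construction.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: line {lineno}: expected '>' FASTA header")
            break
    records: list[FastaRecord] = []
    n_lower = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if any(c.islower() for c in seq):
            n_lower += 1
            seq = seq.upper()
        records.append(FastaRecord(rec.id, rec.description, seq))
    if n_lower:
        logger.warning("uppercased %d FASTA records containing lowercase residues", n_lower)
    return records


def cleavage_sites(protein: str, rule: CleavageRule) -> list[int]:
    """0-based positions i such that cleavage occurs between i and i+1."""
    n = len(protein)
    return [
        i
        for i in range(n - 1)
        if protein[i] in rule.cut_after and protein[i + 1] not in rule.suppress_before
    ]


def digest(protein: str, rule: CleavageRule) -> list[tuple[str, int]]:
    """Digest a protein into peptide substrings with missed-cleavage counts.

    Protein termini always count as boundaries; every substring between
    boundaries spanning at most ``rule.max_missed`` internal cleavage sites
    is returned, as ``(sequence, n_missed)`` pairs in N-to-C order.
    """
    if not protein:
        return []
    bounds = [0] + [i + 1 for i in cleavage_sites(protein, rule)] + [len(protein)]
    out: list[tuple[str, int]] = []
    for a in range(len(bounds) - 1):
        for missed in range(rule.max_missed + 1):
            b = a + missed + 1
            if b >= len(bounds):
                break
            out.append((protein[bounds[a] : bounds[b]], missed))
    return out


def sequence_mass(sequence: str, mod_deltas=(), nterm_delta: float | None = None) -> float:
    """Neutral monoisotopic mass: residue masses + mod deltas + water."""
    try:
        mass = sum(AA_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise KeyError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None
    mass += sum(mod_deltas) + (nterm_delta or 0.0)
    return mass + WATER


def peptide_mass(pep: Peptide) -> float:
    """Neutral monoisotopic mass of a peptide form (recomputed from fields)."""
    return sequence_mass(pep.sequence, pep.mod_deltas, pep.nterm_delta)


def enumerate_modified_forms(
    sequence: str,
    scheme: ModificationScheme,
    missed_cleavages: int = 0,
) -> list[Peptide]:
    """All modified forms of a peptide under a modification scheme.

    Static modifications are folded into every form.  Every subset of
    variable-modification sites, crossed with {no N-terminal mod} and each
    N-terminal mod, is emitted subject to the ``max_variable`` budget (an
    applied N-terminal mod consumes one unit of the budget).
    """
    static = tuple(scheme.static_mods.get(aa, 0.0) for aa in sequence)
    var_sites = [i for i, aa in enumerate(sequence) if aa in scheme.variable_mods]
    nterm_options: list[float | None] = [None] + list(scheme.nterm_mods)

    forms: list[Peptide] = []
    for nterm in nterm_options:
        budget = scheme.max_variable - (1 if nterm is not None else 0)
        if budget < 0:
            continue
        for k in range(min(budget, len(var_sites)) + 1):
            for combo in itertools.combinations(var_sites, k):
                deltas = list(static)
                for i in combo:
                    deltas[i] += scheme.variable_mods[sequence[i]]
                deltas_t = tuple(deltas)
                forms.append(
                    Peptide(
                        sequence=sequence,
                        mod_deltas=deltas_t,
                        nterm_delta=nterm,
                        neutral_mass=sequence_mass(sequence, deltas_t, nterm),
                        missed_cleavages=missed_cleavages,
                    )
                )
    return forms


def make_decoy(target: Peptide, rng_seed: int, max_retries: int = 20) -> Peptide:
    """Shuffle a target peptide into a same-mass decoy.

    The C-terminal residue is held fixed (preserving tryptic character) and
    the remaining positions are permuted, with each residue's modification
    delta traveling with it.  Up to ``max_retries`` seeded draws are made to
    avoid reproducing the target; if all fail (homopolymers, length <= 2)
    the decoy equals the target and is flagged as a collision so downstream
    competition can drop the pair.
    """
    if target.is_decoy:
        raise ValueError("cannot make a decoy of a decoy")
    rng = np.random.default_rng(rng_seed)
    n = len(target.sequence)
    pairs = list(zip(target.sequence, target.mod_deltas))
    interior, cterm = pairs[:-1], pairs[-1]

    shuffled = pairs
    collision = True
    for _ in range(max_retries):
        perm = rng.permutation(len(interior))
        cand = [interior[i] for i in perm] + [cterm]
        if n > 2 and cand != pairs:
            shuffled = cand
            collision = False
            break
        if n <= 2:
            break
    seq = "".join(aa for aa, _ in shuffled)
    deltas = tuple(d for _, d in shuffled)
    return Peptide(
        sequence=seq,
        mod_deltas=deltas,
        nterm_delta=target.nterm_delta,
        neutral_mass=sequence_mass(seq, deltas, target.nterm_delta),
        is_decoy=True,
        source_target=target.modified_sequence,
        collision=collision,
        missed_cleavages=target.missed_cleavages,
    )


def precursor_window(precursor_mz: float, charge: int, tol_ppm: float) -> tuple[float, float]:
    """Neutral-mass interval implied by a precursor m/z, charge, and ppm tolerance."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    neutral = charge * (precursor_mz - PROTON)
    if neutral <= 0:
        raise ValueError(f"non-positive neutral mass from m/z {precursor_mz}, charge {charge}")
    return neutral * (1 - tol_ppm * 1e-6), neutral * (1 + tol_ppm * 1e-6)


class CandidateIndex:
    """Peptides sorted by neutral mass, queryable by closed mass interval."""

    def __init__(self, peptides: list[Peptide]):
        self.peptides = sorted(peptides, key=lambda p: (p.neutral_mass, p.modified_sequence))
        self._masses = np.array([p.neutral_mass for p in self.peptides])

    def __len__(self) -> int:
        return len(self.peptides)

    def query(self, lo: float, hi: float) -> list[Peptide]:
        """Exactly the peptides with lo <= neutral_mass <= hi, ascending by mass."""
        i = int(np.searchsorted(self._masses, lo, side="left"))
        j = int(np.searchsorted(self._masses, hi, side="right"))
        return self.peptides[i:j]


def query_candidates(index: CandidateIndex, interval: tuple[float, float]) -> list[Peptide]:
    return index.query(*interval)


# ---------------------------------------------------------------------------
# Database construction
# ---------------------------------------------------------------------------

@dataclass
class PeptideDatabase:
    """The joint target+decoy search space with the pairing bijection."""

    targets: list[Peptide]
    decoys: list[Peptide]
    pairing: dict[str, str]  # target modified_sequence -> decoy modified_sequence
    index: CandidateIndex
    collisions: set[str]  # target modified_sequence of flagged pairs
    n_ambiguous_dropped: int = 0

    @property
    def target_base_sequences(self) -> set[str]:
        return {p.sequence for p in self.targets}


def build_database(
    records: list[FastaRecord],
    rule: CleavageRule = TRYPSIN,
    scheme: ModificationScheme | None = None,
    min_len: int = 6,
    max_len: int = 50,
    decoy_seed: int = 0,
) -> PeptideDatabase:
    """Digest, modify, and decoy a protein collection into a search database.

    Peptide uniqueness is at the level of the modified-sequence string; each
    unique target form gets one shuffled decoy, seeded deterministically
    from ``decoy_seed`` and the target's modified sequence.
    """
    if scheme is None:
        scheme = default_modification_scheme()

    n_ambiguous = 0
    base: dict[str, int] = {}  # sequence -> min missed cleavages
    for rec in records:
        for seq, missed in digest(rec.sequence, rule):
            if not (min_len <= len(seq) <= max_len):
                continue
            if AMBIGUOUS & set(seq):
                n_ambiguous += 1
                continue
            if seq not in base or missed < base[seq]:
                base[seq] = missed
    if n_ambiguous:
        logger.info("dropped %d digest peptides containing ambiguity codes", n_ambiguous)

    targets: list[Peptide] = []
    seen: set[str] = set()
    for seq in sorted(base):
        for form in enumerate_modified_forms(seq, scheme, base[seq]):
            key = form.modified_sequence
            if key not in seen:
                seen.add(key)
                targets.append(form)

    decoys: list[Peptide] = []
    pairing: dict[str, str] = {}
    collisions: set[str] = set()
    taken = set(seen)  # decoy strings must not collide with targets or other decoys
    for t in targets:
        seed = (zlib.crc32(t.modified_sequence.encode()) ^ (decoy_seed * 0x9E3779B1)) & 0x7FFFFFFF
        d = make_decoy(t, seed)
        for bump in range(1, 20):
            if d.collision or d.modified_sequence not in taken:
                break
            d = make_decoy(t, (seed + bump) & 0x7FFFFFFF)
        if not d.collision and d.modified_sequence in taken:
            d = replace(d, collision=True)
        decoys.append(d)
        taken.add(d.modified_sequence)
        pairing[t.modified_sequence] = d.modified_sequence
        if d.collision:
            collisions.add(t.modified_sequence)
    if collisions:
        logger.info("flagged %d decoy collisions (unshufflable targets)", len(collisions))

    index = CandidateIndex(targets + decoys)
    return PeptideDatabase(
        targets=targets,
        decoys=decoys,
        pairing=pairing,
        index=index,
        collisions=collisions,
        n_ambiguous_dropped=n_ambiguous,
    )
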