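"""The three classic hand-designed PSM score functions and theoretical
spectrum generation.

* XCorr: cross-correlation of a binned observed spectrum against a
  constant-intensity theoretical spectrum, corrected by the mean dot
  product at nonzero bin offsets in the range -75..75.
* Hyperscore: log(nb! * ny! * sum(Ib) * sum(Iy)) over matched b/y ions with
  unit-normalized intensities, computed in log space.
* Andromeda: a binomial significance of the matched theoretical peak count
  after top-q peak filtering, maximized over q.  The default reports
  -10*log10 of the binomial tail probability (the original score's
  convention); a bare-pmf variant is available via ``mode="pmf"``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .digest import Peptide
from .masses import AA_MASS, CO, H2O, NH3, PROTON, WATER
from .spectra import (
    XCORR_BIN_WIDTH,
    BinnedSpectrum,
    Spectrum,
    bin_spectrum,
    top_q_filter,
)

XCORR_MAIN_INTENSITY = 50.0  # b/y peaks in the theoretical vector
XCORR_MINOR_INTENSITY = 10.0  # a-ions and neutral losses


@dataclass
class TheoreticalSpectrum:
    """Fragment m/z values with ion-series labels for one peptide."""

    peptide: Peptide
    mz: np.ndarray
    series: np.ndarray  # e.g. 'b', 'y', 'a', 'b-NH3', 'y-H2O'
    charges: np.ndarray
    max_frag_charge: int = 1

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class IonMatchCounts:
    """Matched b/y ion counts with their unit-normalized intensities."""

    n_b: int
    n_y: int
    intensities_b: list[float] = field(default_factory=list)
    intensities_y: list[float] = field(default_factory=list)


@dataclass
class BinomialMatch:
    """Theoretical-vs-observed peak matching summary for binomial scoring."""

    n: int  # theoretical peak count
    k: int  # matched theoretical peaks
    q: int  # peaks-per-100-Da filter parameter in force


def theoretical_fragments(
    pep: Peptide,
    series: frozenset[str] | set[str] = frozenset({"b", "y"}),
    max_frag_charge: int = 1,
    neutral_losses: bool = False,
) -> TheoreticalSpectrum:
    """Generate fragment ions for a peptide.

    b_i carries the first i residues (plus any N-terminal mod) and a proton;
    y_i carries the last i residues plus water and a proton.  a-ions are
    b-ions minus CO; when ``neutral_losses`` is set, ammonia and water
    losses of each b/y ion are added.  Multiply-charged fragments are
    placed at (m + (z-1)*proton)/z.
    """
    n = len(pep.sequence)
    if n < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    residue = np.array([AA_MASS[aa] for aa in pep.sequence]) + np.asarray(pep.mod_deltas)
    prefix = np.cumsum(residue)[:-1]  # b_1 .. b_{n-1} residue mass
    if pep.nterm_delta is not None:
        prefix = prefix + pep.nterm_delta
    suffix = np.cumsum(residue[::-1])[:-1]  # y_1 .. y_{n-1} residue mass

    singly: list[tuple[float, str]] = []
    if "b" in series:
        singly += [(m + PROTON, "b") for m in prefix]
    if "y" in series:
        singly += [(m + WATER + PROTON, "y") for m in suffix]
    if "a" in series:
        singly += [(m + PROTON - CO, "a") for m in prefix]
    if neutral_losses:
        for m in prefix:
            singly += [(m + PROTON - NH3, "b-NH3"), (m + PROTON - H2O, "b-H2O")]
        for m in suffix:
            singly += [(m + WATER + PROTON - NH3, "y-NH3"), (m + WATER + PROTON - H2O, "y-H2O")]

    mzs: list[float] = []
    labels: list[str] = []
    charges: list[int] = []
    for z in range(1, max_frag_charge + 1):
        for m, lab in singly:
            mzs.append((m + (z - 1) * PROTON) / z)
            labels.append(lab)
            charges.append(z)
    order = np.lexsort((np.arange(len(mzs)), np.array(mzs)))
    return TheoreticalSpectrum(
        peptide=pep,
        mz=np.array(mzs)[order],
        series=np.array(labels)[order],
        charges=np.array(charges)[order],
        max_frag_charge=max_frag_charge,
    )


def match_peaks(
    s: Spectrum, fragments: TheoreticalSpectrum, tol_ppm: float
) -> tuple[IonMatchCounts, BinomialMatch]:
    """Match theoretical fragments to observed peaks within a ppm tolerance.

    A fragment at m/z m matches an observed peak within m * tol * 1e-6.
    Each observed peak supports at most one fragment per ion series, with
    the closest-m/z pairing winning.  Matched intensities are normalized by
    the spectrum's maximum intensity.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    counts = IonMatchCounts(n_b=0, n_y=0)
    total_matched = 0
    if len(s) and len(fragments):
        max_int = float(s.intensity.max())
        for lab in np.unique(fragments.series):
            frag_idx = np.nonzero(fragments.series == lab)[0]
            # candidate (|delta|, fragment, peak) pairs within tolerance
            pairs: list[tuple[float, int, int]] = []
            for fi in frag_idx:
                m = fragments.mz[fi]
                tol = m * tol_ppm * 1e-6
                lo = int(np.searchsorted(s.mz, m - tol, side="left"))
                hi = int(np.searchsorted(s.mz, m + tol, side="right"))
                for pi in range(lo, hi):
                    pairs.append((abs(s.mz[pi] - m), int(fi), pi))
            pairs.sort()
            used_frag: set[int] = set()
            used_peak: set[int] = set()
            for _, fi, pi in pairs:
                if fi in used_frag or pi in used_peak:
                    continue
                used_frag.add(fi)
                used_peak.add(pi)
                total_matched += 1
                rel = float(s.intensity[pi]) / max_int if max_int > 0 else 0.0
                if lab == "b":
                    counts.n_b += 1
                    counts.intensities_b.append(rel)
                elif lab == "y":
                    counts.n_y += 1
                    counts.intensities_y.append(rel)
    return counts, BinomialMatch(n=len(fragments), k=total_matched, q=0)


def xcorr(u: BinnedSpectrum, v: BinnedSpectrum) -> float:
    """Cross-correlation score between binned observed and theoretical spectra.

    score = <u, v> - (1/150) * sum over offsets r in -75..75, r != 0 of
    <u shifted by r, v>, with out-of-range indices treated as zero.  The
    r = 0 term is excluded so that the background is a pure offset average.
    """
    if len(u) != len(v):
        raise ValueError("binned spectra must have equal length")
    if abs(u.bin_width - v.bin_width) > 1e-12:
        raise ValueError("binned spectra must share a bin width")
    uu, vv = u.u, v.u
    # window sums of u of width 151 centered at each bin, minus the center
    background = np.convolve(uu, np.ones(151), mode="full")[75 : 75 + len(uu)] - uu
    return float(vv @ uu - (vv @ background) / 150.0)


def binned_theoretical(
    t: TheoreticalSpectrum,
    bin_width: float = XCORR_BIN_WIDTH,
    n_bins: int | None = None,
) -> BinnedSpectrum:
    """Constant-intensity binned theoretical spectrum for XCorr.

    b/y ions are placed at intensity 50, a-ions and neutral losses at 10; a
    bin keeps the maximum intensity of the ions falling into it.
    """
    if n_bins is None:
        n_bins = max(1, math.ceil((float(t.mz.max()) + bin_width) / bin_width))
    v = np.zeros(n_bins)
    idx = np.floor(t.mz / bin_width).astype(int)
    major = np.isin(t.series, ("b", "y"))
    for i, is_major in zip(idx, major):
        if 0 <= i < n_bins:
            v[i] = max(v[i], XCORR_MAIN_INTENSITY if is_major else XCORR_MINOR_INTENSITY)
    return BinnedSpectrum(u=v, bin_width=bin_width)


def hyperscore(m: IonMatchCounts) -> float:
    """log(nb! * ny! * sum(Ib) * sum(Iy)), natural log, via log-gamma.

    Returns 0 when either ion series is unmatched or an intensity sum is
    zero (the degenerate floor).
    """
    sum_b = sum(m.intensities_b)
    sum_y = sum(m.intensities_y)
    if m.n_b == 0 or m.n_y == 0 or sum_b <= 0 or sum_y <= 0:
        return 0.0
    return math.lgamma(m.n_b + 1) + math.lgamma(m.n_y + 1) + math.log(sum_b) + math.log(sum_y)


def binomial_tail(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by exact summation."""
    if k <= 0:
        return 1.0
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def andromeda_score(
    s: Spectrum,
    t: TheoreticalSpectrum,
    tol_ppm: float,
    q_max: int = 10,
    mode: str = "tail",
) -> float:
    """Binomial significance of the matched-peak count, maximized over q.

    For each q in 1..q_max the spectrum is filtered to its q most intense
    peaks per 100 m/z, the number k of matched theoretical peaks (out of n)
    is counted, and under ``mode="tail"`` the candidate score is
    -10*log10(P(X >= k)) for X ~ Binomial(n, q/100).  The maximum over q is
    returned, ties resolved toward smaller q.  ``mode="pmf"`` instead
    maximizes the bare binomial pmf C(n,k) (q/100)^k (1-q/100)^(n-k).
    """
    if q_max < 1:
        raise ValueError("q_max must be >= 1")
    if mode not in ("tail", "pmf"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(t)
    best = -math.inf
    for q in range(1, q_max + 1):
        filtered = top_q_filter(s, q)
        _, bm = match_peaks(filtered, t, tol_ppm)
        p = q / 100.0
        if mode == "tail":
            tail = max(binomial_tail(n, bm.k, p), 1e-300)
            cand = -10.0 * math.log10(tail)
        else:
            cand = math.comb(n, bm.k) * p**bm.k * (1 - p) ** (n - bm.k)
        if cand > best:  # strict: ties keep the smaller q
            best = cand
    return best


# ---------------------------------------------------------------------------
# PSM-level convenience wrappers (used by the search pipeline)
# ---------------------------------------------------------------------------

def xcorr_psm(s: Spectrum, pep: Peptide, neutral_losses: bool = True) -> float:
    """XCorr of a spectrum against a peptide's theoretical spectrum."""
    t = theoretical_fragments(pep, series={"b", "y", "a"}, neutral_losses=neutral_losses)
    max_mz = max(float(s.mz[-1]) if len(s) else 0.0, float(t.mz.max())) + XCORR_BIN_WIDTH
    n_bins = max(1, math.ceil(max_mz / XCORR_BIN_WIDTH))
    u = bin_spectrum(s, XCORR_BIN_WIDTH, max_mz=max_mz)
    v = binned_theoretical(t, XCORR_BIN_WIDTH, n_bins=n_bins)
    return xcorr(u, v)


def hyperscore_psm(s: Spectrum, pep: Peptide, tol_ppm: float = 20.0) -> float:
    t = theoretical_fragments(pep, series={"b", "y"})
    counts, _ = match_peaks(s, t, tol_ppm)
    return hyperscore(counts)


def andromeda_psm(
    s: Spectrum, pep: Peptide, tol_ppm: float = 20.0, q_max: int = 10, mode: str = "tail"
) -> float:
    t = theoretical_fragments(pep, series={"b", "y", "a"}, neutral_losses=True)
    return andromeda_score(s, t, tol_ppm, q_max=q_max, mode=mode)
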