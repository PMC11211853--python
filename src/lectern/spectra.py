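"""MS2 spectrum containers, MGF reading/writing, peak-list preprocessing,
and the mzTab / Percolator-PIN report writers.

MGF parsing is delegated to pyteomics; spectra without an annotated
precursor charge are skipped (with a logged count) rather than guessed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

#: Bin width used for cross-correlation scoring: the average spacing between
#: fragment masses differing by one dalton unit (the "Thomson bin").
XCORR_BIN_WIDTH = 1.0005079

XCORR_REGIONS = 10
XCORR_REGION_MAX = 50.0


@dataclass
class Spectrum:
    """One MS2 spectrum: precursor (m/z, charge) plus a peak list.

    Peaks are kept as parallel arrays, sorted ascending by m/z at
    construction time.
    """

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class BinnedSpectrum:
    """A spectrum discretized onto a uniform m/z grid."""

    u: np.ndarray
    bin_width: float
    offset: float = 0.0

    def __len__(self) -> int:
        return len(self.u)


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file into Spectrum objects, in file order.

    Blocks lacking a CHARGE line are skipped with a logged count.  Charge
    strings like ``2+`` parse to the integer 2.
    """
    spectra: list[Spectrum] = []
    skipped = 0
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            charges = params.get("charge")
            if not charges:
                skipped += 1
                continue
            pepmass = params["pepmass"]
            title = str(params.get("title", f"index={i}"))
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass),
                    charge=int(charges[0]),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    if skipped:
        logger.warning("skipped %d MGF spectra lacking a charge annotation", skipped)
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Write spectra to an MGF file (TITLE, PEPMASS, CHARGE, peak lines)."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": s.charge,
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def bin_spectrum(
    s: Spectrum,
    bin_width: float = XCORR_BIN_WIDTH,
    region_count: int = XCORR_REGIONS,
    max_mz: float | None = None,
) -> BinnedSpectrum:
    """Bin and normalize an observed spectrum for cross-correlation scoring.

    Peak intensities are summed into bins of ``bin_width`` Da, square-root
    transformed, and the resulting vector is split into ``region_count``
    equal regions each scaled so its maximum is 50.  Empty regions stay
    zero.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if max_mz is None:
        max_mz = float(s.mz[-1]) + bin_width if len(s) else bin_width
    n_bins = max(1, math.ceil(max_mz / bin_width))
    u = np.zeros(n_bins)
    if len(s):
        idx = np.floor(s.mz / bin_width).astype(int)
        keep = idx < n_bins
        np.add.at(u, idx[keep], s.intensity[keep])
    u = np.sqrt(u)
    edges = np.linspace(0, n_bins, region_count + 1).astype(int)
    for a, b in zip(edges[:-1], edges[1:]):
        peak = u[a:b].max() if b > a else 0.0
        if peak > 0:
            u[a:b] *= XCORR_REGION_MAX / peak
    return BinnedSpectrum(u=u, bin_width=bin_width)


def top_q_filter(s: Spectrum, q: int, window: float = 100.0) -> Spectrum:
    """Keep the q most intense peaks per half-open ``window``-Da m/z window.

    Ties are broken in favor of the lower-m/z peak.  Output peaks remain a
    subset of the input, so the filter is idempotent.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if len(s) == 0:
        return s
    keep_idx: list[int] = []
    win = np.floor(s.mz / window).astype(int)
    for w in np.unique(win):
        members = np.nonzero(win == w)[0]
        ranked = sorted(members, key=lambda i: (-s.intensity[i], s.mz[i]))
        keep_idx.extend(ranked[:q])
    keep_idx.sort()
    return Spectrum(
        spectrum_id=s.spectrum_id,
        precursor_mz=s.precursor_mz,
        charge=s.charge,
        mz=s.mz[keep_idx],
        intensity=s.intensity[keep_idx],
    )


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

_MZTAB_PSM_COLUMNS = [
    "sequence",
    "PSM_ID",
    "accession",
    "unique",
    "database",
    "database_version",
    "search_engine",
    "search_engine_score[1]",
    "modifications",
    "retention_time",
    "charge",
    "exp_mass_to_charge",
    "calc_mass_to_charge",
    "spectra_ref",
    "pre",
    "post",
    "start",
    "end",
    "opt_global_is_decoy",
]


def write_mztab(psms, path, engine_name: str = "lectern") -> None:
    """Write top-ranked PSMs as a minimal mzTab file (MTD + PSM sections).

    ``psms`` is an iterable of objects with ``spectrum_id``, ``peptide``,
    ``score``, ``is_decoy``, ``precursor_mz`` and ``charge`` attributes
    (one per spectrum at most).  Scores are printed with 6 decimals.
    """
    with open(path, "w") as out:
        out.write("MTD\tmzTab-version\t1.0.0\n")
        out.write("MTD\tmzTab-mode\tSummary\n")
        out.write("MTD\tmzTab-type\tIdentification\n")
        out.write(f"MTD\tdescription\t{engine_name} database search results\n")
        out.write(
            "MTD\tpsm_search_engine_score[1]\t[MS, MS:1001143, search engine specific score for PSMs, ]\n"
        )
        out.write("PSH\t" + "\t".join(_MZTAB_PSM_COLUMNS) + "\n")
        for i, p in enumerate(psms):
            row = [
                p.peptide.modified_sequence,
                str(i),
                "null",
                "null",
                "null",
                "null",
                engine_name,
                f"{p.score:.6f}",
                "null",
                "null",
                str(p.charge),
                f"{p.precursor_mz:.6f}",
                "null",
                p.spectrum_id,
                "null",
                "null",
                "null",
                "null",
                "1" if p.is_decoy else "0",
            ]
            out.write("PSM\t" + "\t".join(row) + "\n")


def read_mztab_psms(path) -> list[dict]:
    """Line-oriented reader for the PSM section written by :func:`write_mztab`."""
    rows: list[dict] = []
    header: list[str] | None = None
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "PSH":
                header = fields[1:]
            elif fields[0] == "PSM":
                if header is None:
                    raise ValueError("PSM row before PSH header")
                rows.append(dict(zip(header, fields[1:])))
    return rows


def write_pin(psms, path, max_charge: int = 4) -> None:
    """Write PSMs as a Percolator-input (PIN) tab-separated file.

    Features are deliberately minimal: the PSM score, the precursor m/z,
    and a one-hot charge encoding.  Labels are +1 for targets, -1 for
    decoys.  ScanNr falls back to the ordinal of the spectrum in the input
    when no scan number is recoverable from the title.
    """
    charge_cols = [f"charge{z}" for z in range(1, max_charge + 1)]
    header = ["SpecId", "Label", "ScanNr", "score", "precursor_mz", *charge_cols, "Peptide", "Proteins"]
    with open(path, "w") as out:
        out.write("\t".join(header) + "\n")
        for i, p in enumerate(psms):
            onehot = ["1" if p.charge == z else "0" for z in range(1, max_charge + 1)]
            row = [
                f"{p.spectrum_id}_{i}",
                "-1" if p.is_decoy else "1",
                str(i),
                f"{p.score:.6f}",
                f"{p.precursor_mz:.6f}",
                *onehot,
                f"-.{p.peptide.modified_sequence}.-",
                "decoy" if p.is_decoy else "target",
            ]
            out.write("\t".join(row) + "\n")
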