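"""Peak-list I/O and Kendrick mass arithmetic.

A sample arrives as a delimited peak list (one row per resolved peak:
m/z, intensity, optionally S/N and an assigned elemental formula).  This
module reads and writes those files, applies the export-window and
signal-to-noise filters used when peak lists are produced from broadband
negative-ESI FT-ICR spectra, computes CH2-based Kendrick quantities, and
splits a spectrum into even- and odd-nominal-mass halves so each sample
yields two data points downstream.

Kendrick convention: the measured mass is rescaled by 14.00000/14.01565
so that CH2 homologs differ by exactly 14; the Kendrick mass defect
(KMD) is the nearest-integer Kendrick mass minus the Kendrick exact
mass, stored in milli-Daltons so members of one homologous series share
a KMD to within the measurement error.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CH2_MASS",
    "KENDRICK_FACTOR",
    "Peak",
    "Spectrum",
    "KendrickValue",
    "compute_kendrick",
    "read_peaklist",
    "write_peaklist",
    "read_manifest",
    "write_manifest",
    "filter_peaks",
    "split_parity",
]

#: Exact mass of the CH2 repeat unit (Da).
CH2_MASS = 14.01565

#: Rescaling factor taking IUPAC mass to Kendrick (CH2-based) mass.
KENDRICK_FACTOR = 14.00000 / CH2_MASS

_LABELS = ("Biological", "Meteorite", "Petroleum", "Synthetic")


def _round_half_away(x: float) -> int:
    """Nearest integer, ties rounded half away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class Peak:
    """One resolved peak: m/z (Da, singly charged assumed) and intensity.

    ``snr`` and ``formula`` are optional columns carried through from the
    peak-list export when present.
    """

    mz: float
    intensity: float
    snr: float | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if not self.intensity > 0:
            raise ValueError(
                f"peak intensity must be positive, got {self.intensity}"
            )
        if self.snr is not None and self.snr < 0:
            raise ValueError(f"peak S/N must be non-negative, got {self.snr}")


@dataclass(frozen=True)
class KendrickValue:
    """CH2-based Kendrick quantities for one measured mass."""

    kendrick_mass: float
    nominal_mass: int
    kmd_mDa: float


@dataclass
class Spectrum:
    """One sample's peak list plus metadata.

    ``peaks`` is kept sorted ascending by m/z; duplicate m/z values are
    retained as distinct peaks.  ``parity`` is ``"all"`` for an unsplit
    spectrum, or ``"even"``/``"odd"`` after :func:`split_parity`.
    """

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)
    label: str | None = None
    parity: str = "all"

    def __post_init__(self) -> None:
        if self.parity not in ("all", "even", "odd"):
            raise ValueError(f"invalid parity {self.parity!r}")
        if self.label is not None and self.label not in _LABELS:
            raise ValueError(
                f"label {self.label!r} not one of {_LABELS} (or None)"
            )
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def has_snr(self) -> bool:
        return any(p.snr is not None for p in self.peaks)


def compute_kendrick(mz: float) -> KendrickValue:
    """Kendrick mass, nominal (nearest-integer) mass and KMD for one m/z.

    The Kendrick mass is ``mz * 14.00000/14.01565``; the nominal mass is
    its nearest integer (ties half away from zero), which bounds the
    defect to (-500, 500] mDa so every peak lands on the KMD axis.
    """
    if not mz > 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    km = mz * KENDRICK_FACTOR
    nominal = _round_half_away(km)
    return KendrickValue(km, nominal, (nominal - km) * 1000.0)


def kendrick_arrays(mz: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`compute_kendrick`: (kendrick_mass, nominal, kmd_mDa)."""
    mz = np.asarray(mz, dtype=float)
    km = mz * KENDRICK_FACTOR
    nominal = np.floor(km + 0.5)  # km > 0 for physical peaks
    return km, nominal.astype(np.int64), (nominal - km) * 1000.0


# ---------------------------------------------------------------------------
# delimited I/O

_COLUMN_ALIASES = {
    "mz": "mz", "m/z": "mz", "mass": "mz", "exp. m/z": "mz",
    "intensity": "intensity", "abundance": "intensity",
    "rel. abundance": "intensity", "magnitude": "intensity",
    "snr": "snr", "s/n": "snr", "sn": "snr",
    "formula": "formula", "molecular formula": "formula",
    "composition": "formula",
}


def _sniff(text: str) -> tuple[str, bool]:
    """Detect delimiter (comma vs tab) and whether a header row is present."""
    first = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    cells = first.split(sep)

    def _numeric(c: str) -> bool:
        try:
            float(c)
            return True
        except ValueError:
            return False

    has_header = len(cells) >= 2 and not all(_numeric(c) for c in cells[:2])
    return sep, has_header


def read_peaklist(
    path: str | Path,
    sample_id: str | None = None,
    label: str | None = None,
) -> Spectrum:
    """Read one delimited peak list (CSV or TSV) into a :class:`Spectrum`.

    The delimiter and the presence of a header row are auto-detected.
    With a header, columns are mapped by name (``mz``/``m/z``,
    ``intensity``, ``snr``/``s/n``, ``formula``); without one they are
    taken positionally as (mz, intensity, snr, formula).  Malformed rows
    raise with the offending line numbers rather than being dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty peak list")
    sep, has_header = _sniff(text)

    if has_header:
        df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
        df.columns = [
            _COLUMN_ALIASES.get(str(c).strip().lower(), str(c).strip().lower())
            for c in df.columns
        ]
        if "mz" not in df.columns or "intensity" not in df.columns:
            raise ValueError(
                f"{path}: header must name an m/z and an intensity column, "
                f"got {list(df.columns)}"
            )
        offset = 2  # 1-based line number of the first data row
    else:
        df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str)
        names = ["mz", "intensity", "snr", "formula"][: df.shape[1]]
        df = df.iloc[:, : len(names)]
        df.columns = names
        offset = 1

    bad_lines: list[int] = []
    for col in ("mz", "intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((np.flatnonzero(vals.isna()) + offset).tolist())
        df[col] = vals
    if bad_lines:
        raise ValueError(
            f"{path}: non-numeric m/z or intensity on line(s) "
            f"{sorted(set(bad_lines))}"
        )
    if "snr" in df.columns:
        df["snr"] = pd.to_numeric(df["snr"], errors="coerce")

    peaks = []
    for row in df.itertuples(index=False):
        snr = getattr(row, "snr", None)
        if snr is not None and (isinstance(snr, float) and math.isnan(snr)):
            snr = None
        formula = getattr(row, "formula", None)
        if formula is not None and (not isinstance(formula, str) or not formula.strip()):
            formula = None
        peaks.append(Peak(float(row.mz), float(row.intensity), snr, formula))
    return Spectrum(sample_id or path.stem, peaks, label=label)


def write_peaklist(s: Spectrum, path: str | Path, sep: str = ",") -> Path:
    """Write a spectrum back out in the delimited dialect, 6 decimals."""
    path = Path(path)
    cols: dict[str, list] = {
        "mz": [f"{p.mz:.6f}" for p in s.peaks],
        "intensity": [f"{p.intensity:.6f}" for p in s.peaks],
    }
    if s.has_snr:
        cols["snr"] = ["" if p.snr is None else f"{p.snr:.6f}" for p in s.peaks]
    if any(p.formula for p in s.peaks):
        cols["formula"] = [p.formula or "" for p in s.peaks]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV mapping peak-list files to sample ids and labels.

    Columns: ``path``, ``sample_id``, ``label``; ``path`` is resolved
    relative to the manifest's own directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"path", "sample_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    return df


def write_manifest(rows: Iterable[tuple[str, str, str]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=["path", "sample_id", "label"]).to_csv(
        path, index=False
    )
    return path


def load_spectra(manifest: str | Path) -> list[Spectrum]:
    """Load every spectrum named in a manifest file."""
    df = read_manifest(manifest)
    return [
        read_peaklist(r.path, sample_id=str(r.sample_id), label=str(r.label))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# filters and parity split

def filter_peaks(
    s: Spectrum,
    mz_min: float = 150.0,
    mz_max: float = 750.0,
    snr_min: float = 2.0,
) -> Spectrum:
    """Apply the peak-list export filters: retain peaks with
    ``mz_min <= mz <= mz_max`` (both endpoints inclusive) and, when a
    peak carries an S/N value, ``snr > snr_min`` (strict).  Peaks with
    no S/N value pass the S/N test.  Idempotent.
    """
    if not mz_min < mz_max:
        raise ValueError(f"need mz_min < mz_max, got [{mz_min}, {mz_max}]")
    kept = [
        p
        for p in s.peaks
        if mz_min <= p.mz <= mz_max and (p.snr is None or p.snr > snr_min)
    ]
    return Spectrum(s.sample_id, kept, label=s.label, parity=s.parity)


def split_parity(s: Spectrum, basis: str = "measured") -> tuple[Spectrum, Spectrum]:
    """Partition a spectrum into even- and odd-nominal-mass halves.

    Parity is taken from the nearest integer of the measured m/z
    (``basis="measured"``, the default) or of the Kendrick mass
    (``basis="kendrick"``, for sensitivity analysis).  The two outputs
    partition the input exactly.
    """
    if s.parity != "all":
        raise ValueError("split_parity expects an unsplit spectrum")
    if basis not in ("measured", "kendrick"):
        raise ValueError(f"unknown parity basis {basis!r}")
    even, odd = [], []
    for p in s.peaks:
        x = p.mz if basis == "measured" else p.mz * KENDRICK_FACTOR
        (even if _round_half_away(x) % 2 == 0 else odd).append(p)
    return (
        Spectrum(s.sample_id, even, label=s.label, parity="even"),
        Spectrum(s.sample_id, odd, label=s.label, parity="odd"),
    )
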