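"""Biomarker mass enumeration and ppm matching.

Two target families tied to the decay products of terrestrial biomass:

* diketopiperazines (DKPs) — cyclic dipeptides formed by abiotic
  "tail-biting" degradation of proteins.  A DKP's neutral mass is the
  sum of the two amino-acid *residue* masses (residue = amino acid -
  H2O; cyclization of the dipeptide removes the second water, which is
  exactly what using residue masses accounts for);
* saturated straight-chain fatty acids (SFAs), CnH2nO2, the canonical
  lipid-derived homologous series.

Targets are converted to [M-H]- m/z (negative electrospray) and matched
against measured peak lists at a ppm tolerance appropriate to FT-ICR
mass accuracy (default 1 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from types import MappingProxyType

import numpy as np

from .peaklist import Spectrum

__all__ = [
    "ELEMENT_MASS",
    "PROTON_MASS",
    "RESIDUE_FORMULAS",
    "residue_masses",
    "TargetEntry",
    "TargetMassList",
    "MatchResult",
    "enumerate_dkp_masses",
    "sfa_series",
    "to_mz",
    "match_peaks",
]

# Monoisotopic elemental masses (Da), CODATA/AME-derived standard values.
ELEMENT_MASS = MappingProxyType(
    {
        "H": 1.00782503207,
        "C": 12.0,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "S": 31.97207100,
    }
)

#: Mass of a proton (Da); [M-H]- m/z = M - PROTON_MASS (electron included).
PROTON_MASS = 1.00727646688

# Residue formulas (amino acid minus H2O) of the 20 coded amino acids as
# (C, H, N, O, S) counts.  Leu and Ile share a formula and hence a mass.
RESIDUE_FORMULAS = MappingProxyType(
    {
        "Gly": (2, 3, 1, 1, 0),
        "Ala": (3, 5, 1, 1, 0),
        "Ser": (3, 5, 1, 2, 0),
        "Pro": (5, 7, 1, 1, 0),
        "Val": (5, 9, 1, 1, 0),
        "Thr": (4, 7, 1, 2, 0),
        "Cys": (3, 5, 1, 1, 1),
        "Leu": (6, 11, 1, 1, 0),
        "Ile": (6, 11, 1, 1, 0),
        "Asn": (4, 6, 2, 2, 0),
        "Asp": (4, 5, 1, 3, 0),
        "Gln": (5, 8, 2, 2, 0),
        "Lys": (6, 12, 2, 1, 0),
        "Glu": (5, 7, 1, 3, 0),
        "Met": (5, 9, 1, 1, 1),
        "His": (6, 7, 3, 1, 0),
        "Phe": (9, 9, 1, 1, 0),
        "Arg": (6, 12, 4, 1, 0),
        "Tyr": (9, 9, 1, 2, 0),
        "Trp": (11, 10, 2, 1, 0),
    }
)


def _formula_mass(c: int, h: int, n: int, o: int, s: int = 0) -> float:
    e = ELEMENT_MASS
    return c * e["C"] + h * e["H"] + n * e["N"] + o * e["O"] + s * e["S"]


def residue_masses() -> dict[str, float]:
    """Monoisotopic residue masses (Da) of the 20 coded amino acids."""
    return {aa: _formula_mass(*f) for aa, f in RESIDUE_FORMULAS.items()}


@dataclass(frozen=True)
class TargetEntry:
    """One enumerated neutral mass with its contributing compositions."""

    neutral_mass: float
    compositions: tuple[str, ...]
    series: str  # "DKP" or "SFA"


@dataclass
class TargetMassList:
    """Sorted, duplicate-merged list of enumerated neutral masses."""

    entries: list[TargetEntry]

    def __post_init__(self) -> None:
        masses = [e.neutral_mass for e in self.entries]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("entry masses must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def masses(self) -> np.ndarray:
        return np.array([e.neutral_mass for e in self.entries])


@dataclass
class MatchResult:
    """Per-target match report against one spectrum."""

    series: str
    adduct: str
    ppm_tol: float
    target_masses: np.ndarray  # neutral masses, one per considered target
    target_mz: np.ndarray  # expected m/z
    compositions: list[tuple[str, ...]]
    matched: np.ndarray  # bool per target
    peak_index: np.ndarray  # nearest-peak index (-1 if spectrum empty)
    observed_mz: np.ndarray  # nearest peak m/z (nan if none)
    ppm_error: np.ndarray  # signed ppm error of the nearest peak
    below_cutoff: list[TargetEntry]  # targets under the window lower bound

    @property
    def n_measurable(self) -> int:
        return len(self.target_masses)

    @property
    def n_matched(self) -> int:
        return int(self.matched.sum())


def enumerate_dkp_masses(
    residues: dict[str, float] | None = None, merge_tol: float = 1e-4
) -> TargetMassList:
    """All DKP neutral masses from unordered pairs of coded amino acids.

    Every unordered pair of the 20 amino acids (210 with both orders
    and homodimers collapsed — cyclo(Ala-Gly) and cyclo(Gly-Ala) are the
    same molecule) contributes the sum of its two residue masses.
    Masses agreeing within ``merge_tol`` (default 0.1 mDa, far below
    any non-coincidental gap) are merged into one entry listing every
    contributing composition; Leu/Ile isobars and exact elemental
    coincidences such as Gly+Glu = Ala+Asp collapse this way.
    """
    if merge_tol < 0:
        raise ValueError("merge tolerance must be non-negative")
    res = residues if residues is not None else residue_masses()
    pairs = sorted(
        ((res[a] + res[b], f"{a}+{b}") for a, b in
         combinations_with_replacement(sorted(res), 2)),
    )
    entries: list[TargetEntry] = []
    cluster_mass, cluster_comps = pairs[0][0], [pairs[0][1]]
    for mass, comp in pairs[1:]:
        if mass - cluster_mass <= merge_tol:
            cluster_comps.append(comp)
        else:
            entries.append(TargetEntry(cluster_mass, tuple(cluster_comps), "DKP"))
            cluster_mass, cluster_comps = mass, [comp]
    entries.append(TargetEntry(cluster_mass, tuple(cluster_comps), "DKP"))
    return TargetMassList(entries)


def sfa_series(c_min: int = 2, c_max: int = 30) -> TargetMassList:
    """Neutral monoisotopic masses of CnH2nO2 for n in [c_min, c_max]."""
    if not 2 <= c_min <= c_max:
        raise ValueError(f"need 2 <= c_min <= c_max, got [{c_min}, {c_max}]")
    entries = [
        TargetEntry(_formula_mass(n, 2 * n, 0, 2), (f"C{n}H{2 * n}O2",), "SFA")
        for n in range(c_min, c_max + 1)
    ]
    return TargetMassList(entries)


def to_mz(neutral_mass: float, adduct: str = "[M-H]-") -> float:
    """Expected m/z of a neutral mass under the given adduct (charge 1)."""
    if adduct != "[M-H]-":
        raise ValueError(f"unsupported adduct {adduct!r}")
    return neutral_mass - PROTON_MASS


def match_peaks(
    s: Spectrum,
    targets: TargetMassList,
    adduct: str = "[M-H]-",
    ppm_tol: float = 1.0,
    mz_min: float | None = 150.0,
) -> MatchResult:
    """Match enumerated targets against a measured peak list.

    A target matches when some peak lies within ``ppm_tol`` parts per
    million of its expected m/z; the nearest peak is reported per
    target.  Targets whose expected m/z falls below ``mz_min`` (the
    export window's lower bound, i.e. the detection cutoff) are flagged
    separately and excluded from the measurable denominator.
    """
    if not ppm_tol > 0:
        raise ValueError("ppm tolerance must be positive")
    series = targets.entries[0].series if targets.entries else ""
    expected = np.array([to_mz(e.neutral_mass, adduct) for e in targets.entries])
    if mz_min is not None:
        measurable = expected >= mz_min
    else:
        measurable = np.ones(len(expected), dtype=bool)
    below = [e for e, m in zip(targets.entries, measurable) if not m]
    kept = [e for e, m in zip(targets.entries, measurable) if m]
    exp = expected[measurable]

    mz = s.mz
    if len(mz):
        pos = np.clip(np.searchsorted(mz, exp), 1, len(mz) - 1) if len(mz) > 1 else np.zeros(len(exp), dtype=int)
        lo = np.maximum(pos - 1, 0)
        nearest = np.where(np.abs(mz[lo] - exp) <= np.abs(mz[pos] - exp), lo, pos)
        obs = mz[nearest]
        ppm = (obs - exp) / exp * 1e6
        matched = np.abs(ppm) <= ppm_tol
    else:
        nearest = np.full(len(exp), -1, dtype=int)
        obs = np.full(len(exp), np.nan)
        ppm = np.full(len(exp), np.nan)
        matched = np.zeros(len(exp), dtype=bool)

    return MatchResult(
        series=series,
        adduct=adduct,
        ppm_tol=ppm_tol,
        target_masses=np.array([e.neutral_mass for e in kept]),
        target_mz=exp,
        compositions=[e.compositions for e in kept],
        matched=matched,
        peak_index=nearest,
        observed_mz=obs,
        ppm_error=ppm,
        below_cutoff=below,
    )
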