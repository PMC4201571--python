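"""Monoisotopic mass arithmetic, residue alphabets, PTMs and fragment ions.

Neuropeptides are observed intact (no proteolytic digestion), so the unit of
search is the full peptide sequence plus any localized modifications.  All
masses are monoisotopic; leucine and isoleucine share a neutral residue mass
and are merged into a single symbol ('L') in the 19-letter decoy alphabet.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from math import isfinite
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _ptmass

# Fundamental monoisotopic constants (Da)
PROTON = 1.00727646688
WATER = 18.0105646863
AMMONIA = 17.0265491015

#: the 20 standard residues
STANDARD_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: the 19-symbol alphabet used for decoy generation: isoleucine removed,
#: leucine retained (identical neutral residue masses)
DECOY_ALPHABET = "ACDEFGHKLMNPQRSTVWY"

#: symbol -> monoisotopic residue mass (Da)
RESIDUE_MASS: dict[str, float] = {
    aa: _ptmass.std_aa_mass[aa] for aa in STANDARD_ALPHABET
}

#: mass lookup indexed by decoy-alphabet code (0..18)
DECOY_MASS_TABLE = np.array([RESIDUE_MASS[a] for a in DECOY_ALPHABET])


def normalize_il(sequence: str) -> str:
    """Map isoleucine to leucine; used for all decoy/target equality checks."""
    return sequence.replace("I", "L")


@dataclass(frozen=True)
class ResidueAlphabet:
    """The residue alphabet and its mass map."""

    symbols: str = STANDARD_ALPHABET
    decoy_symbols: str = DECOY_ALPHABET
    residue_mass: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_MASS))


@dataclass(frozen=True)
class ModificationSpec:
    """A post-translational modification.

    ``targets`` is a string of eligible residue symbols (empty = any residue),
    ``position`` restricts placement: 'anywhere', 'n-term' or 'c-term'.
    """

    name: str
    delta_mass: float
    targets: str = ""
    position: str = "anywhere"
    variable: bool = True

    def __post_init__(self) -> None:
        if not isfinite(self.delta_mass):
            raise ValueError(f"non-finite delta mass for modification {self.name!r}")
        if self.position not in ("anywhere", "n-term", "c-term"):
            raise ValueError(f"bad position {self.position!r}")

    def eligible_sites(self, sequence: str):
        """Sites (int index, or 'n-term'/'c-term') where this mod may sit."""
        if self.position == "n-term":
            if not self.targets or sequence[0] in self.targets:
                return ["n-term"]
            return []
        if self.position == "c-term":
            if not self.targets or sequence[-1] in self.targets:
                return ["c-term"]
            return []
        return [i for i, aa in enumerate(sequence) if not self.targets or aa in self.targets]


#: standard neuropeptide PTM set with reference monoisotopic deltas
STANDARD_MODS: dict[str, ModificationSpec] = {
    m.name: m
    for m in (
        ModificationSpec("amidation", -0.984016, position="c-term"),
        ModificationSpec("phosphorylation", +79.966331, targets="STY"),
        ModificationSpec("acetylation_nterm", +42.010565, position="n-term"),
        ModificationSpec("acetylation_K", +42.010565, targets="K"),
        ModificationSpec("pyroglutamination_Q", -17.0265491015, targets="Q", position="n-term"),
        ModificationSpec("methylation_KR", +14.015650, targets="KR"),
        ModificationSpec("sulfation_Y", +79.956815, targets="Y"),
        ModificationSpec("oxidation_M", +15.994915, targets="M"),
    )
}


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with localized modifications.

    ``mods`` is a tuple of (site, ModificationSpec) pairs where site is a
    0-based residue index or 'n-term'/'c-term'.  ``source`` distinguishes
    target-database entries from permuted decoys; decoys carry the id of the
    candidate they were permuted from.
    """

    sequence: str
    mods: tuple = ()
    source: str = "target"
    peptide_id: str = ""
    candidate_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(f"peptide too short: {self.sequence!r}")
        bad = set(self.sequence) - set(STANDARD_ALPHABET)
        if bad:
            raise ValueError(
                f"unknown residue symbol {sorted(bad)[0]!r} in {self.sequence!r}"
            )
        sites = [s for s, _ in self.mods]
        if len(sites) != len(set(sites)):
            raise ValueError("more than one modification on a single site")

    def with_mods(self, mods) -> "Peptide":
        return replace(self, mods=tuple(mods))


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int  # 1..n-1
    loss: str  # 'none' | 'H2O' | 'NH3'
    charge: int
    mz: float


@dataclass(frozen=True)
class TheoreticalSpectrum:
    peptide: Peptide
    ions: tuple
    neutral_mass: float

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([ion.mz for ion in self.ions])


def _mod_deltas(p: Peptide) -> tuple[np.ndarray, float, float]:
    """Per-residue mod deltas plus n-/c-terminal deltas."""
    per_res = np.zeros(len(p.sequence))
    nterm = cterm = 0.0
    for site, spec in p.mods:
        if site == "n-term":
            nterm += spec.delta_mass
        elif site == "c-term":
            cterm += spec.delta_mass
        else:
            per_res[site] += spec.delta_mass
    return per_res, nterm, cterm


def peptide_neutral_mass(p: Peptide) -> float:
    """Monoisotopic neutral mass: residue masses + water + modification deltas."""
    per_res, nterm, cterm = _mod_deltas(p)
    residues = sum(RESIDUE_MASS[aa] for aa in p.sequence)
    return residues + WATER + float(per_res.sum()) + nterm + cterm


def sequence_neutral_mass(sequence: str) -> float:
    """Neutral mass of an unmodified sequence (fast path, no Peptide object)."""
    return sum(RESIDUE_MASS[aa] for aa in sequence) + WATER


def precursor_mz(p: Peptide, z: int) -> float:
    """m/z of the [M + zH]^z+ precursor."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (peptide_neutral_mass(p) + z * PROTON) / z


LOSSES = (("none", 0.0), ("H2O", WATER), ("NH3", AMMONIA))


def fragment_mz_arrays(
    p: Peptide, charges: Iterable[int] = (1,), losses: bool = True
):
    """Fast fragment enumeration.

    Returns (mz, series, index, loss, charge) parallel arrays where series is
    0 for b and 1 for y.  b_i covers prefix residues 1..i (plus any N-terminal
    and in-prefix mods); y_i covers the i-residue suffix plus water.  Water and
    ammonia loss variants are emitted for every ion when ``losses`` is set,
    irrespective of residue composition.
    """
    n = len(p.sequence)
    per_res, nterm, cterm = _mod_deltas(p)
    res = np.array([RESIDUE_MASS[aa] for aa in p.sequence]) + per_res
    prefix = np.cumsum(res)[:-1] + nterm  # b_1 .. b_{n-1} neutral fragment part
    suffix = np.cumsum(res[::-1])[:-1] + cterm + WATER  # y_1 .. y_{n-1}

    loss_list = LOSSES if losses else (("none", 0.0),)
    mz_out, series_out, idx_out, loss_out, z_out = [], [], [], [], []
    idx = np.arange(1, n)
    for z in sorted(set(int(c) for c in charges)):
        if z < 1:
            raise ValueError(f"product charge must be >= 1, got {z}")
        for loss_name, loss_mass in loss_list:
            mz_out.append((prefix - loss_mass + z * PROTON) / z)
            mz_out.append((suffix - loss_mass + z * PROTON) / z)
            for s in (0, 1):
                series_out.append(np.full(n - 1, s, dtype=np.int8))
                idx_out.append(idx)
                loss_out.append(np.full(n - 1, loss_name, dtype=object))
                z_out.append(np.full(n - 1, z, dtype=np.int8))

    return (
        np.concatenate(mz_out),
        np.concatenate(series_out),
        np.concatenate(idx_out),
        np.concatenate(loss_out),
        np.concatenate(z_out),
    )


def generate_fragments(
    p: Peptide, charges: Iterable[int] = (1,), losses: bool = True
) -> TheoreticalSpectrum:
    """All b/y fragment ions of ``p`` at the requested product charges."""
    mz, series, idx, loss, z = fragment_mz_arrays(p, charges, losses)
    order = np.argsort(mz, kind="stable")
    ions = tuple(
        FragmentIon("by"[series[i]], int(idx[i]), str(loss[i]), int(z[i]), float(mz[i]))
        for i in order
    )
    return TheoreticalSpectrum(p, ions, peptide_neutral_mass(p))


def enumerate_mod_variants(
    p: Peptide, mods: Sequence[ModificationSpec], max_var: int = 3
) -> list[Peptide]:
    """All placements of variable modifications on ``p``.

    Fixed mods are applied to every eligible site unconditionally; variable
    mods are enumerated with at most one modification per site and at most
    ``max_var`` variable mods in total.  The unmodified (fixed-only) peptide is
    always included.
    """
    if max_var < 0:
        raise ValueError("max_var must be >= 0")
    fixed_assign = []
    occupied = set()
    for spec in mods:
        if not spec.variable:
            for site in spec.eligible_sites(p.sequence):
                if site not in occupied:
                    fixed_assign.append((site, spec))
                    occupied.add(site)

    site_options = []  # (site, spec) choices for variable mods
    for spec in mods:
        if spec.variable:
            for site in spec.eligible_sites(p.sequence):
                if site not in occupied:
                    site_options.append((site, spec))

    variants: dict[tuple, Peptide] = {}

    def _key(assign):
        return tuple(sorted(((str(s), m.name) for s, m in assign)))

    for r in range(0, min(max_var, len(site_options)) + 1):
        for combo in itertools.combinations(site_options, r):
            sites = [s for s, _ in combo]
            if len(sites) != len(set(sites)):
                continue
            assign = tuple(fixed_assign) + tuple(combo)
            variants.setdefault(_key(assign), p.with_mods(assign))
    return list(variants.values())
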