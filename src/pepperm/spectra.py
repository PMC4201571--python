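"""Spectrum and database containers, FASTA/MGF I/O, and simulators.

The simulators provide the synthetic test-bed: ideal uniform spectra (every
+1 b/y ion, water/ammonia losses included, equal intensities) stand in for
manually validated reference spectra, and the noisy simulator perturbs them
with m/z jitter, peak dropout, and uniform background peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _ptmgf

from .mass_model import (
    DECOY_ALPHABET,
    PROTON,
    STANDARD_ALPHABET,
    Peptide,
    fragment_mz_arrays,
    peptide_neutral_mass,
    precursor_mz,
)

#: intensity assigned to every peak of an ideal uniform spectrum (arbitrary
#: units; scale cancels in rank-based permutation p-values)
IDEAL_INTENSITY = 100.0
#: theoretical m/z values closer than this are merged into one peak
MZ_MERGE_TOL = 1e-4


@dataclass(frozen=True)
class ExperimentalSpectrum:
    """A tandem spectrum: precursor m/z + charge and a centroided peak list."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.spectrum_id!r} has no peaks")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in spectrum {self.spectrum_id!r}")
        order = np.argsort(self.mz, kind="stable")
        object.__setattr__(self, "mz", self.mz[order])
        object.__setattr__(self, "intensity", self.intensity[order])

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def neutral_mass(self, charge: int | None = None) -> float:
        """Neutral precursor mass at the stated (or an assumed) charge."""
        z = self.precursor_charge if charge is None else charge
        return self.precursor_mz * z - z * PROTON


@dataclass
class PeptideDatabase:
    """An ordered collection of peptides with unique identifiers."""

    entries: list[Peptide] = field(default_factory=list)
    name: str = "database"

    def __post_init__(self) -> None:
        ids = [p.peptide_id for p in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate peptide identifiers in database")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.entries]

    def neutral_masses(self) -> np.ndarray:
        return np.array([peptide_neutral_mass(p) for p in self.entries])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> PeptideDatabase:
    """Strict FASTA reader over the 20-letter residue alphabet.

    Malformed records are rejected with the offending line number; sequences
    containing non-residue characters are rejected naming the character.
    """
    entries: list[Peptide] = []
    header: str | None = None
    seq_parts: list[str] = []
    header_line = 0

    def _flush(line_no: int) -> None:
        nonlocal header, seq_parts
        if header is None:
            return
        seq = "".join(seq_parts)
        if not seq:
            raise ValueError(f"line {header_line}: record {header!r} has no sequence")
        bad = set(seq) - set(STANDARD_ALPHABET)
        if bad:
            raise ValueError(
                f"line {header_line}: non-residue character {sorted(bad)[0]!r} "
                f"in record {header!r}"
            )
        pid = header.split()[0]
        source = "decoy" if pid.startswith("decoy|") else "target"
        candidate_id = pid.split("|")[1] if source == "decoy" else ""
        entries.append(
            Peptide(seq, source=source, peptide_id=pid, candidate_id=candidate_id)
        )
        header, seq_parts = None, []

    line_no = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise ValueError(f"line {line_no}: empty FASTA header")
            else:
                if header is None:
                    raise ValueError(f"line {line_no}: sequence data before any header")
                seq_parts.append(line.upper())
        _flush(line_no if entries or header else 0)
    return PeptideDatabase(entries, name=str(path))


def write_fasta(db, path) -> None:
    """Write a database (or iterable of peptides) as wrapped FASTA."""
    with open(path, "w") as fh:
        for p in db:
            fh.write(f">{p.peptide_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path) -> list[ExperimentalSpectrum]:
    """Read spectra from a Mascot Generic Format file.

    PEPMASS is interpreted as the precursor m/z (first value only).  Blocks
    without a CHARGE line default to 1+ with a warning.
    """
    spectra = []
    with _ptmgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params:
                raise ValueError(f"spectrum block {i}: missing PEPMASS")
            pep = params["pepmass"]
            mz0 = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            if "charge" in params:
                charge = int(params["charge"][0])
            else:
                warnings.warn(f"spectrum block {i}: missing CHARGE, assuming 1+")
                charge = 1
            if len(entry["m/z array"]) == 0:
                raise ValueError(f"spectrum block {i}: empty peak list")
            sid = str(params.get("title", f"spectrum_{i}"))
            spectra.append(
                ExperimentalSpectrum(
                    sid, mz0, charge, entry["m/z array"], entry["intensity array"]
                )
            )
    return spectra


def write_mgf(spectra, path) -> None:
    """Deterministic MGF writer (round-trips through :func:`read_mgf`)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def merge_peaks(mz: np.ndarray, intensity: np.ndarray, tol: float = MZ_MERGE_TOL):
    """Merge peaks whose m/z coincide within ``tol`` (intensities summed is
    wrong for ideal uniform spectra, so the merged peak keeps one unit)."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    keep_mz, keep_int = [mz[0]], [intensity[0]]
    for m, h in zip(mz[1:], intensity[1:]):
        if m - keep_mz[-1] <= tol:
            keep_int[-1] = max(keep_int[-1], h)
        else:
            keep_mz.append(m)
            keep_int.append(h)
    return np.array(keep_mz), np.array(keep_int)


def simulate_ideal_spectrum(p: Peptide, charge: int = 1) -> ExperimentalSpectrum:
    """Ideal uniform spectrum: one equal-intensity peak per +1 b/y ion,
    including single water and ammonia losses for every ion."""
    mz, *_ = fragment_mz_arrays(p, charges=(1,), losses=True)
    mz, inten = merge_peaks(np.asarray(mz), np.full(mz.shape, IDEAL_INTENSITY))
    return ExperimentalSpectrum(
        f"ideal_{p.peptide_id or p.sequence}", precursor_mz(p, charge), charge, mz, inten
    )


def synthesize_noisy_spectrum(
    p: Peptide,
    rng: np.random.Generator,
    jitter_sd: float = 0.05,
    drop_frac: float = 0.2,
    n_noise_peaks: int = 20,
    noise_intensity: float = 30.0,
    charge: int = 1,
) -> ExperimentalSpectrum:
    """Ideal spectrum perturbed to emulate a real acquisition.

    Peak m/z values receive Gaussian jitter (``jitter_sd`` Da), a fraction of
    the true peaks is dropped, and uniform-random background peaks are added
    across the observed m/z range with exponential intensities.
    """
    if not 0 <= drop_frac < 1:
        raise ValueError("drop_frac must be in [0, 1)")
    ideal = simulate_ideal_spectrum(p, charge=charge)
    n = ideal.n_peaks
    n_keep = n - int(round(drop_frac * n))
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    mz = ideal.mz[keep]
    inten = ideal.intensity[keep]
    if jitter_sd > 0:
        mz = mz + rng.normal(0.0, jitter_sd, size=mz.shape)
    if n_noise_peaks > 0:
        lo, hi = float(ideal.mz.min()), float(ideal.mz.max())
        noise_mz = rng.uniform(lo, hi, size=n_noise_peaks)
        noise_int = rng.exponential(noise_intensity, size=n_noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    return ExperimentalSpectrum(
        f"noisy_{p.peptide_id or p.sequence}",
        ideal.precursor_mz,
        ideal.precursor_charge,
        np.abs(mz),
        inten,
    )


def default_length_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Neuropeptide-like length distribution: lognormal around ~15 residues,
    clipped to the supported 2-60 range."""
    lengths = np.round(rng.lognormal(mean=np.log(15.0), sigma=0.45, size=n))
    return np.clip(lengths, 2, 60).astype(int)


def generate_synthetic_database(
    n_peptides: int,
    rng: np.random.Generator,
    length_dist=None,
    name: str = "synthetic",
) -> PeptideDatabase:
    """Random unique peptides over the 19-symbol decoy alphabet.

    ``length_dist`` may be None (default neuropeptide-like sampler), an int
    (constant length), or a callable ``f(rng, n) -> lengths``.
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    if length_dist is None:
        sampler = default_length_sampler
    elif isinstance(length_dist, int):
        sampler = lambda r, n: np.full(n, length_dist, dtype=int)  # noqa: E731
    else:
        sampler = length_dist

    alphabet = np.array(list(DECOY_ALPHABET))
    seen: set[str] = set()
    entries: list[Peptide] = []
    while len(entries) < n_peptides:
        need = n_peptides - len(entries)
        lengths = sampler(rng, need)
        for L in lengths:
            seq = "".join(alphabet[rng.integers(0, 19, size=int(L))])
            if seq in seen:
                continue
            seen.add(seq)
            entries.append(
                Peptide(seq, peptide_id=f"syn{len(entries):04d}", source="target")
            )
    return PeptideDatabase(entries, name=name)
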