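"""End-to-end miniature fixture: a small target database, ideal and noisy
spectra of known peptides, and the truth mapping — everything needed to
exercise the full decoy/search/report pipeline from files."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra import (
    PeptideDatabase,
    generate_synthetic_database,
    simulate_ideal_spectrum,
    synthesize_noisy_spectrum,
    write_fasta,
    write_mgf,
)


@dataclass
class EndToEndFixture:
    target_db: PeptideDatabase
    spectra: list
    truth: dict  # spectrum_id -> true sequence
    fasta_path: Path | None = None
    mgf_path: Path | None = None


def end_to_end_fixture(
    seed: int,
    out_dir=None,
    n_peptides: int = 20,
    n_ideal: int = 10,
    n_noisy: int = 10,
    drop_frac: float = 0.3,
    jitter_sd: float = 0.02,
    n_noise_peaks: int = 15,
) -> EndToEndFixture:
    """Miniature experiment: 20-peptide database, 10 ideal and 10 noisy
    spectra of known database peptides.  Deterministic under ``seed``; when
    ``out_dir`` is given, FASTA/MGF files are written there."""
    rng = np.random.default_rng(seed)
    db = generate_synthetic_database(n_peptides, rng, length_dist=12, name="fixture")
    idx = rng.choice(len(db), size=max(n_ideal, n_noisy), replace=False)
    spectra, truth = [], {}
    for j in range(n_ideal):
        p = db.entries[int(idx[j % idx.size])]
        s = simulate_ideal_spectrum(p, charge=1)
        s = type(s)(f"ideal_{j:02d}", s.precursor_mz, 1, s.mz, s.intensity)
        spectra.append(s)
        truth[s.spectrum_id] = p.sequence
    for j in range(n_noisy):
        p = db.entries[int(idx[j % idx.size])]
        s = synthesize_noisy_spectrum(
            p,
            rng,
            jitter_sd=jitter_sd,
            drop_frac=drop_frac,
            n_noise_peaks=n_noise_peaks,
            charge=1,
        )
        s = type(s)(f"noisy_{j:02d}", s.precursor_mz, 1, s.mz, s.intensity)
        spectra.append(s)
        truth[s.spectrum_id] = p.sequence

    fixture = EndToEndFixture(db, spectra, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fixture.fasta_path = out / "target.fasta"
        fixture.mgf_path = out / "spectra.mgf"
        write_fasta(db, fixture.fasta_path)
        write_mgf(spectra, fixture.mgf_path)
        with open(out / "truth.tsv", "w") as fh:
            fh.write("spectrum_id\ttrue_sequence\n")
            for sid, seq in truth.items():
                fh.write(f"{sid}\t{seq}\n")
    return fixture
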