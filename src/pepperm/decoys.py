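"""Monte Carlo k-permuted decoy databases.

For each candidate peptide (a target entry whose mass lies near an observed
precursor mass), k unique random sequences of the same length are drawn with
every position sampled i.i.d. uniformly from the 19-symbol I/L-merged
alphabet (a zero-order Markov model).  Draws colliding with the candidate,
any target entry, or an already-emitted decoy (all compared after I->L
normalization) are rejected and redrawn, so the finished database holds
exactly k x |candidates| unique decoys.  The target database is appended to
form the combined search database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mass_model import DECOY_ALPHABET, DECOY_MASS_TABLE, WATER, Peptide, normalize_il
from .spectra import PeptideDatabase

_ALPHA_BYTES = np.frombuffer(DECOY_ALPHABET.encode(), dtype=np.uint8)
#: maps ASCII byte -> decoy alphabet code (19 = not in alphabet)
_BYTE_TO_CODE = np.full(256, 19, dtype=np.uint8)
_BYTE_TO_CODE[_ALPHA_BYTES] = np.arange(19, dtype=np.uint8)


@dataclass
class CandidateSet:
    """Target peptides within the precursor-mass window of observed spectra."""

    candidates: list[Peptide]
    window_da: float
    observed_masses: np.ndarray


@dataclass
class DecoyDatabase:
    """A k-permuted decoy database, optionally combined with its targets.

    Decoy sequences are held per candidate as compact fixed-width byte
    arrays; :meth:`iter_decoys` materializes :class:`Peptide` objects.
    """

    k: int
    seed: int
    target: PeptideDatabase
    combined: bool = True
    _blocks: list = field(default_factory=list)  # (candidate, np.ndarray['S{L}'])

    @property
    def n_decoys(self) -> int:
        return int(sum(arr.size for _, arr in self._blocks))

    @property
    def candidates(self) -> list[Peptide]:
        return [cand for cand, _ in self._blocks]

    def iter_decoys(self):
        for cand, arr in self._blocks:
            for i, raw in enumerate(arr):
                yield Peptide(
                    raw.decode(),
                    source="decoy",
                    peptide_id=f"decoy|{cand.peptide_id}|{i}|seed={self.seed}",
                    candidate_id=cand.peptide_id,
                )

    def __iter__(self):
        yield from self.iter_decoys()
        if self.combined:
            yield from self.target

    def decoy_sequences(self) -> list[str]:
        return [raw.decode() for _, arr in self._blocks for raw in arr]

    def decoy_code_blocks(self):
        """(candidate, codes) pairs where codes is a (k, L) uint8 matrix of
        decoy-alphabet indices."""
        for cand, arr in self._blocks:
            L = arr.dtype.itemsize
            codes = _BYTE_TO_CODE[np.frombuffer(arr.tobytes(), dtype=np.uint8)]
            yield cand, codes.reshape(arr.size, L)

    def decoy_masses(self) -> np.ndarray:
        """Neutral monoisotopic masses of all decoys, in block order."""
        out = []
        for _, codes in self.decoy_code_blocks():
            out.append(DECOY_MASS_TABLE[codes].sum(axis=1) + WATER)
        return np.concatenate(out) if out else np.array([])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for cand, arr in self._blocks:
                cid = cand.peptide_id
                for i, raw in enumerate(arr):
                    fh.write(f">decoy|{cid}|{i}|seed={self.seed}\n{raw.decode()}\n")
            if self.combined:
                for p in self.target:
                    fh.write(f">{p.peptide_id}\n{p.sequence}\n")


def select_candidates(
    db: PeptideDatabase, observed_masses, window_da: float = 12.0
) -> CandidateSet:
    """Target entries whose neutral mass is within +-window_da (closed
    interval) of at least one observed neutral mass."""
    if window_da <= 0:
        raise ValueError("window_da must be positive")
    observed = np.sort(np.asarray(observed_masses, dtype=float))
    masses = db.neutral_masses()
    lo = np.searchsorted(observed, masses - window_da, side="left")
    hi = np.searchsorted(observed, masses + window_da, side="right")
    keep = hi > lo
    candidates = [p for p, k in zip(db.entries, keep) if k]
    if not candidates:
        warnings.warn("no target peptides within the precursor-mass window")
    return CandidateSet(candidates, float(window_da), observed)


def _codes_to_bytes(codes: np.ndarray) -> np.ndarray:
    """(n, L) uint8 code matrix -> array of fixed-width byte strings."""
    L = codes.shape[1]
    return _ALPHA_BYTES[codes].view(f"S{L}").ravel()


def _enumerate_space(length: int) -> np.ndarray:
    """All 19^length sequences as an 'S{length}' array (small lengths only)."""
    grids = np.meshgrid(*([np.arange(19, dtype=np.uint8)] * length), indexing="ij")
    codes = np.stack([g.ravel() for g in grids], axis=1)
    return _codes_to_bytes(codes)


def _draw_unique(
    length: int, k: int, rng: np.random.Generator, forbidden: np.ndarray
) -> np.ndarray:
    """k unique random sequences of ``length`` avoiding the sorted byte-string
    array ``forbidden``; raises with the attainable maximum when k exceeds it."""
    space = 19**length
    available = space - forbidden.size  # forbidden entries are unique & in-space
    if k > available:
        raise ValueError(
            f"requested k={k} exceeds the {available} attainable decoys "
            f"for length {length} (space 19^{length} = {space})"
        )
    if space <= 600_000:  # exhaustive path for tiny sequence spaces
        pool = _enumerate_space(length)
        pool = pool[~np.isin(pool, forbidden)]
        idx = rng.choice(pool.size, size=k, replace=False)
        return pool[np.sort(idx)]

    # pure rejection-and-redraw: each round draws exactly the deficit, so no
    # draw is ever discarded for reasons other than a collision (truncating a
    # sorted surplus would bias the composition of the first position)
    chunks: list[np.ndarray] = []
    got = 0
    while got < k:
        draw = rng.integers(0, 19, size=(k - got, length), dtype=np.uint8)
        cand = np.unique(_codes_to_bytes(draw))
        cand = cand[np.isin(cand, forbidden, invert=True, kind="sort")]
        if chunks:
            prior = np.concatenate(chunks)
            cand = cand[np.isin(cand, prior, invert=True, kind="sort")]
        if cand.size:
            chunks.append(cand)
            got += cand.size
    return np.sort(np.concatenate(chunks))


def k_permute(
    candidate: Peptide,
    k: int,
    rng: np.random.Generator,
    target_sequences=(),
    emitted=(),
) -> list[str]:
    """k unique uniform-random sequences of the candidate's length.

    Sequences equal (after I->L normalization) to the candidate, to any
    sequence in ``target_sequences``, or to ``emitted`` decoys are rejected
    and redrawn.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = len(candidate.sequence)
    forb = {normalize_il(candidate.sequence)}
    forb.update(normalize_il(s) for s in target_sequences if len(s) == L)
    forb.update(s for s in emitted if len(s) == L)
    forbidden = np.sort(np.array(sorted(forb), dtype=f"S{L}"))
    return [s.decode() for s in _draw_unique(L, k, rng, forbidden)]


def build_combined_database(
    cs: CandidateSet, target: PeptideDatabase, k: int, seed: int
) -> DecoyDatabase:
    """Build the combined target + k-permuted decoy database.

    Exactly k decoys per candidate; uniqueness is enforced across the whole
    decoy database and against the I/L-normalized target, by rejection and
    redraw, so the decoy count is exactly k x |candidates|.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    db = DecoyDatabase(k=k, seed=seed, target=target, combined=True)

    targets_by_len: dict[int, list[bytes]] = {}
    for seq in target.sequences():
        targets_by_len.setdefault(len(seq), []).append(normalize_il(seq).encode())
    forb_by_len = {
        L: np.array(sorted(set(v)), dtype=f"S{L}") for L, v in targets_by_len.items()
    }

    # Small sequence spaces (short peptides) see frequent cross-candidate
    # collisions, so their exclusion pool is carried along; for larger spaces
    # candidates draw independently against the target set only and the rare
    # cross-candidate duplicates are repaired in a global pass afterwards.
    SMALL_SPACE = 600_000
    blocks_by_len: dict[int, list[int]] = {}
    for cand in cs.candidates:
        L = len(cand.sequence)
        forb = forb_by_len.get(L, np.array([], dtype=f"S{L}"))
        if 19**L <= SMALL_SPACE:
            arr = _draw_unique(L, k, rng, forb)
            forb_by_len[L] = np.sort(np.concatenate([forb, arr]))
        else:
            arr = _draw_unique(L, k, rng, forb)
        blocks_by_len.setdefault(L, []).append(len(db._blocks))
        db._blocks.append((cand, arr))

    for L, block_ids in blocks_by_len.items():
        if 19**L <= SMALL_SPACE or len(block_ids) < 2:
            continue
        pooled = np.concatenate([db._blocks[b][1] for b in block_ids])
        uniq, counts = np.unique(pooled, return_counts=True)
        if uniq.size == pooled.size:
            continue
        dup = np.sort(uniq[counts > 1])
        taken = uniq
        for b in block_ids:
            cand, arr = db._blocks[b]
            is_dup = np.isin(arr, dup, kind="sort")
            first = np.zeros(arr.size, dtype=bool)  # keep one owner per dup
            remaining = dup
            hit = arr[is_dup]
            keep_mask = np.isin(hit, remaining, kind="sort")
            first[np.nonzero(is_dup)[0][keep_mask]] = True
            remaining = remaining[np.isin(remaining, hit, invert=True, kind="sort")]
            dup = remaining
            redraw = is_dup & ~first
            n_redraw = int(redraw.sum())
            if n_redraw:
                forb = np.sort(
                    np.concatenate([forb_by_len.get(L, np.array([], dtype=f"S{L}")), taken])
                )
                fresh = _draw_unique(L, n_redraw, rng, forb)
                arr = arr.copy()
                arr[np.nonzero(redraw)[0]] = fresh
                taken = np.sort(np.concatenate([taken, fresh]))
                db._blocks[b] = (cand, np.sort(arr))
    return db
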