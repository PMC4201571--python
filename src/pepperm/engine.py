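"""Scoring of spectra against combined target + decoy databases, homeometric
collapsing, and Monte Carlo permutation p-values.

The permutation p-value of a target match is the fraction of scored combined
target + k-permuted decoy peptides (collapsed so that homeometric matches —
identical indicator tuples with masses chained within +-1.5 Da — count once)
whose indicator is equal to or better than the target's, the target's own
cluster included, so no p-value is ever zero.  Significance level t bins
follow the convention "significant at p < 1e-t".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .decoys import DecoyDatabase, select_candidates
from .indicators import (
    INDICATOR_DIRECTIONS,
    INDICATOR_NAMES,
    MatchIndicators,
    compare,
    round_sig,
    count_consecutive,
    greedy_match,
    hyperscore,
    top_peak_prefilter,
    xcorr_background,
    xcorr_from_background,
)
from .mass_model import (
    STANDARD_MODS,
    Peptide,
    enumerate_mod_variants,
    fragment_mz_arrays,
    peptide_neutral_mass,
)
from .spectra import ExperimentalSpectrum, MZ_MERGE_TOL

MAX_T_LEVEL = 6


@dataclass(frozen=True)
class MatchRecord:
    spectrum_id: str
    peptide: Peptide
    neutral_mass: float
    indicators: MatchIndicators


@dataclass(frozen=True)
class HomeometricCluster:
    members: tuple
    representative: MatchRecord


@dataclass(frozen=True)
class PermutationResult:
    spectrum_id: str
    indicator: str
    target_score: float
    n_candidates_collapsed: int
    n_equal_or_better: int
    p_value: float  # NaN when the indicator is undefined for the target
    t_level: int

    @property
    def missing(self) -> bool:
        return np.isnan(self.p_value)


def t_level(p: float) -> int:
    """Largest t in 0..6 with p < 1e-t (capped at 6, the '>=6' bin)."""
    if np.isnan(p):
        return -1
    t = 0
    while t < MAX_T_LEVEL and p < 10.0 ** -(t + 1):
        t += 1
    return t


# ---------------------------------------------------------------------------
# Array-backed scoring core
# ---------------------------------------------------------------------------

class SpectrumScorer:
    """Per-spectrum context: preprocessed arrays shared by all candidates."""

    def __init__(self, exp: ExperimentalSpectrum, config: RunConfig):
        self.exp = exp
        self.config = config
        self.mz_range = float(exp.mz.max() - exp.mz.min())
        if self.mz_range <= 0:
            raise ValueError(
                f"spectrum {exp.spectrum_id!r}: degenerate single-point m/z range"
            )
        self.n_peaks_considered = min(config.top_peaks_lambda, exp.n_peaks)
        self.yprime = xcorr_background(exp, config.bin_width)

    def score_one(self, peptide: Peptide, mass: float):
        """Raw per-candidate scores; Poisson family and deltaCn are filled in
        vectorized passes afterwards."""
        cfg = self.config
        mz, series, idx, loss, z = fragment_mz_arrays(peptide, cfg.charges, cfg.losses)
        order = np.argsort(mz, kind="stable")
        mz, series, idx, loss, z = (
            mz[order], series[order], idx[order], loss[order], z[order]
        )
        n_theo = mz.size
        n_theo_mz = int(1 + np.count_nonzero(np.diff(mz) > MZ_MERGE_TOL))

        if cfg.prefilter and not top_peak_prefilter(
            self.exp, mz, cfg.top_n, cfg.frag_tol_da
        ):
            matched: list[tuple[int, int]] = []
        else:
            matched = greedy_match(mz, self.exp.mz, cfg.frag_tol_da)

        t_idx = np.array([t for t, _ in matched], dtype=int)
        e_idx = np.array([e for _, e in matched], dtype=int)
        n_matched = len(matched)
        conv = float(self.exp.intensity[e_idx].sum()) if n_matched else 0.0
        n_b = int(np.count_nonzero(series[t_idx] == 0)) if n_matched else 0
        n_y = n_matched - n_b
        hyper = hyperscore(n_b, n_y, conv)
        n_consec = (
            count_consecutive(series[t_idx], idx[t_idx], loss[t_idx], z[t_idx])
            if n_matched
            else 0
        )
        sp = conv * (n_matched / n_theo) * (1.0 + 0.075 * n_consec)
        xc = xcorr_from_background(mz, self.yprime, cfg.bin_width)
        lam = max(
            n_theo_mz * self.n_peaks_considered * 2.0 * cfg.frag_tol_da / self.mz_range,
            1e-12,
        )
        return n_matched, conv, hyper, sp, xc, lam


def _eligible_entries(db, neutral_mass: float, prec_tol: float):
    """(peptide-or-sequence iterator) restricted by the precursor window.

    For a DecoyDatabase the decoy mass filter runs vectorized over the
    compact byte blocks; target entries are checked one by one.
    """
    out: list[tuple[Peptide, float]] = []
    if isinstance(db, DecoyDatabase):
        masses = db.decoy_masses()
        keep = np.abs(masses - neutral_mass) <= prec_tol
        offset = 0
        for cand, arr in db._blocks:
            for i in np.nonzero(keep[offset : offset + arr.size])[0]:
                p = Peptide(
                    arr[i].decode(),
                    source="decoy",
                    peptide_id=f"decoy|{cand.peptide_id}|{int(i)}|seed={db.seed}",
                    candidate_id=cand.peptide_id,
                )
                out.append((p, float(masses[offset + int(i)])))
            offset += arr.size
        entries = db.target.entries if db.combined else []
    else:
        entries = list(db)
    for p in entries:
        m = peptide_neutral_mass(p)
        if abs(m - neutral_mass) <= prec_tol:
            out.append((p, m))
    return out


def score_spectrum(
    exp: ExperimentalSpectrum,
    db,
    config: RunConfig = RunConfig(),
    charge: int | None = None,
) -> list[MatchRecord]:
    """Score every database entry within the precursor tolerance.

    ``db`` may be a DecoyDatabase (combined target + decoys) or any iterable
    of peptides.  Variable modifications named in ``config.mods`` expand each
    entry over its modification variants.  When the spectrum charge is
    unknown (0), charges 1-4 are searched and pooled.
    """
    charges = (
        [exp.precursor_charge]
        if (charge is None and exp.precursor_charge >= 1)
        else ([charge] if charge else [1, 2, 3, 4])
    )
    mods = [STANDARD_MODS[name] for name in config.mods]
    scorer = SpectrumScorer(exp, config)

    # with modifications enabled, an entry may reach the precursor window only
    # after a mass shift: widen the pre-expansion filter by the largest total
    # shift any variant can carry
    slack = 0.0
    if mods:
        variable = sorted((abs(m.delta_mass) for m in mods if m.variable), reverse=True)
        slack = sum(variable[: config.max_var]) + sum(
            abs(m.delta_mass) for m in mods if not m.variable
        )

    peptides: list[Peptide] = []
    masses: list[float] = []
    for z in charges:
        neutral = exp.neutral_mass(z)
        for p, m in _eligible_entries(db, neutral, config.prec_tol_da + slack):
            if mods:
                for var in enumerate_mod_variants(p, mods, config.max_var):
                    mv = peptide_neutral_mass(var)
                    if abs(mv - neutral) <= config.prec_tol_da:
                        peptides.append(var)
                        masses.append(mv)
            else:
                peptides.append(p)
                masses.append(m)
    if not peptides:
        warnings.warn(f"spectrum {exp.spectrum_id!r}: no candidates within tolerance")
        return []

    raw = np.array([scorer.score_one(p, m) for p, m in zip(peptides, masses)])
    n_matched = raw[:, 0].astype(int)
    conv, hyper, sp, xc, lam = raw[:, 1], raw[:, 2], raw[:, 3], raw[:, 4], raw[:, 5]
    poisson_p = stats.poisson.sf(n_matched - 1, lam)
    poisson_p[n_matched <= 0] = 1.0
    e_value = poisson_p * len(peptides)
    best = float(np.max(xc))
    dcn = (best - xc) / best if best > 0 else np.full(xc.shape, np.nan)

    records = [
        MatchRecord(
            exp.spectrum_id,
            p,
            float(m),
            MatchIndicators(
                int(n_matched[i]), float(conv[i]), float(hyper[i]), float(sp[i]),
                float(xc[i]), float(dcn[i]), float(lam[i]), float(poisson_p[i]),
                float(e_value[i]),
            ),
        )
        for i, (p, m) in enumerate(zip(peptides, masses))
    ]
    records.sort(
        key=lambda r: (-r.indicators.n_matched, -r.indicators.hyperscore, r.peptide.peptide_id)
    )
    return records


# ---------------------------------------------------------------------------
# Homeometric collapsing
# ---------------------------------------------------------------------------

def _cluster_labels(
    indicator_matrix: np.ndarray, masses: np.ndarray, mass_tol: float, rounding: int
) -> np.ndarray:
    """Cluster label per record: identical rounded indicator tuples, then
    single-linkage chaining on mass with link distance <= mass_tol."""
    rounded = round_sig(indicator_matrix, rounding)
    labels = np.full(masses.size, -1, dtype=int)
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(rounded):
        # NaN != NaN; use a stable textual key so missing values group together
        key = tuple("nan" if np.isnan(v) else v for v in row)
        groups.setdefault(key, []).append(i)
    next_label = 0
    for members in groups.values():
        members = np.array(members)
        order = members[np.argsort(masses[members], kind="stable")]
        m_sorted = masses[order]
        breaks = np.nonzero(np.diff(m_sorted) > mass_tol)[0]
        cluster_of = np.zeros(order.size, dtype=int)
        for b in breaks:
            cluster_of[b + 1 :] += 1
        for pos, rec_idx in enumerate(order):
            labels[rec_idx] = next_label + cluster_of[pos]
        next_label += int(cluster_of[-1]) + 1 if order.size else 0
    return labels


def collapse_homeometric(
    records: list[MatchRecord],
    mass_tol: float = 1.5,
    rounding: int = 6,
) -> list[HomeometricCluster]:
    """Partition records into homeometric clusters.

    Clusters hold records with identical indicator tuples (rounded to
    ``rounding`` significant digits)
    whose masses chain within ``mass_tol`` under single linkage.  A cluster
    containing a target record is represented by that target record.
    """
    if not records:
        return []
    mat = np.array([r.indicators.as_tuple() for r in records], dtype=float)
    masses = np.array([r.neutral_mass for r in records])
    labels = _cluster_labels(mat, masses, mass_tol, rounding)
    clusters: dict[int, list[MatchRecord]] = {}
    for lab, rec in zip(labels, records):
        clusters.setdefault(int(lab), []).append(rec)
    out = []
    for lab in sorted(clusters):
        members = clusters[lab]
        rep = next((r for r in members if r.peptide.source == "target"), members[0])
        out.append(HomeometricCluster(tuple(members), rep))
    return out


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

def permutation_pvalue(
    clusters: list[HomeometricCluster],
    target: MatchRecord,
    indicator: str,
    direction: str | None = None,
    rounding: int = 6,
) -> PermutationResult:
    """Permutation p-value of ``target`` for one indicator.

    p = (#clusters with indicator equal-or-better than the target's, the
    target's own cluster included) / (#clusters).  Undefined target values
    (NaN deltaCn) yield a result flagged missing rather than p = 1.
    """
    names = list(INDICATOR_NAMES)
    col = names.index(indicator)
    direction = direction or INDICATOR_DIRECTIONS[indicator]
    target_cluster = next(
        (c for c in clusters if any(r is target for r in c.members)), None
    )
    if target_cluster is None:
        raise ValueError("target record not present among the clusters")
    tval = round_sig(target_cluster.representative.indicators.as_tuple()[col], rounding)
    n_clusters = len(clusters)
    if np.isnan(tval):
        return PermutationResult(
            target.spectrum_id, indicator, float("nan"), n_clusters, 0, float("nan"), -1
        )
    n_eq_better = sum(
        1
        for c in clusters
        if compare(round_sig(c.representative.indicators.as_tuple()[col], rounding), tval, direction)
    )
    p = n_eq_better / n_clusters
    return PermutationResult(
        target.spectrum_id, indicator, float(tval), n_clusters, n_eq_better, p, t_level(p)
    )


def spectrum_pvalues(
    records: list[MatchRecord],
    target: MatchRecord,
    config: RunConfig = RunConfig(),
    indicators=INDICATOR_NAMES,
) -> list[PermutationResult]:
    """Collapse then compute permutation p-values for each indicator."""
    clusters = collapse_homeometric(records, config.mass_tol_da, config.rounding)
    return [permutation_pvalue(clusters, target, name, rounding=config.rounding) for name in indicators]


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

def find_target_record(
    records: list[MatchRecord], true_sequence: str | None = None
) -> MatchRecord | None:
    """The record for the known true peptide, or the best-scoring target."""
    targets = [r for r in records if r.peptide.source == "target"]
    if true_sequence is not None:
        targets = [r for r in targets if r.peptide.sequence == true_sequence]
    if not targets:
        return None
    return max(targets, key=lambda r: (r.indicators.n_matched, r.indicators.hyperscore))


def run_experiment(
    spectra,
    target_db,
    k_levels,
    seed: int,
    config: RunConfig = RunConfig(),
    truth: dict | None = None,
    candidate_set=None,
    indicators=INDICATOR_NAMES,
) -> pd.DataFrame:
    """Full pipeline over several decoy sizes k.

    For each k one combined database is built (decoys shared across all
    spectra, seeded deterministically from ``seed``), every spectrum is
    scored against it, and permutation p-values are emitted per indicator.
    ``truth`` maps spectrum_id -> true peptide sequence when known.
    """
    from .decoys import build_combined_database

    k_levels = list(k_levels)
    if candidate_set is None:
        observed = [s.neutral_mass() for s in spectra]
        candidate_set = select_candidates(target_db, observed, config.window_da)

    child_seeds = np.random.SeedSequence(seed).generate_state(len(k_levels))
    rows = []
    for k, kseed in zip(k_levels, child_seeds):
        db = build_combined_database(candidate_set, target_db, int(k), int(kseed % 2**31))
        for spec in spectra:
            records = score_spectrum(spec, db, config)
            if not records:
                continue
            true_seq = truth.get(spec.spectrum_id) if truth else None
            target = find_target_record(records, true_seq)
            if target is None:
                warnings.warn(
                    f"spectrum {spec.spectrum_id!r}: no target record within tolerance"
                )
                continue
            for res in spectrum_pvalues(records, target, config, indicators):
                rows.append(
                    {
                        "k": int(k),
                        "spectrum_id": res.spectrum_id,
                        "indicator": res.indicator,
                        "target_score": res.target_score,
                        "n_candidates_collapsed": res.n_candidates_collapsed,
                        "n_equal_or_better": res.n_equal_or_better,
                        "p_value": res.p_value,
                        "t_level": res.t_level,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "k", "spectrum_id", "indicator", "target_score",
            "n_candidates_collapsed", "n_equal_or_better", "p_value", "t_level",
        ],
    )


def significance_histogram(results: pd.DataFrame, indicator: str) -> pd.DataFrame:
    """Counts of spectra per significance level t (the '>=6' levels pooled),
    with cumulative counts at the 1e-2 and 1e-4 thresholds, per k."""
    sub = results[results["indicator"] == indicator]
    rows = []
    for k, grp in sub.groupby("k"):
        counts = {f"t{t}": 0 for t in range(MAX_T_LEVEL)}
        counts["t6plus"] = 0
        for t in grp["t_level"]:
            if t < 0:
                continue
            counts["t6plus" if t >= MAX_T_LEVEL else f"t{t}"] += 1
        p = grp["p_value"]
        rows.append(
            {
                "k": k,
                "indicator": indicator,
                **counts,
                "cum_1e-2": int((p < 1e-2).sum()),
                "cum_1e-4": int((p < 1e-4).sum()),
                "total": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)
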