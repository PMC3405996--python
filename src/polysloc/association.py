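"""Association statistics between marker distributions and population
structure, plus the small categorical utilities of the survey workflow:
contingency tables with the heterozygote/non-carrier exclusion rule,
Cramér's V, Fisher's exact test, per-subgenome marker frequencies, the
Evanno ΔK summary of Bayesian-clustering log-likelihoods, and
compatibility scoring of pollination assays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

#: Enumeration guard for exact r x c Fisher tests.
MAX_ENUMERATED_TABLES = 10_000_000


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    excluded: int = 0  # accessions dropped by the exclusion rule

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def drop_empty(self) -> "ContingencyTable":
        """Drop all-zero rows and columns (warning if any were dropped)."""
        rk = self.row_margins > 0
        ck = self.col_margins > 0
        if not rk.all() or not ck.all():
            warnings.warn("dropping empty rows/columns from contingency table")
        return ContingencyTable(
            [r for r, keep in zip(self.row_labels, rk) if keep],
            [c for c, keep in zip(self.col_labels, ck) if keep],
            self.counts[np.ix_(rk, ck)],
            excluded=self.excluded,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class AssociationResult:
    V: float
    chi2: float
    p_value: float
    test: str  # "fisher_exact" | "chi2"
    table: ContingencyTable


def build_contingency(
    panel: pd.DataFrame,
    markers: Sequence[str],
    clusters: Mapping[str, str] | None = None,
) -> ContingencyTable:
    """Marker-by-cluster contingency table with the survey exclusion rule.

    ``panel`` needs columns ``accession`` and ``markers`` (list of marker
    symbols per accession, or a ";"-separated string) and, unless a
    separate ``clusters`` mapping is given, a ``cluster`` column.
    Accessions carrying two or more of the queried markers (heterozygotes)
    or none of them are excluded; the exclusion count is recorded on the
    returned table.
    """
    markers = list(markers)
    if clusters is None:
        clusters = dict(zip(panel["accession"], panel["cluster"]))
    cluster_labels = sorted(set(clusters.values()))
    counts = np.zeros((len(markers), len(cluster_labels)), dtype=np.int64)
    excluded = 0
    for _, row in panel.iterrows():
        acc = row["accession"]
        if acc not in clusters:
            raise ValueError(f"accession {acc!r} missing from cluster table")
        carried = row["markers"]
        if isinstance(carried, str):
            carried = [m for m in carried.split(";") if m]
        hits = [m for m in markers if m in carried]
        if len(hits) != 1:
            excluded += 1
            continue
        counts[markers.index(hits[0]),
               cluster_labels.index(clusters[acc])] += 1
    if counts.sum() == 0:
        raise ValueError("contingency table empty after exclusions")
    return ContingencyTable(markers, cluster_labels, counts, excluded=excluded)


def cramers_v(table: ContingencyTable) -> AssociationResult:
    """Cramér's V with significance from Fisher's exact test.

    ``V = sqrt(chi2 / (n (min(r, c) - 1)))`` with the Pearson chi-square
    of independence (no continuity correction). Degenerate all-zero rows
    or columns are dropped with a warning before computing.
    """
    t = table.drop_empty()
    r, c = t.counts.shape
    if t.n == 0:
        raise ValueError("empty table")
    if r < 2 or c < 2:
        raise ValueError("need at least a 2x2 table after dropping empties")
    chi2, _, _, _ = chi2_contingency(t.counts, correction=False)
    v = math.sqrt(chi2 / (t.n * (min(r, c) - 1)))
    _, p_two = fisher_exact(t)
    return AssociationResult(V=v, chi2=float(chi2), p_value=p_two,
                             test="fisher_exact", table=t)


def _log_factorials(n: int) -> np.ndarray:
    out = np.zeros(n + 1)
    out[1:] = np.cumsum(np.log(np.arange(1, n + 1)))
    return out


def _table_log_prob(counts: np.ndarray, lf: np.ndarray) -> float:
    n = counts.sum()
    return (lf[counts.sum(axis=1)].sum() + lf[counts.sum(axis=0)].sum()
            - lf[n] - lf[counts.ravel()].sum())


def _enumerate_tables(row_margins, col_margins):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(row_margins), len(col_margins)

    def rec(row_idx, remaining_cols, acc):
        if row_idx == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                yield np.vstack(acc + [last])
            return
        target = row_margins[row_idx]

        def fill(col_idx, left, row_acc):
            if col_idx == c - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    yield row_acc + [left]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from fill(col_idx + 1, left - v, row_acc + [v])

        for row in fill(0, target, []):
            new_cols = [rc - v for rc, v in zip(remaining_cols, row)]
            yield from rec(row_idx + 1, new_cols, acc + [np.asarray(row)])

    yield from rec(0, list(col_margins), [])


def fisher_exact(
    table: ContingencyTable,
    monte_carlo: bool = False,
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> tuple[float | None, float]:
    """Fisher's exact test of independence with fixed margins.

    For 2x2 tables the one-tailed p is the hypergeometric tail in the
    direction of the observed deviation and the two-tailed p sums the
    probabilities of all tables no more probable than the observed one
    (relative tolerance 1e-7). For larger tables the two-tailed
    probability-mass test is computed by total enumeration when at most
    ``MAX_ENUMERATED_TABLES`` tables share the margins (estimated by an
    upper bound), otherwise Monte Carlo resampling must be requested
    explicitly; the one-tailed p is undefined (``None``) beyond 2x2.

    Returns ``(p_one_tailed, p_two_tailed)``.
    """
    counts = table.counts
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty table")
    lf = _log_factorials(n)
    obs_lp = _table_log_prob(counts, lf)
    cutoff = obs_lp + math.log1p(1e-7)

    if counts.shape == (2, 2):
        a = int(counts[0, 0])
        r1 = int(counts[0].sum())
        c1 = int(counts[:, 0].sum())
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        probs = {}
        for x in range(lo, hi + 1):
            t = np.array([[x, r1 - x], [c1 - x, n - r1 - c1 + x]])
            probs[x] = _table_log_prob(t, lf)
        expected = r1 * c1 / n
        if a >= expected:
            one = sum(math.exp(lp) for x, lp in probs.items() if x >= a)
        else:
            one = sum(math.exp(lp) for x, lp in probs.items() if x <= a)
        two = sum(math.exp(lp) for lp in probs.values() if lp <= cutoff)
        return min(one, 1.0), min(two, 1.0)

    row_m = [int(x) for x in table.row_margins]
    col_m = [int(x) for x in table.col_margins]
    # upper bound on the number of tables with these margins
    bound = 1.0
    for rm in row_m[:-1]:
        bound *= math.comb(rm + len(col_m) - 1, len(col_m) - 1)
    if bound > MAX_ENUMERATED_TABLES and not monte_carlo:
        raise ValueError(
            "table too large for exact enumeration; pass monte_carlo=True"
        )
    if monte_carlo:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_resamples):
            t = _random_table(row_m, col_m, rng)
            if _table_log_prob(t, lf) <= cutoff:
                hits += 1
        return None, (hits + 1) / (n_resamples + 1)
    two = 0.0
    for t in _enumerate_tables(row_m, col_m):
        lp = _table_log_prob(t, lf)
        if lp <= cutoff:
            two += math.exp(lp)
    return None, min(two, 1.0)


def _random_table(row_m, col_m, rng) -> np.ndarray:
    """Random table with fixed margins via permutation of unit assignments."""
    rows = np.repeat(np.arange(len(row_m)), row_m)
    cols = np.repeat(np.arange(len(col_m)), col_m)
    rng.shuffle(cols)
    t = np.zeros((len(row_m), len(col_m)), dtype=np.int64)
    np.add.at(t, (rows, cols), 1)
    return t


# ---------------------------------------------------------------------------
# Marker frequencies over subgenome slots
# ---------------------------------------------------------------------------

def marker_frequencies(
    panel: pd.DataFrame,
    subgenome_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-marker allele frequencies over the 2N slots of each subgenome.

    Each accession contributes two allele slots per subgenome (the
    allotetraploid is diploid within each subgenome). An accession
    carrying a single queried marker on a subgenome is taken as homozygous
    there (2 slots); one carrying two markers on the same subgenome is a
    heterozygote (1 slot each).

    Returns a DataFrame with columns ``marker, subgenome, slots,
    total_slots, frequency`` (frequency in percent).
    """
    if panel.empty:
        raise ValueError("empty panel")
    subgenomes = sorted(set(subgenome_of.values()))
    n_acc = len(panel)
    slots = {m: 0 for m in subgenome_of}
    for carried in panel["markers"]:
        if isinstance(carried, str):
            carried = [m for m in carried.split(";") if m]
        by_sub: dict[str, list[str]] = {s: [] for s in subgenomes}
        for m in carried:
            if m in subgenome_of:
                by_sub[subgenome_of[m]].append(m)
        for s, ms in by_sub.items():
            if len(ms) == 1:
                slots[ms[0]] += 2
            else:
                for m in ms:
                    slots[m] += 1
    rows = []
    for m in subgenome_of:
        total = 2 * n_acc
        rows.append({
            "marker": m,
            "subgenome": subgenome_of[m],
            "slots": slots[m],
            "total_slots": total,
            "frequency": 100.0 * slots[m] / total,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def delta_k(runs: Mapping[int, Sequence[float]]) -> pd.DataFrame:
    """Evanno ΔK from per-K log-likelihoods across replicate runs.

    ``runs`` maps each K to the ln P(X|K) values of its independent runs.
    For interior K: ``L'(K) = mean L(K) - mean L(K-1)``,
    ``|L''(K)| = |L'(K+1) - L'(K)|`` and ``ΔK = |L''(K)| / sd(L(K))``
    with the sample (n-1) standard deviation. ΔK is NaN (flagged) where
    the sd is zero and undefined at the boundary K values.
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[0] + len(ks))):
        raise ValueError("need at least 3 consecutive K values")
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError(f"K={k}: need at least 2 runs for sd")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    lp = {k: mean[k] - mean[k - 1] for k in ks[1:]}
    rows = []
    for k in ks:
        lpp = abs(lp[k + 1] - lp[k]) if k in lp and (k + 1) in lp else None
        dk = None
        flagged = False
        if lpp is not None:
            if sd[k] == 0:
                flagged = True
            else:
                dk = lpp / sd[k]
        rows.append({
            "K": k, "mean_lnP": mean[k], "sd_lnP": sd[k],
            "Lprime": lp.get(k), "abs_Lsecond": lpp,
            "deltaK": dk, "sd_zero": flagged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pollination assay scoring
# ---------------------------------------------------------------------------

def score_cross(
    pollen_tubes: int | None = None,
    silique_mm: float | None = None,
    stringent: bool = False,
) -> str:
    """Score a cross as compatible or incompatible.

    Fewer than 20 penetrating pollen tubes (10 with ``stringent=True``)
    marks an incompatible cross; compatible crosses typically show >100.
    Where pollen tubes were not assessed, a silique shorter than 5 mm
    marks incompatibility. Exactly one measurement must be supplied; the
    boundary values (exactly 20 tubes / 5 mm) count as compatible.
    """
    if (pollen_tubes is None) == (silique_mm is None):
        raise ValueError("supply exactly one of pollen_tubes or silique_mm")
    if pollen_tubes is not None:
        if pollen_tubes < 0:
            raise ValueError("negative pollen tube count")
        threshold = 10 if stringent else 20
        return "incompatible" if pollen_tubes < threshold else "compatible"
    if silique_mm < 0:
        raise ValueError("negative silique length")
    return "incompatible" if silique_mm < 5.0 else "compatible"
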