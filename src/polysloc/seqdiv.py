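"""Pairwise and group nucleotide-distance estimation.

Implements the classical distance estimators used to quantify divergence
between S-locus haplogroups and between homeologs and their parental
orthologs:

* uncorrected proportion of differing sites (p-distance), with the
  transition/transversion split,
* the Jukes–Cantor multiple-hit correction with its analytic standard
  error,
* the Kimura two-parameter correction,
* Nei–Gojobori synonymous/nonsynonymous divergence with equal-weight
  averaging over minimal substitution pathways,
* between-group mean divergence with analytic or site-bootstrap standard
  errors.

Gap and ambiguity handling is pairwise deletion by default: a site is
compared only when both sequences carry an unambiguous base. Complete
deletion (drop a column if *any* sequence in the alignment has a gap or
ambiguity there) is available where the full alignment is in hand.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .alignment import VALID_BASES, Alignment

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Standard genetic code, DNA alphabet. ``*`` marks stop codons.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = tuple(c for c, aa in CODON_TABLE.items() if aa != "*")


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the estimator's domain."""


@dataclass
class DistanceEstimate:
    """A pairwise distance with its raw proportions and precision.

    Attributes
    ----------
    p
        Proportion of differing compared sites (``p = P + Q``).
    P, Q
        Transition and transversion proportions.
    d
        Corrected distance in substitutions per site (``None`` until a
        correction has been applied).
    SE
        Standard error of ``d`` where an analytic formula exists.
    L
        Number of compared sites.
    """

    p: float
    P: float
    Q: float
    L: int
    d: float | None = None
    SE: float | None = None
    method: str = "p"


@dataclass
class KaKsEstimate:
    """Nei–Gojobori synonymous/nonsynonymous divergence for a codon pair.

    ``S_sites + N_sites`` always equals three times the codon count;
    ``Ks``/``Ka`` are ``None`` (with ``saturated=True``) when the raw
    proportion reaches the Jukes–Cantor saturation bound of 3/4.
    """

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    Ks: float | None
    Ka: float | None
    saturated: bool = False


def p_distance(
    a: str,
    b: str,
    deletion: Literal["pairwise", "complete"] = "pairwise",
    columns: Sequence[int] | None = None,
) -> DistanceEstimate:
    """Uncorrected pairwise distance with transition/transversion split.

    Parameters
    ----------
    a, b
        Equal-length aligned sequences.
    deletion
        ``"pairwise"`` skips sites where either sequence has a gap or
        ambiguous base. ``"complete"`` requires ``columns``: the columns
        retained after complete deletion across the whole alignment (see
        :meth:`polysloc.alignment.Alignment.comparable_columns`).
    columns
        Restrict the comparison to these column indices.

    Raises
    ------
    ValueError
        If the sequences differ in length or no comparable sites remain.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    if deletion == "complete" and columns is None:
        raise ValueError(
            "complete deletion requires the retained columns of the full "
            "alignment; pass columns=alignment.comparable_columns()"
        )
    idx = range(len(a)) if columns is None else columns
    L = 0
    ts = tv = 0
    for j in idx:
        x, y = a[j], b[j]
        if x not in VALID_BASES or y not in VALID_BASES:
            continue
        L += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if L == 0:
        raise ValueError("no comparable sites")
    return DistanceEstimate(
        p=(ts + tv) / L, P=ts / L, Q=tv / L, L=L, method="p"
    )


def jukes_cantor(p: float, L: int) -> DistanceEstimate:
    """Jukes–Cantor corrected distance d = -(3/4) ln(1 - 4p/3).

    The standard error follows the delta method:
    ``SE = sqrt(p(1-p) / (L (1 - 4p/3)^2))``.

    Raises
    ------
    SaturationError
        If ``p >= 0.75``, where the correction is undefined.
    """
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"saturated: p={p} outside [0, 0.75)")
    w = 1.0 - 4.0 * p / 3.0
    d = -0.75 * math.log(w) if p > 0 else 0.0
    se = math.sqrt(p * (1.0 - p) / (L * w * w)) if L > 0 else float("nan")
    return DistanceEstimate(p=p, P=float("nan"), Q=float("nan"), L=L,
                            d=d, SE=se, method="JC")


def kimura_2p(P: float, Q: float) -> DistanceEstimate:
    """Kimura two-parameter distance from transition/transversion
    proportions: ``d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)``.

    Raises
    ------
    SaturationError
        If either logarithm argument is non-positive.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated: P={P}, Q={Q}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceEstimate(p=P + Q, P=P, Q=Q, L=0, d=d, method="K2P")


def corrected_distance(a: str, b: str, method: str = "JC",
                       columns: Sequence[int] | None = None) -> DistanceEstimate:
    """Pairwise distance under ``method`` in {"p", "JC", "K2P"}."""
    est = p_distance(a, b, columns=columns)
    if method == "p":
        est.d = est.p
        return est
    if method == "JC":
        out = jukes_cantor(est.p, est.L)
        out.P, out.Q = est.P, est.Q
        return out
    if method == "K2P":
        out = kimura_2p(est.P, est.Q)
        out.L = est.L
        return out
    raise ValueError(f"unknown distance method: {method!r}")


# ---------------------------------------------------------------------------
# Nei–Gojobori synonymous / nonsynonymous divergence
# ---------------------------------------------------------------------------

def _codon_syn_sites(codon: str) -> float:
    """Fraction of the codon's 3 sites that are synonymous.

    At each position, each of the three possible nucleotide changes counts
    1/3 of a site; a change is synonymous when it yields a sense codon for
    the same amino acid. Changes to stop codons count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:
                s += 1.0 / 3.0
    return s


def _count_path(path: list[str]) -> tuple[float, float]:
    """Synonymous/nonsynonymous step counts along one substitution path."""
    sd = nd = 0.0
    for c1, c2 in zip(path, path[1:]):
        if CODON_TABLE[c1] == CODON_TABLE[c2]:
            sd += 1.0
        else:
            nd += 1.0
    return sd, nd


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average Sd/Nd between two codons over all minimal substitution
    pathways, weighting pathways equally and excluding those that pass
    through a stop codon. If every pathway hits a stop, all pathways are
    used (the divergence still has to be scored somehow; such codon pairs
    are vanishingly rare in real coding sequence)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        path = [c1]
        cur = c1
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1:]
            path.append(cur)
        counts = _count_path(path)
        fallback.append(counts)
        # endpoints are checked by the caller; only intermediates matter here
        if all(CODON_TABLE[c] != "*" for c in path[1:-1]):
            valid.append(counts)
    paths = valid or fallback
    sd = sum(x[0] for x in paths) / len(paths)
    nd = sum(x[1] for x in paths) / len(paths)
    return sd, nd


def nei_gojobori(a: str, b: str) -> KaKsEstimate:
    """Nei–Gojobori (1986) synonymous and nonsynonymous divergence.

    Site counts are averaged between the two sequences; multi-difference
    codons are scored by equal-weight averaging over minimal substitution
    pathways (stop-codon intermediates excluded). ``Ks`` and ``Ka`` apply
    the Jukes–Cantor correction to ``Sd/S_sites`` and ``Nd/N_sites``.

    Codons containing gaps or ambiguous bases in either sequence are
    skipped entirely (pairwise deletion at codon resolution).
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i:i + 3], b[i:i + 3]
        if any(ch not in VALID_BASES for ch in c1 + c2):
            continue
        if CODON_TABLE[c1] == "*" or CODON_TABLE[c2] == "*":
            raise ValueError(f"internal stop codon at position {i + 1}")
        n_codons += 1
        s_a += _codon_syn_sites(c1)
        s_b += _codon_syn_sites(c2)
        dsd, dnd = _codon_differences(c1, c2)
        sd += dsd
        nd += dnd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    ks = jukes_cantor(ps, n_codons).d if ps < 0.75 else None
    ka = jukes_cantor(pn, n_codons).d if pn < 0.75 else None
    return KaKsEstimate(S_sites=s_sites, N_sites=n_sites, Sd=sd, Nd=nd,
                        Ks=ks, Ka=ka, saturated=saturated)


# ---------------------------------------------------------------------------
# Group means
# ---------------------------------------------------------------------------

def group_mean_divergence(
    set_a: Alignment,
    set_b: Alignment,
    method: str = "JC",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, list[tuple[str, str]]]:
    """Mean corrected distance between two sequence sets.

    Averages all between-set pairwise distances. The standard error is the
    analytic per-pair formula when both sets are singletons; otherwise it
    is a nonparametric bootstrap over alignment sites (columns resampled
    with replacement, ``n_bootstrap`` replicates).

    Returns
    -------
    (mean_d, SE, excluded)
        ``excluded`` lists saturated pairs that were dropped from the mean.
    """
    if set_a.n_sequences == 0 or set_b.n_sequences == 0:
        raise ValueError("both sets must be non-empty")
    pairs = [(la, lb) for la in set_a.labels for lb in set_b.labels]

    def mean_over_pairs(get_seq_a, get_seq_b) -> tuple[float, list]:
        vals, excluded = [], []
        for la, lb in pairs:
            try:
                vals.append(
                    corrected_distance(get_seq_a(la), get_seq_b(lb), method).d
                )
            except SaturationError:
                excluded.append((la, lb))
        if not vals:
            raise SaturationError("all pairs saturated")
        return float(np.mean(vals)), excluded

    mean_d, excluded = mean_over_pairs(set_a.sequence, set_b.sequence)

    if set_a.n_sequences == 1 and set_b.n_sequences == 1 and not excluded:
        est = corrected_distance(
            set_a.rows[0], set_b.rows[0], method
        )
        se = est.SE if est.SE is not None else float("nan")
        return mean_d, se, excluded

    rng = np.random.default_rng(seed)
    L = set_a.length
    rows_a = {lab: np.frombuffer(set_a.sequence(lab).encode(), dtype="S1")
              for lab in set_a.labels}
    rows_b = {lab: np.frombuffer(set_b.sequence(lab).encode(), dtype="S1")
              for lab in set_b.labels}
    reps = []
    for _ in range(n_bootstrap):
        cols = rng.integers(0, L, size=L)
        vals = []
        for la, lb in pairs:
            sa = rows_a[la][cols].tobytes().decode()
            sb = rows_b[lb][cols].tobytes().decode()
            try:
                vals.append(corrected_distance(sa, sb, method).d)
            except (SaturationError, ValueError):
                continue
        if vals:
            reps.append(np.mean(vals))
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else float("nan")
    return mean_d, se, excluded


def identity_percent(a: str, b: str) -> float:
    """Percent identity over compared sites, ``(1 - p) * 100``."""
    return (1.0 - p_distance(a, b).p) * 100.0
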