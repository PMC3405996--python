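"""Exact F2 segregation distributions under allopolyploid inheritance models.

An allotetraploid carries four copies of each chromosome. Two dominant
PCR markers (presence/absence scored) segregating in an F2 can sit either
on homologous copies of one locus (allelic) or on two independent loci
(nonallelic), and each locus can pair strictly within its subgenome
(disomic — behaves as a diploid locus) or across all four copies
(tetrasomic — a gamete receives a random pair of the four copies; random
chromosome segregation, no double reduction).

All gamete and F2 class probabilities are computed as exact rationals by
enumeration, then compared to observed counts with a Pearson chi-square
goodness-of-fit test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from scipy.stats import chi2 as chi2_dist

#: Symbol for a null (marker-absent) allele.
NULL = "-"

ClassKey = tuple[bool, bool]  # (first marker present, second marker present)


def class_labels(markers: Sequence[str]) -> dict[ClassKey, str]:
    m1, m2 = markers
    return {
        (True, True): f"{m1}/{m2}",
        (True, False): f"{m1}/{NULL}",
        (False, True): f"{NULL}/{m2}",
        (False, False): f"{NULL}/{NULL}",
    }


#: Canonical class order: both, first only, second only, neither.
CLASS_ORDER: tuple[ClassKey, ...] = (
    (True, True), (True, False), (False, True), (False, False)
)


@dataclass(frozen=True)
class LocusSpec:
    """One locus of the F1 parent.

    ``mode`` is ``"disomic"`` (two allele copies, gamete gets one) or
    ``"tetrasomic"`` (four copies, gamete gets an unordered pair).
    ``f1_genotype`` lists the allele copies, ``"-"`` denoting a null.
    """

    mode: str
    f1_genotype: tuple[str, ...]

    def __post_init__(self):
        expected = {"disomic": 2, "tetrasomic": 4}.get(self.mode)
        if expected is None:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.f1_genotype) != expected:
            raise ValueError(
                f"{self.mode} locus needs {expected} allele copies, "
                f"got {len(self.f1_genotype)}"
            )


@dataclass(frozen=True)
class SegregationModel:
    """A named inheritance model: loci plus the scored markers."""

    name: str
    loci: tuple[LocusSpec, ...]
    markers: tuple[str, str]

    def __post_init__(self):
        for m in self.markers:
            hits = sum(m in locus.f1_genotype for locus in self.loci)
            if hits != 1:
                raise ValueError(
                    f"marker {m!r} must appear in exactly one locus "
                    f"(found in {hits})"
                )


def gametes(locus: LocusSpec) -> dict[tuple[str, ...], Fraction]:
    """Exact gamete distribution of one locus.

    Disomic: each of the two copies with probability 1/2 (gamete carries a
    single allele). Tetrasomic: each unordered pair of the four copies with
    probability 1/6 — random chromosome segregation without double
    reduction. Gametes with identical allele content are merged.
    """
    dist: dict[tuple[str, ...], Fraction] = {}
    if locus.mode == "disomic":
        for allele in locus.f1_genotype:
            key = (allele,)
            dist[key] = dist.get(key, Fraction(0)) + Fraction(1, 2)
    else:
        for i, j in itertools.combinations(range(4), 2):
            key = tuple(sorted((locus.f1_genotype[i], locus.f1_genotype[j])))
            dist[key] = dist.get(key, Fraction(0)) + Fraction(1, 6)
    assert sum(dist.values()) == 1
    return dist


def f2_class_distribution(model: SegregationModel) -> dict[ClassKey, Fraction]:
    """Exact F2 presence/absence class distribution.

    An F2 genotype is the union of two independent gametes at every locus;
    a marker is "present" when it occurs in at least one of the two gametes
    at its locus. Loci segregate independently, so per-marker presence
    probabilities at distinct loci multiply; markers at the same locus are
    handled jointly through the gamete pair enumeration.
    """
    # per locus: joint distribution over (marker1 present, marker2 present)
    # restricted to the markers that live on that locus
    per_locus: list[dict[tuple[bool, ...], Fraction]] = []
    locus_markers: list[list[int]] = []
    for locus in model.loci:
        mk = [k for k, m in enumerate(model.markers) if m in locus.f1_genotype]
        locus_markers.append(mk)
        gd = gametes(locus)
        joint: dict[tuple[bool, ...], Fraction] = {}
        for g1, p1 in gd.items():
            for g2, p2 in gd.items():
                present = tuple(
                    (model.markers[k] in g1) or (model.markers[k] in g2)
                    for k in mk
                )
                joint[present] = joint.get(present, Fraction(0)) + p1 * p2
        per_locus.append(joint)

    dist: dict[ClassKey, Fraction] = {key: Fraction(0) for key in CLASS_ORDER}
    for combo in itertools.product(*[d.items() for d in per_locus]):
        presence = [False, False]
        prob = Fraction(1)
        for (pattern, p), mk in zip(combo, locus_markers):
            prob *= p
            for flag, k in zip(pattern, mk):
                presence[k] = presence[k] or flag
        dist[(presence[0], presence[1])] += prob
    assert sum(dist.values()) == 1
    return dist


# ---------------------------------------------------------------------------
# Model presets: the unique simple F1 genotypes consistent with two dominant
# markers under each pairing/allelism hypothesis.
# ---------------------------------------------------------------------------

def preset_models(markers: tuple[str, str] = ("A", "B")) -> dict[str, SegregationModel]:
    m1, m2 = markers
    return {
        "disomic_allelic": SegregationModel(
            "disomic_allelic",
            (LocusSpec("disomic", (m1, m2)),),
            markers,
        ),
        "disomic_nonallelic": SegregationModel(
            "disomic_nonallelic",
            (LocusSpec("disomic", (m1, NULL)), LocusSpec("disomic", (m2, NULL))),
            markers,
        ),
        "tetrasomic_allelic": SegregationModel(
            "tetrasomic_allelic",
            (LocusSpec("tetrasomic", (m1, m1, m2, m2)),),
            markers,
        ),
        "tetrasomic_nonallelic": SegregationModel(
            "tetrasomic_nonallelic",
            (
                LocusSpec("tetrasomic", (m1, m1, NULL, NULL)),
                LocusSpec("tetrasomic", (m2, m2, NULL, NULL)),
            ),
            markers,
        ),
    }


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class GofResult:
    """Pearson chi-square goodness-of-fit of observed F2 counts to a model.

    ``rejected_impossible`` is set when a structurally impossible class
    (expected probability exactly 0) was observed; the statistic is then
    infinite and the p-value 0.
    """

    model: str
    observed: tuple[int, ...]
    n: int
    expected: tuple[float, ...]
    probabilities: tuple[Fraction, ...]
    chi2: float
    df: int
    p_value: float
    rejected_impossible: bool = False


def chisq_gof(
    observed: Sequence[int],
    dist: Mapping[ClassKey, Fraction],
    model_name: str = "",
) -> GofResult:
    """Pearson goodness-of-fit against exact class probabilities.

    Expected counts are ``N * p_i`` from the exact rationals, never from
    rounded values. Classes with zero probability contribute nothing to the
    statistic and are excluded from the degrees of freedom
    (``df = #{p_i > 0} - 1``); observing a count in such a class rejects
    the model outright (chi-square infinite). No continuity correction.
    """
    obs = tuple(int(x) for x in observed)
    if len(obs) != len(CLASS_ORDER):
        raise ValueError(f"expected {len(CLASS_ORDER)} class counts")
    if any(x < 0 for x in obs):
        raise ValueError("negative counts")
    n = sum(obs)
    if n == 0:
        raise ValueError("no observations (N=0)")
    probs = tuple(dist[key] for key in CLASS_ORDER)
    expected = tuple(float(n * p) for p in probs)
    rejected = any(o > 0 and p == 0 for o, p in zip(obs, probs))
    positive = [i for i, p in enumerate(probs) if p > 0]
    df = len(positive) - 1
    if rejected:
        return GofResult(model_name, obs, n, expected, probs,
                         float("inf"), df, 0.0, rejected_impossible=True)
    stat = 0.0
    for i in positive:
        e = n * probs[i]
        stat += float((obs[i] - e) ** 2 / e)
    p_value = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return GofResult(model_name, obs, n, expected, probs, stat, df, p_value)


def compare_models(
    observed: Sequence[int],
    models: Mapping[str, SegregationModel] | None = None,
) -> list[GofResult]:
    """Fit every model to the observed counts, ranked by descending p-value.

    The first entry is the best-supported model. Ties in p-value (both 0,
    say) fall back to ascending chi-square.
    """
    if models is None:
        models = preset_models()
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    results = [
        chisq_gof(observed, f2_class_distribution(m), name)
        for name, m in models.items()
    ]
    results.sort(key=lambda r: (-r.p_value, r.chi2))
    return results
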