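"""Synthetic data with the statistical structure the analyses assume.

Three generators make the whole pipeline testable without external data:

* a sequence panel of deeply diverged haplogroups (near-identical within a
  haplogroup, ~91% identity between haplogroups), evolved by a
  Jukes–Cantor substitution process on a star genealogy of haplogroup
  founders — the matched process for the JC estimator, so
  parameter-recovery tests are exact in expectation;
* an allotetraploid accession panel in which every accession carries one
  marker per homeologous subgenome (rare heterozygotes carry two on one
  subgenome), with marker frequencies depending on the population cluster;
* F2 populations drawn gamete-by-gamete from any of the four inheritance
  models, so observed class counts converge to the exact distributions of
  :mod:`polysloc.inheritance`.

All generators are deterministic under a fixed seed (one seeded generator
per invocation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .alignment import Alignment
from .inheritance import (CLASS_ORDER, SegregationModel, class_labels,
                          gametes)

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Default cluster specification: two population clusters with strongly
#: differentiated subgenome-1 markers (A southwestern, B/C north-eastern)
#: and a near-fixed subgenome-2 marker D — mirroring a two-cluster survey
#: of ~50 allotetraploid accessions.
DEFAULT_CLUSTER_SPEC: dict[str, dict[str, dict[str, float]]] = {
    "cluster1": {
        "sub1": {"A": 1.0, "B": 0.0, "C": 0.0},
        "sub2": {"D": 0.95, "E": 0.05},
    },
    "cluster2": {
        "sub1": {"A": 0.0, "B": 0.85, "C": 0.15},
        "sub2": {"D": 0.9, "E": 0.1},
    },
}


@dataclass
class SimulationConfig:
    """Study-shaped defaults for all three generators.

    Divergences are in substitutions/site (true branch-path lengths of the
    substitution process, not raw p-distances). Defaults emulate the
    surveyed panel: five haplogroups at ~0.09 between-group divergence
    (≈91% identity) with ≤0.005 within-group divergence (>99% identity),
    49 accessions in two clusters, a single rare heterozygote expected per
    panel, and an F2 family of 95 under the disomic-allelic model.
    """

    n_haplogroups: int = 5
    seqs_per_haplogroup: int = 3
    seq_length: int = 600
    between_divergence: float = 0.09
    within_divergence: float = 0.005
    n_accessions: int = 49
    cluster_spec: dict = field(
        default_factory=lambda: {k: {s: dict(v) for s, v in sub.items()}
                                 for k, sub in DEFAULT_CLUSTER_SPEC.items()})
    heterozygote_rate: float = 0.02
    heterozygote_subgenome: str = "sub1"
    f2_model: str = "disomic_allelic"
    f2_n: int = 95
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.heterozygote_rate <= 1:
            raise ValueError("heterozygote_rate must be in [0, 1]")
        for cl, sub in self.cluster_spec.items():
            for s, freqs in sub.items():
                if not freqs:
                    raise ValueError(f"empty frequency vector for {cl}/{s}")
                total = sum(freqs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"frequencies for {cl}/{s} sum to {total}, not 1")
                if any(p < 0 for p in freqs.values()):
                    raise ValueError("negative frequency")

    def subgenome_of(self) -> dict[str, str]:
        """Marker -> subgenome mapping implied by the cluster spec."""
        out: dict[str, str] = {}
        for sub in self.cluster_spec.values():
            for s, freqs in sub.items():
                for m in freqs:
                    out[m] = s
        return out


def _expected_p(d: float) -> float:
    """Expected p-distance after d substitutions/site under Jukes–Cantor."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _evolve(seq: np.ndarray, branch: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence along a branch under the Jukes–Cantor process:
    each site substitutes with probability 3/4 (1 - exp(-4t/3)), uniformly
    to one of the three other bases."""
    p = _expected_p(branch)
    out = seq.copy()
    hit = rng.random(seq.size) < p
    idx = np.nonzero(hit)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        cur = np.searchsorted(BASES, out[idx])
        out[idx] = BASES[(cur + shift) % 4]
    return out


def simulate_haplogroup_sequences(config: SimulationConfig) -> Alignment:
    """Aligned sequence panel of diverged haplogroups on a star genealogy.

    Founders sit at the tips of a star of branch length
    ``(between - within)/2`` from a random ancestor, so two sequences from
    different haplogroups are separated by a total path of
    ``between_divergence`` substitutions/site; each sequence then evolves
    ``within_divergence / 2`` from its founder, giving within-group paths
    of ``within_divergence``. Labels are ``H{g}_s{i}``: the haplogroup is
    recoverable from the prefix before the underscore.
    """
    cfg = config
    if cfg.seq_length <= 0:
        raise ValueError("seq_length must be positive")
    if not cfg.between_divergence > cfg.within_divergence >= 0:
        raise ValueError("require between_divergence > within_divergence >= 0")
    if _expected_p(cfg.between_divergence) >= 0.75:
        raise ValueError(
            "requested divergence implies an expected p-distance >= 0.75; "
            "distance corrections are undefined there"
        )
    rng = np.random.default_rng(cfg.seed)
    ancestor = BASES[rng.integers(0, 4, size=cfg.seq_length)]
    founder_branch = 0.5 * (cfg.between_divergence - cfg.within_divergence)
    tip_branch = 0.5 * cfg.within_divergence
    labels, rows = [], []
    for g in range(1, cfg.n_haplogroups + 1):
        founder = _evolve(ancestor, founder_branch, rng)
        for i in range(1, cfg.seqs_per_haplogroup + 1):
            tip = _evolve(founder, tip_branch, rng)
            labels.append(f"H{g}_s{i}")
            rows.append(tip.tobytes().decode())
    return Alignment(labels, rows)


def haplogroup_of(label: str) -> str:
    """Haplogroup prefix of a simulated sequence label (``H2_s1`` -> ``H2``)."""
    return label.split("_")[0]


def simulate_panel(config: SimulationConfig) -> pd.DataFrame:
    """Allotetraploid accession panel with cluster-correlated markers.

    Each accession is assigned a cluster (uniformly among the cluster
    spec's labels) and draws one marker per subgenome from that cluster's
    frequency vector; with probability ``heterozygote_rate`` it carries a
    second, different marker on ``heterozygote_subgenome`` (when that
    subgenome segregates more than one marker in its cluster).

    Returns a DataFrame with columns ``accession, cluster, markers``
    (markers as a list of symbols).
    """
    cfg = config
    if not cfg.cluster_spec:
        raise ValueError("cluster_spec must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    cluster_labels = sorted(cfg.cluster_spec)
    rows = []
    for i in range(1, cfg.n_accessions + 1):
        cl = cluster_labels[rng.integers(0, len(cluster_labels))]
        carried: list[str] = []
        for sub in sorted(cfg.cluster_spec[cl]):
            freqs = cfg.cluster_spec[cl][sub]
            names = sorted(freqs)
            probs = np.array([freqs[m] for m in names])
            first = names[rng.choice(len(names), p=probs)]
            carried.append(first)
            if (sub == cfg.heterozygote_subgenome
                    and rng.random() < cfg.heterozygote_rate):
                others = [m for m in names if m != first and freqs[m] > 0]
                if others:
                    oprobs = np.array([freqs[m] for m in others])
                    oprobs = oprobs / oprobs.sum()
                    carried.append(others[rng.choice(len(others), p=oprobs)])
        rows.append({"accession": f"acc{i:03d}", "cluster": cl,
                     "markers": carried})
    return pd.DataFrame(rows)


def simulate_f2(
    model: SegregationModel,
    n: int,
    seed: int | None = None,
) -> dict[str, int]:
    """Draw an F2 population of size ``n`` under an inheritance model.

    Each individual unites two gametes sampled independently from the F1
    gamete distribution of every locus; the individual's class is the
    presence/absence pattern of the model's two markers. Returns counts
    per class label (e.g. ``A/B``), summing to ``n``.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    labels = class_labels(model.markers)
    present = np.zeros((n, 2), dtype=bool)
    for locus in model.loci:
        gd = gametes(locus)
        gam = list(gd.keys())
        probs = np.array([float(p) for p in gd.values()])
        probs /= probs.sum()
        if n:
            draws = rng.choice(len(gam), size=(n, 2), p=probs)
            for k, marker in enumerate(model.markers):
                if marker not in locus.f1_genotype:
                    continue
                has = np.array([marker in g for g in gam])
                present[:, k] |= has[draws].any(axis=1)
    counts = {labels[key]: 0 for key in CLASS_ORDER}
    for key in CLASS_ORDER:
        mask = (present[:, 0] == key[0]) & (present[:, 1] == key[1])
        counts[labels[key]] = int(mask.sum())
    return counts
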