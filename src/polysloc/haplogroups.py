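"""Haplogroup classification and parental-origin assignment.

S-locus receptor kinase alleles fall into deeply diverged haplogroups that
are maintained across species by balancing selection: sequences of the
same specificity are nearly identical (>98% identity) while different
specificities share at most 91–92%. A query is therefore assigned to a
known haplogroup when it exceeds a strict identity threshold against some
reference, and each homeolog of an allotetraploid is attributed to a
parental subgenome by comparing corrected distances to the two parental
orthologs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import Alignment
from .seqdiv import corrected_distance, p_distance


@dataclass
class HaplogroupCall:
    query: str
    best_reference: str
    identity: float  # percent on compared sites
    call: str  # "same_haplogroup" | "novel_haplogroup"
    tie: bool = False


@dataclass
class OriginCall:
    query: str
    d_parent1: float | None
    d_parent2: float | None
    se_parent1: float | None
    se_parent2: float | None
    origin: str  # "parent1" | "parent2" | "ambiguous"
    single_parent: bool = False


def classify_haplogroup(
    query: str,
    references: Alignment,
    threshold: float = 98.0,
    query_label: str = "query",
) -> HaplogroupCall:
    """Assign a query sequence to a haplogroup by identity threshold.

    Identity is computed on compared sites (pairwise deletion) against
    every reference; the best reference wins, ties broken by input order
    and flagged. The call is ``same_haplogroup`` only for identity
    *strictly above* the threshold — a query at exactly the threshold is
    novel.

    ``query`` is the aligned query sequence (same coordinate system as the
    references).
    """
    best_ref = None
    best_identity = -1.0
    tie = False
    for label, seq in references:
        identity = (1.0 - p_distance(query, seq).p) * 100.0
        if identity > best_identity + 1e-12:
            best_identity = identity
            best_ref = label
            tie = False
        elif abs(identity - best_identity) <= 1e-12:
            tie = True
    call = "same_haplogroup" if best_identity > threshold else "novel_haplogroup"
    return HaplogroupCall(
        query=query_label, best_reference=best_ref,
        identity=best_identity, call=call, tie=tie,
    )


def assign_origin(
    query: str,
    ortholog_p1: str | None,
    ortholog_p2: str | None,
    method: str = "JC",
    tolerance: float = 1e-9,
    query_label: str = "query",
) -> OriginCall:
    """Attribute a homeolog to a parental subgenome by comparative distance.

    The parent with the smaller corrected distance wins; distances equal
    within ``tolerance`` give ``ambiguous``. With only one ortholog
    available the call is made from that single comparison and flagged
    ``single_parent``.
    """
    if ortholog_p1 is None and ortholog_p2 is None:
        raise ValueError("at least one parental ortholog is required")

    def dist(seq):
        if seq is None:
            return None, None
        est = corrected_distance(query, seq, method)
        return est.d, est.SE

    d1, se1 = dist(ortholog_p1)
    d2, se2 = dist(ortholog_p2)
    if d1 is None:
        origin, single = "parent2", True
    elif d2 is None:
        origin, single = "parent1", True
    elif abs(d1 - d2) <= tolerance:
        origin, single = "ambiguous", False
    else:
        origin, single = ("parent1" if d1 < d2 else "parent2"), False
    return OriginCall(query_label, d1, d2, se1, se2, origin, single)
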