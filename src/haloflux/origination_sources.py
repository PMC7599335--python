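"""Taxonomic classification of gene-family originations.

A family whose reconciliation shows an origination inside the species tree
was either transferred in from a lineage outside the sampled taxa or born
de novo.  To tell these apart, the family's sequences are placed onto a
reference gene tree spanning the tree of life (with the study's own clade
removed to avoid self-placement) and the placement edges' taxonomic labels
are aggregated:

* per sequence, the jplace like_weight_ratios are normalized to sum to 1;
* per taxonomic label path, normalized weights are summed across sequences
  and averaged per sequence; the top-weight label is the family's inferred
  phylogenetic affiliation (its donor, for an incoming transfer);
* a family with no reference homologs at all is a de novo gene;
* when fewer than four reference taxa remain after pruning, placement
  cannot be run and the family is assigned to the last common ancestor of
  the remaining reference taxa;
* ties resolve to the least-specific common ancestor of the tied labels.

A robustness check compares, for sequences that also exist in the raw
reference trees, the best-placement label against the label of the
sequence's true sister branch, classifying each family as all / some /
none of its sequences identically placed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .formats_io import PlacementProfile, SpeciesTree

__all__ = [
    "OriginationCall",
    "RobustnessResult",
    "summarize_placements",
    "classify_origination",
    "robustness_check",
    "aggregate_by_node",
]

MIN_PLACEMENT_TAXA = 4  # placement algorithms need >= 4 reference taxa


@dataclass
class OriginationCall:
    """Classified origination: where it happened and where it came from."""

    family_id: str
    origin_node: str
    source: str  # de_novo | taxon_label | lca_fallback
    label: tuple[str, ...]  # taxonomic label path; empty iff de_novo
    weight: float  # winning summed normalized like_weight_ratio

    def __post_init__(self) -> None:
        if self.source not in ("de_novo", "taxon_label", "lca_fallback"):
            raise ValueError(f"unknown source {self.source!r}")
        if (self.source == "de_novo") != (len(self.label) == 0):
            raise ValueError("label must be empty exactly for de novo calls")
        if not 0.0 <= self.weight <= 1.0 + 1e-9:
            raise ValueError("weight must lie in [0, 1]")


@dataclass
class RobustnessResult:
    frac_all: float
    frac_some: float
    frac_none: float
    n_families: int
    n_excluded: int  # families with no comparable sequence


def _common_prefix(paths: Sequence[tuple[str, ...]]) -> tuple[str, ...]:
    if not paths:
        return ()
    prefix = list(paths[0])
    for p in paths[1:]:
        k = 0
        while k < len(prefix) and k < len(p) and prefix[k] == p[k]:
            k += 1
        prefix = prefix[:k]
    return tuple(prefix)


def summarize_placements(profile: PlacementProfile) -> dict[tuple[str, ...], float]:
    """Aggregate a family's placements into label-path -> mean weight.

    Each sequence's like_weight_ratios are renormalized to sum to 1, mapped
    to their edges' taxonomic label paths, summed per label and divided by
    the number of placed sequences, so the result sums to 1 per family.
    """
    profile.validate()
    placed = {s: p for s, p in profile.placements.items() if p}
    if not placed:
        raise ValueError(f"family {profile.family_id}: no placements for any sequence")
    weights: dict[tuple[str, ...], float] = {}
    for plist in placed.values():
        total = sum(p.like_weight_ratio for p in plist)
        for p in plist:
            label = profile.edge_taxonomy[p.edge_id]
            weights[label] = weights.get(label, 0.0) + p.like_weight_ratio / total
    n = len(placed)
    return {label: w / n for label, w in weights.items()}


def classify_origination(
    family_id: str,
    profile: PlacementProfile | None,
    remaining_ref_taxa: int,
    origin_node: str,
    lca_label: Sequence[str] | None = None,
) -> OriginationCall:
    """Classify one origination-bearing family.

    No reference homologs (``profile is None`` and zero remaining taxa)
    means a de novo gene.  Fewer than four remaining reference taxa means
    placement could not run: the family is "placed" at the last common
    ancestor of the remaining taxa (``lca_label``, or the common prefix of
    the profile's edge labels when a profile is supplied).  Otherwise the
    argmax label of ``summarize_placements`` wins; ties resolve to the tied
    labels' least-specific common ancestor.
    """
    if remaining_ref_taxa <= 0 and profile is None:
        return OriginationCall(family_id, origin_node, "de_novo", (), 1.0)

    if remaining_ref_taxa < MIN_PLACEMENT_TAXA:
        if lca_label is None:
            if profile is None or not profile.edge_taxonomy:
                raise ValueError(
                    f"family {family_id}: LCA fallback needs a label or a profile"
                )
            lca_label = _common_prefix(list(profile.edge_taxonomy.values()))
        return OriginationCall(
            family_id, origin_node, "lca_fallback", tuple(lca_label), 1.0
        )

    if profile is None or not any(profile.placements.values()):
        raise ValueError(
            f"family {family_id}: reference taxa available but no placements"
        )
    weights = summarize_placements(profile)
    best = max(weights.values())
    tied = sorted(label for label, w in weights.items() if abs(w - best) <= 1e-9)
    if len(tied) == 1:
        label = tied[0]
        weight = best
    else:
        label = _common_prefix(tied)
        weight = sum(weights[t] for t in tied)
    return OriginationCall(family_id, origin_node, "taxon_label", label, min(weight, 1.0))


def robustness_check(
    profiles: Mapping[str, PlacementProfile],
    reference_sister_labels: Mapping[str, Mapping[str, Sequence[str]]],
) -> RobustnessResult:
    """Fraction of families whose sequences all / some / none match their
    reference-tree sister label.

    A sequence is comparable when it has both a placement and a reference
    sister label; its best-placement edge's label path is compared to that
    label.  Families with zero comparable sequences are excluded and
    counted.
    """
    n_all = n_some = n_none = n_excluded = 0
    for fam, profile in profiles.items():
        sisters = reference_sister_labels.get(fam, {})
        matches: list[bool] = []
        for seq, plist in profile.placements.items():
            if not plist or seq not in sisters:
                continue
            best = max(plist, key=lambda p: p.like_weight_ratio)
            matches.append(
                profile.edge_taxonomy[best.edge_id] == tuple(sisters[seq])
            )
        if not matches:
            n_excluded += 1
            continue
        if all(matches):
            n_all += 1
        elif any(matches):
            n_some += 1
        else:
            n_none += 1
    n = n_all + n_some + n_none
    if n == 0:
        raise ValueError("no family had a comparable sequence")
    return RobustnessResult(
        frac_all=n_all / n,
        frac_some=n_some / n,
        frac_none=n_none / n,
        n_families=n,
        n_excluded=n_excluded,
    )


def aggregate_by_node(
    calls: Sequence[OriginationCall],
    label_rollup: Mapping[str, str] | None = None,
    functional: Mapping[str, str] | None = None,
    tree: SpeciesTree | None = None,
) -> pd.DataFrame:
    """Per-node stacked origination counts: node x broad group x category.

    Fine labels roll up via ``label_rollup`` (matched against path elements
    from the most specific rank upward); labels without a rollup entry fall
    back to their own top rank.  De novo calls keep the group "de_novo".
    The sum of counts equals the number of calls.
    """
    label_rollup = dict(label_rollup or {})
    functional = dict(functional or {})
    counter: Counter[tuple[str, str, str]] = Counter()
    for call in calls:
        if tree is not None and call.origin_node not in tree.nodes:
            raise ValueError(f"origination at unknown node {call.origin_node!r}")
        if call.source == "de_novo":
            group = "de_novo"
        else:
            group = None
            for rank in reversed(call.label):
                if rank in label_rollup:
                    group = label_rollup[rank]
                    break
            if group is None:
                group = call.label[0] if call.label else "unclassified"
        category = functional.get(call.family_id, "unannotated")
        counter[(call.origin_node, group, category)] += 1
    df = pd.DataFrame(
        [
            {"node": n, "group": g, "category": c, "count": k}
            for (n, g, c), k in sorted(counter.items())
        ],
        columns=["node", "group", "category", "count"],
    )
    return df
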