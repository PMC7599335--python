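"""Summarize sampled reconciliations into ancestral gene contents and fluxes.

Gene tree / species tree reconciliation samplers (ALE and kin) report, per
gene family and per species-tree branch, the *frequency* with which each
event type (duplication D, transfer T, loss L, origination O) and each copy
number was observed across the sampled reconciliations.  These frequencies
quantify statistical support, like bootstrap proportions do for clades.

This module turns those frequencies into discrete statements:

* an event is *called* when its frequency reaches a threshold (default
  0.3, deliberately relaxed to capture signal weakened by alignment, tree
  and reconciliation uncertainty); frequencies above 1 — a branch hosting
  several events of one type — yield one call per whole unit plus one more
  if the remainder reaches the threshold;
* ancestral copy numbers are corrected upward for unobserved extinct
  lineages by dividing by the family's survival probability
  (1 - extinction probability);
* adjusted copy numbers map onto support categories:
  absent (< 0.3), weak [0.3, 0.65), moderate [0.65, 1.0), strong (>= 1.0);
* a multi-subunit complex is called present at a node when at least half
  of its subunits are present (copy number >= 0.3);
* singleton families (one member sequence, never reconciled) count as one
  origination and one strong presence at their genome's leaf.

Per-branch calls summed over families give the event-flux bars and inferred
genome sizes drawn along the species tree; per-pair transfer calls give the
donor x recipient transfer matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import ReconciliationSummary, SpeciesTree

__all__ = [
    "EventThresholds",
    "BranchFlux",
    "AncestralContent",
    "adjust_copies",
    "threshold_events",
    "support_category",
    "ancestral_content",
    "complex_presence",
    "transfer_matrix",
]

EVENT_TYPES = ("duplications", "transfers_in", "losses", "originations")
CATEGORIES = ("absent", "weak", "moderate", "strong")

_EPS = 1e-9  # guards float remainders at the threshold boundary


@dataclass(frozen=True)
class EventThresholds:
    """Frequency threshold for event calls and copy-number category bounds."""

    event_min: float = 0.3
    weak_bound: float = 0.3
    moderate_bound: float = 0.65
    strong_bound: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.event_min <= 1.0:
            raise ValueError("event_min must lie in (0, 1]")
        if not self.weak_bound < self.moderate_bound < self.strong_bound:
            raise ValueError("category bounds must be strictly increasing")


@dataclass
class BranchFlux:
    """Called event counts on one branch, with the contributing families."""

    branch_id: str
    duplications: int = 0
    transfers_in: int = 0
    originations: int = 0
    losses: int = 0
    families: dict[str, list[str]] = field(
        default_factory=lambda: {e: [] for e in EVENT_TYPES}
    )

    def add(self, event: str, family_id: str, calls: int) -> None:
        setattr(self, event, getattr(self, event) + calls)
        self.families[event].extend([family_id] * calls)


@dataclass
class AncestralContent:
    """Per-node inferred gene content.

    ``content[node][family]`` is (adjusted copy number, support category)
    for every family present (adjusted copies >= weak bound) at the node;
    genome size is the count of present families.
    """

    content: dict[str, dict[str, tuple[float, str]]]

    def genome_size(self, node_id: str) -> int:
        return len(self.content.get(node_id, {}))

    def genome_sizes(self) -> dict[str, int]:
        return {n: len(f) for n, f in self.content.items()}


# ---------------------------------------------------------------------------
# Elementary rules
# ---------------------------------------------------------------------------

def adjust_copies(raw: float, extinction_prob: float) -> float:
    """Correct an expected copy number for unobserved extinct lineages.

    Divides by the survival probability 1 - extinction_prob; rejects
    extinction probabilities >= 0.99 where the correction is unstable.
    """
    if raw < 0:
        raise ValueError("raw copy number must be >= 0")
    if not 0.0 <= extinction_prob < 0.99:
        raise ValueError(
            f"extinction probability {extinction_prob} outside [0, 0.99): "
            "correction unstable"
        )
    return raw / (1.0 - extinction_prob)


def event_calls(freq: float, event_min: float = 0.3) -> int:
    """Discrete event calls from a sampled-reconciliation frequency.

    calls = whole units + 1 if the fractional remainder >= event_min;
    e.g. 1.4 at threshold 0.3 gives 2 calls, 0.25 gives 0.
    """
    if freq < 0:
        raise ValueError("frequency must be >= 0")
    whole = math.floor(freq + _EPS)
    remainder = freq - whole
    return whole + (1 if remainder >= event_min - _EPS else 0)


def threshold_events(
    summary: ReconciliationSummary,
    th: EventThresholds = EventThresholds(),
) -> dict[str, dict[str, int]]:
    """Per-branch called event counts for one family: branch -> event -> calls."""
    out: dict[str, dict[str, int]] = {}
    for b, row in summary.branch_rows.items():
        calls = {e: event_calls(getattr(row, e), th.event_min) for e in EVENT_TYPES}
        if any(calls.values()):
            out[b] = calls
    return out


def support_category(adjusted_copies: float, th: EventThresholds = EventThresholds()) -> str:
    """Map an adjusted copy number onto absent/weak/moderate/strong."""
    if adjusted_copies < 0:
        raise ValueError("copy number must be >= 0")
    if adjusted_copies < th.weak_bound - _EPS:
        return "absent"
    if adjusted_copies < th.moderate_bound - _EPS:
        return "weak"
    if adjusted_copies < th.strong_bound - _EPS:
        return "moderate"
    return "strong"


def complex_presence(
    subunit_copies: Sequence[float],
    th: EventThresholds = EventThresholds(),
) -> bool:
    """Presence call for a multi-subunit complex at one node.

    Present iff at least half of the subunits have copy number >= the
    presence threshold (2 * present-count >= subunit count).
    """
    if len(subunit_copies) == 0:
        raise ValueError("empty subunit list")
    present = sum(1 for c in subunit_copies if c >= th.weak_bound - _EPS)
    return 2 * present >= len(subunit_copies)


# ---------------------------------------------------------------------------
# Aggregation over families
# ---------------------------------------------------------------------------

def ancestral_content(
    summaries: Sequence[ReconciliationSummary],
    tree: SpeciesTree,
    th: EventThresholds = EventThresholds(),
    singletons: Mapping[str, str] | None = None,
) -> tuple[AncestralContent, list[BranchFlux]]:
    """Ancestral gene contents and per-branch event fluxes over all families.

    Copy-number presence is evaluated on extinction-adjusted copies; event
    calls use the raw frequencies.  Each singleton family contributes one
    origination call and one strong presence at its leaf.
    """
    singletons = dict(singletons or {})
    overlap = {s.family_id for s in summaries} & set(singletons)
    if overlap:
        raise ValueError(
            f"families appear both in summaries and singletons: {sorted(overlap)}"
        )
    content: dict[str, dict[str, tuple[float, str]]] = {b: {} for b in tree.nodes}
    flux: dict[str, BranchFlux] = {b: BranchFlux(branch_id=b) for b in tree.nodes}

    for summary in summaries:
        summary.validate(tree)
        for b, row in summary.branch_rows.items():
            adj = adjust_copies(row.copies, summary.extinction_prob)
            cat = support_category(adj, th)
            if cat != "absent":
                content[b][summary.family_id] = (adj, cat)
            for e in EVENT_TYPES:
                calls = event_calls(getattr(row, e), th.event_min)
                if calls:
                    flux[b].add(e, summary.family_id, calls)

    for fam, leaf in singletons.items():
        if leaf not in tree.nodes or not tree.nodes[leaf].is_leaf:
            raise ValueError(f"singleton family {fam!r} maps to non-leaf {leaf!r}")
        content[leaf][fam] = (1.0, "strong")
        flux[leaf].add("originations", fam, 1)

    return AncestralContent(content=content), [flux[b] for b in tree.postorder()]


def transfer_matrix(
    summaries: Sequence[ReconciliationSummary],
    tree: SpeciesTree,
    th: EventThresholds = EventThresholds(),
) -> pd.DataFrame:
    """Donor x recipient matrix of called transfer counts.

    Each (donor, recipient, frequency) pair is thresholded independently
    with the unit-plus-remainder rule; self-transfers are rejected.
    """
    branches = tree.postorder()
    mat = pd.DataFrame(0, index=branches, columns=branches, dtype=int)
    for summary in summaries:
        for donor, recipient, freq in summary.transfer_pairs:
            if donor == recipient:
                raise ValueError(
                    f"family {summary.family_id}: self-transfer on branch {donor}"
                )
            if donor not in tree.nodes or recipient not in tree.nodes:
                raise ValueError(
                    f"family {summary.family_id}: transfer pair "
                    f"({donor},{recipient}) not in tree"
                )
            mat.loc[donor, recipient] += event_calls(freq, th.event_min)
    mat.index.name = "donor"
    mat.columns.name = "recipient"
    return mat


def transfer_marginal_consistency(
    summaries: Sequence[ReconciliationSummary],
    tree: SpeciesTree,
    th: EventThresholds = EventThresholds(),
) -> pd.DataFrame:
    """Compare pairwise-thresholded recipient sums with marginal calls.

    Thresholding donor-recipient pairs independently need not match calls
    made on the recipient's summed transfer frequency; branches where the
    two disagree are flagged.
    """
    mat = transfer_matrix(summaries, tree, th)
    pair_sums = mat.sum(axis=0)
    marginal = {b: 0 for b in tree.postorder()}
    for summary in summaries:
        for b, row in summary.branch_rows.items():
            marginal[b] += event_calls(row.transfers_in, th.event_min)
    df = pd.DataFrame(
        {
            "pairwise_calls": pair_sums,
            "marginal_calls": pd.Series(marginal),
        }
    )
    df["consistent"] = df["pairwise_calls"] == df["marginal_calls"]
    df.index.name = "recipient"
    return df
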