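"""Gene-family construction: de novo clustering and fusion-protein splitting.

Proteins that cannot be assigned to a precomputed orthologous group are
clustered de novo by single-linkage over pairwise similarity hits, with
conservative identity/overlap thresholds (defaults 0.6 / 0.9) so that
out-paralogs are not merged into one family.

Fusion (composite) proteins violate the reconciliation assumption that all
residues of a protein share one phylogenetic history.  Families containing
a member annotated with two or more distinct COG/NOG identifiers are
screened with COG profile hits; overlapping regions are resolved in favour
of the better-scoring hit, a trimmed region must retain at least 30% of its
original length, and the family is split into one new family per distinct
COG ("<family>_<COG>"), each resolved region becoming its own member
sequence.  Members without any resolved region are preserved in a
"<family>_rest" residual family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "PairwiseHit",
    "RegionHit",
    "SplitFamily",
    "cluster_single_linkage",
    "detect_fusion_clusters",
    "resolve_regions",
    "split_family",
    "read_domtblout",
    "naive_profile_scan",
]

DEFAULT_MIN_IDENT = 0.6
DEFAULT_MIN_OVERLAP = 0.9
DEFAULT_MIN_RETAINED = 0.3


@dataclass(frozen=True)
class PairwiseHit:
    """Symmetric pairwise similarity hit between two proteins.

    ``overlap`` is aligned length divided by the shorter sequence's length.
    """

    query: str
    subject: str
    identity: float
    overlap: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.overlap <= 1.0):
            raise ValueError("identity and overlap must lie in [0, 1]")


@dataclass(frozen=True)
class RegionHit:
    """Profile hit of one COG on a protein region (1-based inclusive)."""

    protein: str
    cog: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid coordinates {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SplitFamily:
    """Component family produced by fusion splitting.

    Member coordinates are 1-based inclusive; residual (unsplit) members
    carry (None, None) when their full length is unknown.
    """

    family_id: str  # "<parent>_<COG>" or "<parent>_rest"
    members: list[tuple[str, int | None, int | None]]
    residual: bool = False


# ---------------------------------------------------------------------------
# Single-linkage clustering
# ---------------------------------------------------------------------------

def cluster_single_linkage(
    hits: Iterable[PairwiseHit],
    min_ident: float = DEFAULT_MIN_IDENT,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> list[set[str]]:
    """Partition proteins into connected components of the similarity graph.

    An edge exists when identity >= min_ident AND overlap >= min_overlap
    (both thresholds inclusive).  Proteins named only in sub-threshold hits
    become singleton clusters.  Components come back sorted by their
    smallest member for determinism.
    """
    if not (0.0 <= min_ident <= 1.0 and 0.0 <= min_overlap <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    g = nx.Graph()
    for h in hits:
        g.add_node(h.query)
        g.add_node(h.subject)
        if h.identity >= min_ident and h.overlap >= min_overlap:
            g.add_edge(h.query, h.subject)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(c))
    return comps


# ---------------------------------------------------------------------------
# Fusion detection and region resolution
# ---------------------------------------------------------------------------

def detect_fusion_clusters(
    annotations: Mapping[str, set[str]],
    families: Mapping[str, Sequence[str]],
) -> set[str]:
    """Families containing >= 1 member annotated with >= 2 distinct COG ids.

    Members missing from ``annotations`` are treated as unannotated.
    """
    flagged: set[str] = set()
    for fam, members in families.items():
        for protein in members:
            if len(annotations.get(protein, set())) >= 2:
                flagged.add(fam)
                break
    return flagged


def resolve_regions(
    hits: Sequence[RegionHit],
    min_retained: float = DEFAULT_MIN_RETAINED,
) -> list[RegionHit]:
    """Resolve overlapping COG region hits on one protein.

    Hits are processed in descending score (ties: longer region, then lower
    start).  Each accepted region claims its (possibly trimmed) interval;
    later regions are trimmed to their longest contiguous flank outside all
    claimed intervals.  A region retaining less than ``min_retained`` of its
    original length is discarded.  Output is sorted by start and pairwise
    non-overlapping.
    """
    proteins = {h.protein for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(proteins)}")
    ordered = sorted(hits, key=lambda h: (-h.score, -h.length, h.start))
    claimed: list[tuple[int, int]] = []
    accepted: list[RegionHit] = []
    for h in ordered:
        segments = _subtract(h.start, h.end, claimed)
        if not segments:
            continue
        # keep only the longest contiguous flank; ties toward the earlier one
        start, end = max(segments, key=lambda seg: (seg[1] - seg[0], -seg[0]))
        if (end - start + 1) < min_retained * h.length:
            continue
        claimed.append((start, end))
        accepted.append(RegionHit(h.protein, h.cog, start, end, h.score))
    accepted.sort(key=lambda h: h.start)
    return accepted


def _subtract(start: int, end: int, claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Contiguous sub-intervals of [start, end] not covered by any claimed interval."""
    segments = [(start, end)]
    for cs, ce in claimed:
        nxt: list[tuple[int, int]] = []
        for s, e in segments:
            if ce < s or cs > e:
                nxt.append((s, e))
                continue
            if s < cs:
                nxt.append((s, cs - 1))
            if e > ce:
                nxt.append((ce + 1, e))
        segments = nxt
    return segments


def split_family(
    family_id: str,
    members: Sequence[str],
    resolved: Mapping[str, Sequence[RegionHit]],
    sequences: Mapping[str, str] | None = None,
) -> list[SplitFamily]:
    """Split a fusion family into one new family per distinct COG.

    Every resolved region becomes one member record (two same-COG regions of
    one protein yield two records); members with no resolved region land in
    a "<family>_rest" residual family.  Raises if no member has any
    resolved region.
    """
    by_cog: dict[str, list[tuple[str, int, int]]] = {}
    rest: list[tuple[str, int | None, int | None]] = []
    n_regions = 0
    for protein in members:
        regions = resolved.get(protein, [])
        if not regions:
            if sequences and protein in sequences:
                rest.append((protein, 1, len(sequences[protein])))
            else:
                rest.append((protein, None, None))
            continue
        for r in regions:
            if sequences and protein in sequences and r.end > len(sequences[protein]):
                raise ValueError(
                    f"{protein}: region {r.start}-{r.end} exceeds sequence length"
                )
            by_cog.setdefault(r.cog, []).append((protein, r.start, r.end))
            n_regions += 1
    if n_regions == 0:
        raise ValueError(f"family {family_id}: no resolved regions, nothing to split")
    out = [
        SplitFamily(family_id=f"{family_id}_{cog}", members=mem)
        for cog, mem in sorted(by_cog.items())
    ]
    if rest:
        out.append(SplitFamily(family_id=f"{family_id}_rest", members=rest, residual=True))
    return out


# ---------------------------------------------------------------------------
# Profile-hit input
# ---------------------------------------------------------------------------

def read_domtblout(path: str | Path) -> list[RegionHit]:
    """Read HMMER per-domain table output (domtblout dialect).

    Target name is the protein, query name the COG profile; score is the
    per-domain bit score, coordinates are ali_from/ali_to (1-based).
    """
    hits: list[RegionHit] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        f = raw.split()
        if len(f) < 19:
            raise ValueError(f"domtblout row has {len(f)} fields, expected >= 19")
        hits.append(
            RegionHit(
                protein=f[0],
                cog=f[3],
                start=int(f[17]),
                end=int(f[18]),
                score=float(f[13]),
            )
        )
    return hits


def naive_profile_scan(
    sequence: str,
    profile_columns: Sequence[Mapping[str, float]],
    background: Mapping[str, float],
    protein: str = "query",
    cog: str = "profile",
) -> RegionHit | None:
    """Ungapped sliding-window log-odds scan of one profile over a protein.

    ``profile_columns`` holds per-column residue frequencies of the COG
    alignment; the score of a window is the summed log-odds versus the
    background.  Returns the best-scoring window as a RegionHit, or None if
    the sequence is shorter than the profile.  Intended for tests and small
    examples, not as a substitute for a real profile HMM search.
    """
    w = len(profile_columns)
    if w == 0 or len(sequence) < w:
        return None
    floor = 1e-4  # pseudo-frequency for residues unseen in a column
    best_score, best_start = None, 0
    for s in range(len(sequence) - w + 1):
        score = 0.0
        for k in range(w):
            aa = sequence[s + k]
            p = profile_columns[k].get(aa, floor)
            q = background.get(aa, 0.05)
            score += math.log(max(p, floor) / max(q, floor))
        if best_score is None or score > best_score:
            best_score, best_start = score, s
    return RegionHit(
        protein=protein, cog=cog, start=best_start + 1, end=best_start + w, score=best_score
    )
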