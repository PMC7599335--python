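"""Ground-truth synthetic inputs for every pipeline stage.

The generators emulate, at desk scale, the data a reconciliation study
consumes: gene families evolving by origination / duplication / transfer /
loss (DTL) along a species tree, branch-wise event-frequency tables with
controllable reconciliation noise, alignments with a planted fraction of
compositionally biased sites, fusion proteins concatenated from two
families with known breakpoints, and phylogenetic placement scenarios with
known donor labels.

The DTL simulator is discrete and branch-wise (each gene copy entering a
branch undergoes at most one event), mirroring the undated reconciliation
model it stands in for; transfers land only on non-descendant branches, a
time-consistency surrogate in an undated setting.  Copy-number
conservation — copies(child) = copies(parent) + gains - losses — holds
exactly on every simulated history, which is what makes exact recovery
testable downstream.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .composition import AMINO_ACIDS, Alignment
from .families import RegionHit
from .formats_io import (
    BranchRow,
    Placement,
    PlacementProfile,
    ReconciliationSummary,
    SpeciesTree,
    species_tree_from_string,
    write_edge_taxonomy,
    write_jplace,
    write_rec_summary,
    write_singletons,
    write_species_tree,
)

__all__ = [
    "DtlParams",
    "DtlHistory",
    "random_species_tree",
    "simulate_dtl",
    "split_singletons",
    "emit_rec_summaries",
    "simulate_biased_alignment",
    "FusionTruth",
    "make_fusion_proteins",
    "PlacementScenario",
    "default_edge_taxonomy",
    "make_placement_scenarios",
]

GENERATOR_VERSION = "1.0"

EVENT_KINDS = ("D", "T", "L", "O")


def _manifest(generator: str, seed: int, **params) -> dict:
    return {"generator": generator, "version": GENERATOR_VERSION, "seed": seed, **params}


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def random_species_tree(n_leaves: int, seed: int, prefix: str = "L") -> SpeciesTree:
    """Random rooted binary species tree with labelled internal nodes.

    Leaves are ``<prefix>1..<prefix>n``; internal nodes are labelled
    ``n1..n(n-1)`` as they are created by random joins.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    subtrees = [f"{prefix}{i + 1}" for i in range(n_leaves)]
    k = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        k += 1
        label = f"n{k}" if len(subtrees) > 0 else "root"
        subtrees.append(f"({left},{right}){label}")
    return species_tree_from_string(subtrees[0] + ";", id_source="node_labels")


# ---------------------------------------------------------------------------
# DTL histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DtlParams:
    """Per-branch event probabilities of the discrete DTL model."""

    p_dup: float = 0.05
    p_trans: float = 0.05
    p_loss: float = 0.15
    p_orig_root: float = 0.5
    n_families: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_dup", "p_trans", "p_loss"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.p_orig_root <= 1.0:
            raise ValueError("p_orig_root must lie in [0, 1]")
        if self.p_dup + self.p_trans + self.p_loss >= 1.0:
            raise ValueError("p_dup + p_trans + p_loss must be < 1")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")


@dataclass
class DtlHistory:
    """Ground-truth event counts and copy numbers for one family."""

    family_id: str
    origin_node: str
    duplications: Counter = field(default_factory=Counter)  # branch -> count
    transfers_in: Counter = field(default_factory=Counter)
    losses: Counter = field(default_factory=Counter)
    originations: Counter = field(default_factory=Counter)
    transfer_pairs: Counter = field(default_factory=Counter)  # (donor, recipient)
    copies: dict[str, int] = field(default_factory=dict)  # node -> copy count

    def extant_leaves(self, tree: SpeciesTree) -> set[str]:
        return {b for b in tree.leaf_ids if self.copies.get(b, 0) > 0}

    def event_count(self, kind: str, branch: str) -> int:
        return {
            "D": self.duplications,
            "T": self.transfers_in,
            "L": self.losses,
            "O": self.originations,
        }[kind][branch]

    def check_conservation(self, tree: SpeciesTree) -> None:
        """Assert copies(child) = copies(parent) + gains - losses everywhere."""
        for b, node in tree.nodes.items():
            parent_copies = self.copies.get(node.parent, 0) if node.parent else 0
            gains = self.duplications[b] + self.transfers_in[b] + self.originations[b]
            expected = parent_copies + gains - self.losses[b]
            if self.copies.get(b, 0) != expected:
                raise AssertionError(
                    f"{self.family_id}: conservation violated on branch {b}: "
                    f"{self.copies.get(b, 0)} != {expected}"
                )


def _transfer_recipients(tree: SpeciesTree, donor: str) -> list[str]:
    """Branches a transfer from ``donor`` may land on: non-root branches
    outside the donor's subtree."""
    excluded = tree.subtree_ids(donor)
    return [b for b in tree.postorder() if b != tree.root_id and b not in excluded]


def simulate_dtl(tree: SpeciesTree, params: DtlParams) -> list[DtlHistory]:
    """Simulate gene-family DTL histories along a binary species tree.

    Each family originates at the root (probability ``p_orig_root``) or at
    a uniformly chosen other node.  Every gene copy entering a branch
    independently undergoes at most one event: loss (the copy dies),
    duplication (two copies reach the child), or transfer (the copy
    continues and one extra copy is injected on a uniformly chosen
    non-descendant branch, recorded as donor -> recipient on the recipient
    branch).  Transferred copies propagate onward from their landing node.
    """
    for node in tree.nodes.values():
        if not node.is_leaf and len(node.children) != 2:
            raise ValueError("simulate_dtl requires a strictly binary tree")
    rng = np.random.default_rng(params.seed)
    non_root = [b for b in tree.postorder() if b != tree.root_id]
    histories: list[DtlHistory] = []

    for fam_idx in range(params.n_families):
        if rng.random() < params.p_orig_root:
            origin = tree.root_id
        else:
            origin = non_root[rng.integers(len(non_root))]
        hist = DtlHistory(family_id=f"fam{fam_idx:04d}", origin_node=origin)
        hist.originations[origin] += 1
        copies: Counter = Counter()

        # injections: copies appearing at a node (origination or transfer)
        pending: list[tuple[str, int]] = [(origin, 1)]
        guard = 0
        while pending:
            guard += 1
            if guard > 1_000_000:
                raise RuntimeError("runaway transfer cascade; lower event probabilities")
            node_id, n_new = pending.pop()
            copies[node_id] += n_new
            # propagate these new copies depth-first below node_id
            stack = [(node_id, n_new)]
            while stack:
                v, n_in = stack.pop()
                for child in tree.nodes[v].children:
                    survivors = 0
                    for _ in range(n_in):
                        u = rng.random()
                        if u < params.p_loss:
                            hist.losses[child] += 1
                        elif u < params.p_loss + params.p_dup:
                            hist.duplications[child] += 1
                            survivors += 2
                        elif u < params.p_loss + params.p_dup + params.p_trans:
                            recipients = _transfer_recipients(tree, child)
                            r = recipients[rng.integers(len(recipients))]
                            hist.transfers_in[r] += 1
                            hist.transfer_pairs[(child, r)] += 1
                            pending.append((r, 1))
                            survivors += 1
                        else:
                            survivors += 1
                    if survivors:
                        copies[child] += survivors
                        stack.append((child, survivors))

        hist.copies = {b: c for b, c in copies.items() if c > 0}
        hist.check_conservation(tree)
        histories.append(hist)
    return histories


def split_singletons(
    histories: Sequence[DtlHistory], tree: SpeciesTree
) -> tuple[list[DtlHistory], dict[str, str]]:
    """Separate singleton families (one extant copy at one leaf, no other
    events) from families worth reconciling.

    Mirrors a study pipeline where single-member families never get a gene
    tree: they enter the reconstruction via the singleton-origination rule
    instead of a frequency table.
    """
    singletons: dict[str, str] = {}
    rest: list[DtlHistory] = []
    for h in histories:
        leaf = h.origin_node
        only_event = (
            tree.nodes[leaf].is_leaf
            and sum(h.originations.values()) == 1
            and not h.duplications
            and not h.transfers_in
            and not h.losses
            and h.copies == {leaf: 1}
        )
        if only_event:
            singletons[h.family_id] = leaf
        else:
            rest.append(h)
    return rest, singletons


# ---------------------------------------------------------------------------
# ALE-style frequency tables with reconciliation noise
# ---------------------------------------------------------------------------

def _apply_copy_delta(
    copies: Counter, tree: SpeciesTree, branch: str, delta: int
) -> None:
    for b in tree.subtree_ids(branch):
        copies[b] = max(0, copies[b] + delta)


def _perturbed_sample(
    hist: DtlHistory, tree: SpeciesTree, rng: np.random.Generator
) -> tuple[Counter, Counter, Counter, Counter, Counter, Counter]:
    """One noisy pseudo-reconciliation: the truth with one event deleted or
    one spurious event added; copy numbers follow the event edit (clamped
    at zero)."""
    dup = Counter(hist.duplications)
    tin = Counter(hist.transfers_in)
    los = Counter(hist.losses)
    ori = Counter(hist.originations)
    pairs = Counter(hist.transfer_pairs)
    copies = Counter(hist.copies)

    events: list[tuple[str, str]] = []
    for b, c in dup.items():
        events += [("D", b)] * c
    for (d, r), c in pairs.items():
        events += [(f"T:{d}", r)] * c
    for b, c in los.items():
        events += [("L", b)] * c
    for b, c in ori.items():
        events += [("O", b)] * c

    delete = events and rng.random() < 0.5
    if delete:
        kind, b = events[rng.integers(len(events))]
        if kind == "D":
            dup[b] -= 1
            _apply_copy_delta(copies, tree, b, -1)
        elif kind.startswith("T:"):
            donor = kind[2:]
            tin[b] -= 1
            pairs[(donor, b)] -= 1
            _apply_copy_delta(copies, tree, b, -1)
        elif kind == "L":
            los[b] -= 1
            _apply_copy_delta(copies, tree, b, +1)
        else:
            ori[b] -= 1
            _apply_copy_delta(copies, tree, b, -1)
    else:
        non_root = [x for x in tree.postorder() if x != tree.root_id]
        kind = EVENT_KINDS[rng.integers(len(EVENT_KINDS))]
        if kind == "O":
            b = tree.postorder()[rng.integers(len(tree.nodes))]
            ori[b] += 1
            _apply_copy_delta(copies, tree, b, +1)
        else:
            b = non_root[rng.integers(len(non_root))]
            if kind == "D":
                dup[b] += 1
                _apply_copy_delta(copies, tree, b, +1)
            elif kind == "L":
                los[b] += 1
                _apply_copy_delta(copies, tree, b, -1)
            else:  # spurious transfer into b from a valid donor
                donors = [
                    d
                    for d in non_root
                    if d != b and b not in tree.subtree_ids(d)
                ]
                if donors:
                    d = donors[rng.integers(len(donors))]
                    tin[b] += 1
                    pairs[(d, b)] += 1
                    _apply_copy_delta(copies, tree, b, +1)
    return dup, tin, los, ori, pairs, copies


def emit_rec_summaries(
    histories: Sequence[DtlHistory],
    tree: SpeciesTree,
    r_samples: int = 100,
    perturb: float = 0.0,
    seed: int = 0,
    extinction_prob: float = 0.0,
    out_dir: str | Path | None = None,
) -> list[ReconciliationSummary]:
    """Branch-wise frequency tables averaged over pseudo-reconciliations.

    Each of ``r_samples`` samples equals the true history with probability
    1 - perturb, otherwise a copy with one event deleted or one spurious
    event added.  Frequencies and copy numbers are sample means, so with
    ``perturb = 0`` every true event has frequency equal to its integer
    multiplicity.  ``extinction_prob`` is written verbatim to each family's
    ``#extinction`` line.
    """
    if r_samples <= 0:
        raise ValueError("r_samples must be >= 1")
    if not 0.0 <= perturb <= 1.0:
        raise ValueError("perturb must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    summaries: list[ReconciliationSummary] = []

    for hist in histories:
        sum_dup: Counter = Counter()
        sum_tin: Counter = Counter()
        sum_los: Counter = Counter()
        sum_ori: Counter = Counter()
        sum_pairs: Counter = Counter()
        sum_copies: Counter = Counter()
        n_clean = 0
        for _ in range(r_samples):
            if perturb > 0.0 and rng.random() < perturb:
                dup, tin, los, ori, pairs, copies = _perturbed_sample(hist, tree, rng)
                sum_dup.update(dup)
                sum_tin.update(tin)
                sum_los.update(los)
                sum_ori.update(ori)
                sum_pairs.update(pairs)
                sum_copies.update(copies)
            else:
                n_clean += 1
        if n_clean:
            for counter, truth in (
                (sum_dup, hist.duplications),
                (sum_tin, hist.transfers_in),
                (sum_los, hist.losses),
                (sum_ori, hist.originations),
                (sum_pairs, hist.transfer_pairs),
                (sum_copies, hist.copies),
            ):
                for key, c in truth.items():
                    counter[key] += c * n_clean

        branch_rows: dict[str, BranchRow] = {}
        for b in tree.postorder():
            row = BranchRow(
                duplications=sum_dup[b] / r_samples,
                transfers_in=sum_tin[b] / r_samples,
                losses=sum_los[b] / r_samples,
                originations=sum_ori[b] / r_samples,
                copies=sum_copies[b] / r_samples,
            )
            if any(
                (row.duplications, row.transfers_in, row.losses, row.originations, row.copies)
            ):
                branch_rows[b] = row
        summary = ReconciliationSummary(
            family_id=hist.family_id,
            branch_rows=branch_rows,
            transfer_pairs=[
                (d, r, c / r_samples) for (d, r), c in sorted(sum_pairs.items()) if c
            ],
            extinction_prob=extinction_prob,
            n_samples=r_samples,
        )
        summary.validate(tree)
        summaries.append(summary)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in summaries:
            write_rec_summary(s, out_dir / f"{s.family_id}.rec.tsv")
        _write_manifest(
            out_dir,
            _manifest(
                "emit_rec_summaries",
                seed,
                r_samples=r_samples,
                perturb=perturb,
                extinction_prob=extinction_prob,
                n_families=len(histories),
            ),
        )
    return summaries


# ---------------------------------------------------------------------------
# Compositionally biased alignments
# ---------------------------------------------------------------------------

def simulate_biased_alignment(
    n_taxa: int,
    n_sites: int,
    biased_fraction: float,
    bias_strength: float = 1.0,
    seed: int = 0,
) -> tuple[Alignment, list[int]]:
    """Alignment with a planted fraction of compositionally biased sites.

    Unbiased sites draw every taxon's residue from one global frequency
    vector; at a biased site each taxon draws from its own vector, shifted
    toward a taxon-specific preferred residue with weight proportional to
    ``bias_strength - 1`` (so strength 1 means no bias).  Returns the
    alignment and the sorted 0-based planted site indices.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if not 0.0 <= biased_fraction <= 1.0:
        raise ValueError("biased_fraction must lie in [0, 1]")
    if bias_strength < 1.0:
        raise ValueError("bias_strength must be >= 1")
    rng = np.random.default_rng(seed)
    global_freq = rng.dirichlet(np.full(20, 5.0))
    n_biased = int(round(biased_fraction * n_sites))
    planted = sorted(rng.choice(n_sites, size=n_biased, replace=False).tolist())
    planted_set = set(planted)

    preferred = rng.permutation(20)
    taxon_freqs = []
    for t in range(n_taxa):
        v = global_freq.copy()
        v[preferred[t % 20]] += bias_strength - 1.0
        taxon_freqs.append(v / v.sum())

    aa = np.array(list(AMINO_ACIDS))
    cols = np.empty((n_taxa, n_sites), dtype="<U1")
    for j in range(n_sites):
        if j in planted_set:
            for t in range(n_taxa):
                cols[t, j] = aa[rng.choice(20, p=taxon_freqs[t])]
        else:
            cols[:, j] = aa[rng.choice(20, size=n_taxa, p=global_freq)]
    rows = ["".join(cols[t]) for t in range(n_taxa)]
    taxa = [f"T{t + 1}" for t in range(n_taxa)]
    return Alignment(taxa=taxa, rows=rows), planted


# ---------------------------------------------------------------------------
# Fusion proteins
# ---------------------------------------------------------------------------

@dataclass
class FusionTruth:
    protein: str
    cog_a: str
    cog_b: str
    breakpoint: int  # last residue of the A component
    region_a: tuple[int, int]
    region_b: tuple[int, int]


def make_fusion_proteins(
    fam_a: Mapping[str, str],
    fam_b: Mapping[str, str],
    n: int,
    seed: int = 0,
    jitter: int = 0,
    cog_a: str = "COG1009",
    cog_b: str = "COG2111",
) -> tuple[dict[str, str], list[FusionTruth], list[RegionHit]]:
    """Concatenate one sequence from each pool into ``n`` fusion proteins.

    Truth records the exact component intervals (1..L_a and L_a+1..L_a+L_b);
    the emitted region hits have their inner boundaries shifted by a uniform
    offset in [-jitter, +jitter], so inferred breakpoints are within
    ``jitter`` residues of the truth by construction.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not fam_a or not fam_b:
        raise ValueError("both sequence pools must be non-empty")
    rng = np.random.default_rng(seed)
    ids_a, ids_b = sorted(fam_a), sorted(fam_b)
    proteins: dict[str, str] = {}
    truths: list[FusionTruth] = []
    hits: list[RegionHit] = []
    for i in range(n):
        sa = fam_a[ids_a[rng.integers(len(ids_a))]]
        sb = fam_b[ids_b[rng.integers(len(ids_b))]]
        la, lb = len(sa), len(sb)
        pid = f"fusion{i:03d}"
        proteins[pid] = sa + sb
        truths.append(
            FusionTruth(
                protein=pid,
                cog_a=cog_a,
                cog_b=cog_b,
                breakpoint=la,
                region_a=(1, la),
                region_b=(la + 1, la + lb),
            )
        )
        end_a = la + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        start_b = la + 1 + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        end_a = min(max(end_a, 1), la + lb)
        start_b = min(max(start_b, 1), la + lb)
        score_a = 50.0 + float(rng.random()) * 50.0
        score_b = 50.0 + float(rng.random()) * 50.0
        hits.append(RegionHit(pid, cog_a, 1, end_a, score_a))
        hits.append(RegionHit(pid, cog_b, start_b, la + lb, score_b))
    return proteins, truths, hits


def random_protein_pool(n: int, length_range: tuple[int, int], seed: int) -> dict[str, str]:
    """Random protein sequences, for feeding the fusion generator."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    return {
        f"p{seed}_{i}": "".join(
            AMINO_ACIDS[k] for k in rng.integers(0, 20, size=int(rng.integers(lo, hi + 1)))
        )
        for i in range(n)
    }


# ---------------------------------------------------------------------------
# Placement scenarios
# ---------------------------------------------------------------------------

@dataclass
class PlacementScenario:
    family_id: str
    donor_label: str | None  # None means a de novo family (no homologs)
    true_edge: str | None
    profile: PlacementProfile | None
    sister_labels: dict[str, tuple[str, ...]]  # per sequence, for robustness


def default_edge_taxonomy() -> dict[str, tuple[str, ...]]:
    """Small tree-of-life edge taxonomy used by the toy scenarios."""
    return {
        "e1": ("cellular organisms", "Bacteria", "Terrabacteria"),
        "e2": ("cellular organisms", "Bacteria", "FCB group"),
        "e3": ("cellular organisms", "Bacteria", "Proteobacteria"),
        "e4": ("cellular organisms", "Archaea", "TACK"),
        "e5": ("cellular organisms", "Archaea", "DPANN"),
        "e6": ("cellular organisms", "Eukaryota", "Opisthokonta"),
        "e7": ("cellular organisms", "Eukaryota", "Archaeplastida"),
    }


def make_placement_scenarios(
    taxonomy: Mapping[str, Sequence[str]],
    n_families: int,
    donor_labels: Sequence[str | None],
    noise: float = 0.0,
    seed: int = 0,
    n_seqs: int = 3,
    out_dir: str | Path | None = None,
    family_ids: Sequence[str] | None = None,
) -> list[PlacementScenario]:
    """Placement profiles with known donors.

    Each sequence of a family puts weight ``1 - noise`` on an edge under
    the family's true donor label, spreading ``noise`` uniformly over all
    other edges.  A ``None`` donor label yields a de novo family with no
    profile.
    """
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must lie in [0, 1)")
    if len(donor_labels) != n_families:
        raise ValueError("need one donor label (or None) per family")
    if family_ids is not None and len(family_ids) != n_families:
        raise ValueError("need one family id per family")
    taxonomy = {e: tuple(p) for e, p in taxonomy.items()}
    rng = np.random.default_rng(seed)
    edges = sorted(taxonomy)
    scenarios: list[PlacementScenario] = []

    for i, donor in enumerate(donor_labels):
        fam = family_ids[i] if family_ids is not None else f"orig{i:04d}"
        if donor is None:
            scenarios.append(PlacementScenario(fam, None, None, None, {}))
            continue
        candidates = [e for e in edges if donor in taxonomy[e]]
        if not candidates:
            raise ValueError(f"donor label {donor!r} not found in taxonomy")
        true_edge = candidates[int(rng.integers(len(candidates)))]
        others = [e for e in edges if e != true_edge]
        placements: dict[str, list[Placement]] = {}
        sisters: dict[str, tuple[str, ...]] = {}
        for s in range(n_seqs):
            seq = f"{fam}_s{s}"
            plist = [Placement(true_edge, 1.0 - noise, -10.0)]
            if noise > 0 and others:
                share = noise / len(others)
                plist += [Placement(e, share, -20.0) for e in others]
            plist.sort(key=lambda p: -p.like_weight_ratio)
            placements[seq] = plist
            sisters[seq] = taxonomy[true_edge]
        profile = PlacementProfile(
            family_id=fam, placements=placements, edge_taxonomy=dict(taxonomy)
        )
        profile.validate()
        scenarios.append(PlacementScenario(fam, donor, true_edge, profile, sisters))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_edge_taxonomy(taxonomy, out_dir / "edge_taxonomy.tsv")
        for sc in scenarios:
            if sc.profile is not None:
                write_jplace(sc.profile, out_dir / f"{sc.family_id}.jplace")
        _write_manifest(
            out_dir,
            _manifest(
                "make_placement_scenarios",
                seed,
                n_families=n_families,
                noise=noise,
                n_seqs=n_seqs,
            ),
        )
    return scenarios
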