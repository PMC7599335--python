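"""Supermatrix construction and compositional-bias treatments.

Across-taxa compositional heterogeneity is a classic source of phylogenetic
artifacts in deep archaeal phylogenies: taxa that independently converged on
a similar amino-acid composition (e.g. the acidified proteomes of extreme
halophiles) can be drawn together regardless of history.  Two standard
mitigations are implemented here:

* chi-square site trimming — remove the alignment columns that contribute
  most to the per-taxon chi-square deviation from the global amino-acid
  composition, then re-infer the tree from the trimmed supermatrix;
* SR4 recoding — collapse the 20 amino acids into 4 groups so that
  exchanges within a group (which dominate compositional drift) become
  invisible to the substitution model.

The module also computes per-taxon composition tables and the N-ARSC
statistic (mean nitrogen atoms per amino-acid side chain), a genome
streamlining / nutrient limitation signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "SR4_GROUPS",
    "Alignment",
    "CompositionTable",
    "concat_supermatrix",
    "composition_stats",
    "rank_heterogeneous_sites",
    "chi2_trim",
    "TrimResult",
    "sr4_recode",
    "n_arsc",
    "read_fasta_alignment",
    "write_fasta_alignment",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_SKIP = {"-", "X"}

# Four-state amino-acid recoding groups (SR4), mapped onto nucleotide-letter
# stand-ins so downstream tools treat the matrix as 4-state data.
SR4_GROUPS: dict[str, str] = {"AGNPST": "A", "CHWY": "C", "DEKQR": "G", "FILMV": "T"}
_SR4_MAP = {aa: code for group, code in SR4_GROUPS.items() for aa in group}

# Side-chain nitrogen atoms per residue (backbone nitrogen excluded).
SIDECHAIN_N = {"R": 3, "H": 2, "K": 1, "N": 1, "Q": 1, "W": 1}


@dataclass
class Alignment:
    """Protein multiple alignment with optional per-gene partitions.

    ``partitions`` entries are (gene name, first column, last column),
    1-based inclusive, tiling the alignment without overlap when present.
    """

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.partitions:
            cursor = 1
            for name, start, end in self.partitions:
                if start != cursor or end < start:
                    raise ValueError(
                        f"partition {name!r} ({start}-{end}) does not tile the alignment"
                    )
                cursor = end + 1
            if cursor != self.n_columns + 1:
                raise ValueError("partitions do not cover all columns")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string over taxa."""
        return "".join(r[j] for r in self.rows)


def read_fasta_alignment(path: str | Path) -> Alignment:
    from Bio import SeqIO

    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(taxa=taxa, rows=rows)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


def _validate_alphabet(aln: Alignment) -> None:
    allowed = set(AMINO_ACIDS) | _SKIP
    for t, row in zip(aln.taxa, aln.rows):
        bad = set(row) - allowed
        if bad:
            raise ValueError(f"taxon {t!r}: invalid characters {sorted(bad)}")


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------

def concat_supermatrix(
    alignments: Sequence[Alignment],
    taxon_universe: Sequence[str],
    gene_names: Sequence[str] | None = None,
) -> Alignment:
    """Concatenate per-gene alignments into a supermatrix.

    Every taxon of ``taxon_universe`` gets one row; taxa missing from a gene
    are padded with gaps over that gene's columns.  Partitions record the
    per-gene column ranges in input order.
    """
    if not alignments:
        raise ValueError("empty alignment list")
    if gene_names is None:
        gene_names = [f"gene{i + 1}" for i in range(len(alignments))]
    rows = {t: [] for t in taxon_universe}
    partitions: list[tuple[str, int, int]] = []
    cursor = 1
    for name, aln in zip(gene_names, alignments):
        unknown = set(aln.taxa) - set(taxon_universe)
        if unknown:
            raise ValueError(f"gene {name!r}: taxa {sorted(unknown)} outside universe")
        width = aln.n_columns
        by_taxon = dict(zip(aln.taxa, aln.rows))
        for t in taxon_universe:
            rows[t].append(by_taxon.get(t, "-" * width))
        partitions.append((name, cursor, cursor + width - 1))
        cursor += width
    return Alignment(
        taxa=list(taxon_universe),
        rows=["".join(parts) for parts in rows.values()],
        partitions=partitions,
    )


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    taxa: list[str]
    frequencies: np.ndarray  # (n_taxa, 20), gap/X-excluded denominators
    chi2: np.ndarray  # (n_taxa,)
    global_mean: np.ndarray  # (20,)


def _count_matrix(aln: Alignment) -> np.ndarray:
    counts = np.zeros((aln.n_taxa, 20), dtype=float)
    for i, row in enumerate(aln.rows):
        for ch in row:
            j = _AA_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1
    return counts


def _chi2_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon chi-square vs the gap-excluded global mean composition."""
    totals = counts.sum(axis=1)
    grand = counts.sum(axis=0)
    gsum = grand.sum()
    if gsum == 0:
        raise ValueError("alignment has no residues")
    fbar = grand / gsum
    chi2 = np.zeros(len(counts))
    mask = fbar > 0
    for i in range(len(counts)):
        if totals[i] == 0:
            continue
        expected = totals[i] * fbar[mask]
        chi2[i] = np.sum((counts[i, mask] - expected) ** 2 / expected)
    return chi2, fbar


def composition_stats(aln: Alignment) -> CompositionTable:
    """Per-taxon amino-acid frequencies and chi-square heterogeneity.

    chi2 of taxon t is sum over amino acids a (with global frequency > 0) of
    (n_ta - N_t*fbar_a)^2 / (N_t*fbar_a), where N_t is the taxon's residue
    count; gaps and 'X' are excluded from every denominator.
    """
    _validate_alphabet(aln)
    counts = _count_matrix(aln)
    totals = counts.sum(axis=1)
    for t, n in zip(aln.taxa, totals):
        if n == 0:
            raise ValueError(f"taxon {t!r} has zero residues")
    chi2, fbar = _chi2_from_counts(counts)
    freqs = counts / totals[:, None]
    return CompositionTable(taxa=list(aln.taxa), frequencies=freqs, chi2=chi2, global_mean=fbar)


# ---------------------------------------------------------------------------
# Heterogeneous-site ranking and trimming
# ---------------------------------------------------------------------------

def _column_counts(aln: Alignment) -> np.ndarray:
    """Per-column per-taxon amino-acid index, -1 for gap/X: (n_taxa, n_cols)."""
    idx = np.full((aln.n_taxa, aln.n_columns), -1, dtype=np.int64)
    for i, row in enumerate(aln.rows):
        for j, ch in enumerate(row):
            k = _AA_INDEX.get(ch)
            if k is not None:
                idx[i, j] = k
    return idx


def total_heterogeneity(counts: np.ndarray) -> float:
    """H = sum of per-taxon chi-square statistics for a count matrix."""
    chi2, _ = _chi2_from_counts(counts)
    return float(chi2.sum())


def rank_heterogeneous_sites(aln: Alignment, method: str = "single_pass") -> list[int]:
    """Order columns (0-based) from most to least heterogeneity-contributing.

    ``greedy`` repeatedly removes the column whose removal most decreases
    H = sum_t chi2_t, recomputing the global mean after every removal (the
    reference semantics; quadratic in columns).  ``single_pass`` scores each
    column once from full-alignment statistics:

        score(s) = sum_t (f_{t,a(t,s)} - fbar_{a(t,s)}) / fbar_{a(t,s)}

    where a(t,s) is taxon t's residue at site s and gaps contribute 0.
    Ties break toward the lower column index.
    """
    _validate_alphabet(aln)
    if aln.n_taxa < 2 or aln.n_columns < 2:
        raise ValueError("need at least 2 taxa and 2 columns")
    idx = _column_counts(aln)
    n_cols = aln.n_columns

    if method == "single_pass":
        counts = _count_matrix(aln)
        totals = counts.sum(axis=1)
        fbar = counts.sum(axis=0) / counts.sum()
        freqs = np.divide(
            counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0
        )
        scores = np.zeros(n_cols)
        for j in range(n_cols):
            s = 0.0
            for i in range(aln.n_taxa):
                a = idx[i, j]
                if a >= 0 and fbar[a] > 0:
                    s += (freqs[i, a] - fbar[a]) / fbar[a]
            scores[j] = s
        order = sorted(range(n_cols), key=lambda j: (-scores[j], j))
        return order

    if method == "greedy":
        remaining = list(range(n_cols))
        # counts restricted to the remaining columns, updated incrementally
        counts = _count_matrix(aln)
        order: list[int] = []
        while len(remaining) > 1:
            best_j, best_h = None, None
            for j in remaining:
                trial = counts.copy()
                for i in range(aln.n_taxa):
                    a = idx[i, j]
                    if a >= 0:
                        trial[i, a] -= 1
                if trial.sum() == 0:
                    h = 0.0
                else:
                    h = total_heterogeneity(trial)
                if best_h is None or h < best_h - 1e-12 or (
                    abs(h - best_h) <= 1e-12 and j < best_j
                ):
                    best_j, best_h = j, h
            order.append(best_j)
            for i in range(aln.n_taxa):
                a = idx[i, best_j]
                if a >= 0:
                    counts[i, a] -= 1
            remaining.remove(best_j)
        order.extend(remaining)
        return order

    raise ValueError(f"unknown method {method!r}")


@dataclass
class TrimResult:
    alignment: Alignment
    removed_columns: list[int]  # 0-based original indices, removal order
    kept_columns: list[int]  # 0-based original indices, ascending
    method: str
    fraction: float


def chi2_trim(aln: Alignment, fraction: float, method: str = "single_pass") -> TrimResult:
    """Remove the floor(fraction * n_columns) most heterogeneous sites.

    Partitions are re-indexed over the surviving columns (partitions losing
    all their columns are dropped); the returned provenance maps record which
    original columns were removed and kept.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n_remove = math.floor(fraction * aln.n_columns)
    if n_remove == 0:
        kept = list(range(aln.n_columns))
        return TrimResult(
            alignment=Alignment(list(aln.taxa), list(aln.rows), aln.partitions),
            removed_columns=[],
            kept_columns=kept,
            method=method,
            fraction=fraction,
        )
    order = rank_heterogeneous_sites(aln, method=method)
    removed = order[:n_remove]
    removed_set = set(removed)
    kept = [j for j in range(aln.n_columns) if j not in removed_set]
    rows = ["".join(r[j] for j in kept) for r in aln.rows]

    partitions = None
    if aln.partitions:
        partitions = []
        cursor = 1
        for name, start, end in aln.partitions:
            width = sum(1 for j in kept if start - 1 <= j <= end - 1)
            if width > 0:
                partitions.append((name, cursor, cursor + width - 1))
                cursor += width
    return TrimResult(
        alignment=Alignment(list(aln.taxa), rows, partitions),
        removed_columns=removed,
        kept_columns=kept,
        method=method,
        fraction=fraction,
    )


def sr4_recode(aln: Alignment) -> Alignment:
    """Recode a 20-state protein alignment into the 4 SR4 groups.

    AGNPST -> A, CHWY -> C, DEKQR -> G, FILMV -> T; gaps and 'X' pass
    through unchanged.
    """
    _validate_alphabet(aln)
    rows = ["".join(_SR4_MAP.get(ch, ch) for ch in row) for row in aln.rows]
    return Alignment(taxa=list(aln.taxa), rows=rows, partitions=aln.partitions)


def n_arsc(sequence: str) -> float:
    """Mean side-chain nitrogen atoms per residue of a protein sequence.

    Gaps and 'X' are skipped; R counts 3 (guanidinium), H counts 2
    (imidazole), K/N/Q/W count 1, all others 0.
    """
    residues = [ch for ch in sequence.upper() if ch not in _SKIP]
    if not residues:
        raise ValueError("empty effective sequence")
    bad = set(residues) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)}")
    return sum(SIDECHAIN_N.get(ch, 0) for ch in residues) / len(residues)
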