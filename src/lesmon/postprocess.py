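"""Downstream characterization of significant motifs.

Covers four analyses that turn a flat list of significant motifs into an
interpretable result:

* **Families** -- significant motifs are highly redundant (a specific motif
  drags along its degenerate variants), so they are grouped by the overlap
  of their annotated protein sets, s(m1, m2) = |V1 n V2| / min(|V1|, |V2|),
  turned into a distance d = 1/s - 1 and clustered by average linkage; the
  dendrogram is cut into a target number of families (default 200) and each
  family is represented by its best-p-value member.
* **Conservation** -- the fraction of a motif's core occurrences whose
  middle position falls in a conserved element, divided by the background
  fraction of UTR bases that are conserved (fold-enrichment).
* **Strand specificity** -- ratio of forward to reverse-complement
  occurrence counts over all UTRs; an upper-tail test against Binomial(n,
  1/2) via the normal approximation (with continuity correction), BH
  adjusted.  ss >> 1 hints at an RNA-level, post-transcriptional role.
* **Term enrichment** -- one-sided Fisher's exact (hypergeometric upper
  tail) of each annotation term in the motif core against the network
  background, BH adjusted across terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "motif_distance",
    "FamilyTree",
    "build_family_tree",
    "Families",
    "cut_families",
    "ConservationAnnotation",
    "conservation_fold",
    "conserved_background_fraction",
    "read_bed",
    "StrandResult",
    "strand_specificity",
    "bh_adjust",
    "term_enrichment",
    "read_term_map",
    "DISJOINT_DISTANCE",
]

#: Distance assigned to motif pairs with disjoint protein sets (s = 0, where
#: 1/s - 1 is undefined); large but finite so average linkage stays finite.
DISJOINT_DISTANCE = 1e6


def motif_distance(v1: Set[str], v2: Set[str], disjoint_distance: float = DISJOINT_DISTANCE) -> float:
    """d(m1, m2) = 1/s - 1 with s = |V1 n V2| / min(|V1|, |V2|)."""
    if not v1 or not v2:
        raise ValueError("motif protein sets must be nonempty")
    s = len(v1 & v2) / min(len(v1), len(v2))
    if s == 0:
        return disjoint_distance
    return 1.0 / s - 1.0


@dataclass(frozen=True)
class FamilyTree:
    """Average-linkage dendrogram over motifs (protein-set overlap distance)."""

    motifs: Tuple[str, ...]
    linkage_matrix: Optional[np.ndarray]  # None for a single motif
    condensed_distances: Optional[np.ndarray]


def build_family_tree(motifs: Sequence[str], index) -> FamilyTree:
    """Agglomerative average-linkage tree on the pairwise motif distances.

    ``index`` is an :class:`~lesmon.motifs.AnnotationIndex` (or any object
    with ``proteins_of(motif)``).
    """
    motifs = tuple(motifs)
    if len(motifs) == 0:
        raise ValueError("need at least one motif")
    if len(motifs) == 1:
        return FamilyTree(motifs=motifs, linkage_matrix=None, condensed_distances=None)
    sets = [index.proteins_of(m) for m in motifs]
    n = len(motifs)
    condensed = np.empty(n * (n - 1) // 2, dtype=np.float64)
    pos = 0
    for i in range(n):
        for j in range(i + 1, n):
            condensed[pos] = motif_distance(sets[i], sets[j])
            pos += 1
    z = linkage(condensed, method="average")
    return FamilyTree(motifs=motifs, linkage_matrix=z, condensed_distances=condensed)


@dataclass(frozen=True)
class Families:
    assignments: Dict[str, int]  # motif -> family id (1-based, ordered)
    representatives: Dict[int, str]  # family id -> representative motif

    @property
    def n_families(self) -> int:
        return len(self.representatives)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "motif": m,
                "family_id": fam,
                "representative": self.representatives[fam] == m,
            }
            for m, fam in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["motif", "family_id", "representative"])


def cut_families(tree: FamilyTree, target_k: int, pvalues: Mapping[str, float]) -> Families:
    """Cut the dendrogram into exactly min(target_k, #motifs) families.

    The cut undoes the last merges of the agglomeration (rather than
    thresholding on height, which cannot always realize an exact count when
    merge heights tie).  Within each family the motif with the smallest
    clustering p-value is the representative; p-value ties break
    lexicographically on the pattern.
    """
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    motifs = tree.motifs
    n = len(motifs)
    k = min(target_k, n)
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if tree.linkage_matrix is not None:
        for step in range(n - k):  # stop agglomeration k clusters early
            a, b = int(tree.linkage_matrix[step, 0]), int(tree.linkage_matrix[step, 1])
            parent[find(a)] = n + step
            parent[find(b)] = n + step
    roots: Dict[int, List[str]] = {}
    for i, m in enumerate(motifs):
        roots.setdefault(find(i), []).append(m)
    # Deterministic family ids: order families by their lexicographically
    # smallest member motif.
    families = sorted(roots.values(), key=min)
    assignments: Dict[str, int] = {}
    representatives: Dict[int, str] = {}
    for fam_id, members in enumerate(families, start=1):
        for m in members:
            assignments[m] = fam_id
        representatives[fam_id] = min(members, key=lambda m: (pvalues[m], m))
    return Families(assignments=assignments, representatives=representatives)


# ---------------------------------------------------------------------------
# conservation


def read_bed(path) -> Dict[str, List[Tuple[int, int]]]:
    """BED3 (0-based, half-open) -> {sequence name: sorted interval list}."""
    elements: Dict[str, List[Tuple[int, int]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            start, end = int(fields[1]), int(fields[2])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            elements.setdefault(fields[0], []).append((start, end))
    for name in elements:
        elements[name].sort()
    return elements


@dataclass(frozen=True)
class ConservationAnnotation:
    n_occurrences: int
    cons_fraction: float  # Cons(m)
    background_fraction: float  # Cons(*)
    fold: float  # Cons(m) / Cons(*)
    available: bool = True


def conservation_fold(
    core_occurrences: Sequence[Tuple[str, int]],
    elements: Mapping[str, Sequence[Tuple[int, int]]],
    background_fraction: float,
    length: int,
) -> ConservationAnnotation:
    """Conservation fold-enrichment of a motif's core occurrences.

    An occurrence of a length-L motif at ``offset`` has middle position
    ``offset + L // 2`` (0-based); it counts as conserved when that single
    position lies in any element interval (half-open).  ``Cons(m)`` is the
    conserved fraction of occurrences; the fold is Cons(m) divided by the
    background fraction of UTR bases in conserved elements.
    """
    if not 0 < background_fraction <= 1:
        raise ValueError("background_fraction must be in (0, 1]")
    if len(core_occurrences) == 0:
        return ConservationAnnotation(0, float("nan"), background_fraction, float("nan"), False)
    mid_shift = length // 2
    covered = 0
    for seq_id, offset in core_occurrences:
        mid = offset + mid_shift
        for start, end in elements.get(seq_id, ()):
            if start <= mid < end:
                covered += 1
                break
    cons = covered / len(core_occurrences)
    return ConservationAnnotation(
        n_occurrences=len(core_occurrences),
        cons_fraction=cons,
        background_fraction=background_fraction,
        fold=cons / background_fraction,
    )


def conserved_background_fraction(store, elements) -> float:
    """Cons(*): fraction of all UTR bases covered by conserved elements.

    ``elements`` uses sequence-local coordinates keyed by protein (variant
    coordinates refer to the first variant unless keyed ``protein.i``).
    Intervals are clipped to the sequence and merged before counting.
    """
    total = 0
    covered = 0
    for p in store.proteins:
        seq_len = store.weight(p)
        total += seq_len
        ivals = sorted(elements.get(p, ()))
        last_end = 0
        for start, end in ivals:
            start = max(start, last_end, 0)
            end = min(end, seq_len)
            if end > start:
                covered += end - start
                last_end = end
    if total == 0:
        raise ValueError("empty UTR store")
    return covered / total


# ---------------------------------------------------------------------------
# strand specificity


@dataclass(frozen=True)
class StrandResult:
    n_forward: int
    n_reverse: int
    ratio: float  # ss = forward / reverse-complement occurrences
    pvalue: float  # upper-tail normal approx to Binomial(n, 1/2)
    adjusted_pvalue: Optional[float] = None


def strand_specificity(fwd: int, rc: int) -> StrandResult:
    """Strand specificity and its one-sided binomial test.

    Under no strand preference the forward count is Binomial(n, 1/2) with
    n = fwd + rc.  The p-value is the upper tail Pr[X >= fwd] under the
    normal approximation N(n/2, sqrt(n)/2) with continuity correction, so a
    motif occurring mostly on the reverse strand (ss < 1) gets p near 1.
    """
    if fwd < 0 or rc < 0:
        raise ValueError("counts must be non-negative")
    n = fwd + rc
    if n == 0:
        raise ValueError("both strand counts are zero")
    ratio = fwd / rc if rc > 0 else float("inf")
    p = float(stats.norm.sf(fwd - 0.5, loc=n / 2.0, scale=math.sqrt(n) / 2.0))
    return StrandResult(n_forward=fwd, n_reverse=rc, ratio=ratio, pvalue=min(p, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# term enrichment


def read_term_map(path) -> Dict[str, Set[str]]:
    """Two-column TSV (term_id, protein_id[, term_name]) -> term -> protein set."""
    term_map: Dict[str, Set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            term_map.setdefault(fields[0], set()).add(fields[1])
    return term_map


def term_enrichment(
    core: Set[str], background: Set[str], term_map: Mapping[str, Set[str]]
) -> pd.DataFrame:
    """One-sided Fisher's exact enrichment of each term in the motif core.

    For a term with K members in the background (terms with none are
    skipped) and x members in the core of size n, the p-value is the
    hypergeometric upper tail Pr[X >= x] with population |background|.
    BH-adjusted across terms.
    """
    core = set(core)
    background = set(background)
    if not core <= background:
        raise ValueError("core must be a subset of the background")
    n_bg, n_core = len(background), len(core)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & background
        if not members:
            continue
        x = len(core & members)
        p = float(stats.hypergeom.sf(x - 1, n_bg, len(members), n_core))
        rows.append(
            {
                "term": term,
                "n_term": len(members),
                "n_core": n_core,
                "n_overlap": x,
                "pvalue": min(p, 1.0),
            }
        )
    frame = pd.DataFrame(rows, columns=["term", "n_term", "n_core", "n_overlap", "pvalue"])
    if len(frame):
        frame["padj"] = bh_adjust(frame["pvalue"].to_numpy())
    else:
        frame["padj"] = np.zeros(0)
    return frame
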