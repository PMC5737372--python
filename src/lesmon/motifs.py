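"""5' UTR sequences and degenerate RNA motifs.

Motifs are strings over the seven-symbol alphabet {A, C, G, U, R, Y, N}
with R = A|G (purine), Y = C|U (pyrimidine) and N = any base.  A protein is
*annotated* with a motif when its (truncated, variant-merged) 5' UTR contains
at least one forward-strand match.  Matching is implemented with per-position
bitmasks over a 4-bit base encoding, so a motif position matches a sequence
base exactly when their masks intersect; any character outside {A, C, G, U}
gets the empty mask and can never match (this also implements the variant
separator and the masking of ambiguous input bases).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Iterator, List, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "MOTIF_ALPHABET",
    "SEPARATOR",
    "UTRStore",
    "SequencePool",
    "read_utrs",
    "enumerate_motifs",
    "match_motif",
    "reverse_complement",
    "MotifAnnotation",
    "AnnotationIndex",
    "build_annotation_index",
    "find_occurrences",
    "scramble_sequences",
]

#: Fixed symbol ordering used for enumeration.
MOTIF_ALPHABET = "ACGURYN"

#: Sentinel joining UTR variants of one protein; matches no motif symbol.
SEPARATOR = "|"

_BASE_CODE = {"A": 1, "C": 2, "G": 4, "U": 8}
SYMBOL_MASK = {"A": 1, "C": 2, "G": 4, "U": 8, "R": 1 | 4, "Y": 2 | 8, "N": 15}
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "N": "N"}

# base -> 4-bit code; anything else (N, separator, masked chars) -> 0
_CODE_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _CODE_TABLE[ord(_b)] = _c


def _encode(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _motif_masks(pattern: str) -> np.ndarray:
    try:
        return np.array([SYMBOL_MASK[s] for s in pattern], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid motif symbol {exc.args[0]!r} in {pattern!r}") from None


@dataclass(frozen=True)
class UTRStore:
    """Per-protein truncated 5' UTR sequences (RNA alphabet).

    ``records`` maps a protein identifier to the tuple of its UTR variants.
    A protein's sampling weight for the Monte Carlo null is the total length
    of its UTR (sum over variants, separator excluded).
    """

    records: Dict[str, Tuple[str, ...]]

    def __post_init__(self):
        for p, variants in self.records.items():
            if not variants or any(len(v) == 0 for v in variants):
                raise ValueError(f"protein {p!r} has an empty UTR record")

    @property
    def proteins(self) -> List[str]:
        return sorted(self.records)

    def __len__(self):
        return len(self.records)

    def __contains__(self, protein):
        return protein in self.records

    def merged(self, protein: str) -> str:
        """All variants joined with the non-matchable separator."""
        return SEPARATOR.join(self.records[protein])

    def weight(self, protein: str) -> int:
        return sum(len(v) for v in self.records[protein])

    def weights(self, order: Iterable[str]) -> np.ndarray:
        """Sampling weights aligned with ``order``; 0 for missing proteins."""
        return np.array(
            [self.weight(p) if p in self.records else 0 for p in order], dtype=np.float64
        )

    def to_fasta(self, path):
        with open(path, "wt", encoding="utf-8") as fh:
            for p in self.proteins:
                for i, variant in enumerate(self.records[p]):
                    suffix = f".{i + 1}" if len(self.records[p]) > 1 else ""
                    fh.write(f">{p}{suffix} protein={p}\n{variant}\n")


def read_utrs(fasta, truncate_to=500, merge_variants=True, id_regex=None) -> UTRStore:
    """Read 5' UTRs from FASTA into a :class:`UTRStore`.

    T is converted to U, sequences are uppercased and truncated to their
    first ``truncate_to`` bases (the region immediately downstream of the
    transcription start site, robust to uncertain start-codon annotation).
    The protein identifier is the first whitespace token of the header, or
    the first group of ``id_regex`` when given.  With ``merge_variants``
    multiple records of one protein are kept as separate variants whose
    union is associated with the protein; matching never crosses variants.
    Empty records are dropped with a warning.
    """
    import re

    if truncate_to < 1:
        raise ValueError("truncate_to must be >= 1")
    collected: Dict[str, List[str]] = {}
    for record in SeqIO.parse(str(fasta), "fasta"):
        if id_regex is not None:
            m = re.search(id_regex, record.description)
            if m is None:
                logger.warning("header %r does not match id_regex; dropped", record.id)
                continue
            protein = m.group(1)
        else:
            protein = record.id
        seq = str(record.seq).upper().replace("T", "U")[:truncate_to]
        if not seq:
            logger.warning("empty record for protein %r dropped", protein)
            continue
        if protein in collected and not merge_variants:
            logger.warning("duplicate record for %r (merge_variants off); kept first", protein)
            continue
        collected.setdefault(protein, []).append(seq)
    return UTRStore(records={p: tuple(v) for p, v in collected.items()})


def enumerate_motifs(length: int, alphabet: str = MOTIF_ALPHABET) -> Iterator[str]:
    """Yield all ``|alphabet| ** length`` motifs once, in lexicographic order
    of the fixed symbol ordering (A, C, G, U, R, Y, N by default)."""
    if length < 1:
        raise ValueError("motif length must be >= 1")
    for tup in itertools.product(alphabet, repeat=length):
        yield "".join(tup)


def match_motif(pattern: str, seq: str) -> List[int]:
    """All (possibly overlapping) 0-based offsets where ``pattern`` matches
    ``seq`` on the forward strand."""
    masks = _motif_masks(pattern)
    L, n = len(masks), len(seq)
    if n < L:
        return []
    codes = _encode(seq)
    hits = np.ones(n - L + 1, dtype=bool)
    for j, mask in enumerate(masks):
        hits &= (codes[j : n - L + 1 + j] & mask) != 0
    return [int(i) for i in np.flatnonzero(hits)]


def reverse_complement(pattern: str) -> str:
    """Reverse complement in RNA space (A<->U, C<->G, R<->Y, N<->N)."""
    try:
        return "".join(_COMPLEMENT[s] for s in reversed(pattern))
    except KeyError as exc:
        raise ValueError(f"invalid motif symbol {exc.args[0]!r}") from None


class SequencePool:
    """All UTR variants concatenated into one code array for fast scanning.

    A zero (non-matchable) code separates consecutive variants, so no match
    can span a variant or protein boundary.  Scanning the pool once per
    motif replaces a per-sequence Python loop.
    """

    def __init__(self, store: UTRStore):
        self.store = store
        self.proteins = store.proteins
        codes: List[np.ndarray] = []
        starts: List[int] = []
        seg_protein: List[int] = []
        seg_variant: List[int] = []
        pos = 0
        for pi, p in enumerate(self.proteins):
            for vi, variant in enumerate(store.records[p]):
                starts.append(pos)
                seg_protein.append(pi)
                seg_variant.append(vi)
                codes.append(_encode(variant))
                pos += len(variant)
                codes.append(np.zeros(1, dtype=np.uint8))
                pos += 1
        self.codes = np.concatenate(codes) if codes else np.zeros(0, dtype=np.uint8)
        self.seg_start = np.array(starts, dtype=np.int64)
        self.seg_protein = np.array(seg_protein, dtype=np.int64)
        self.seg_variant = np.array(seg_variant, dtype=np.int64)

    def scan(self, pattern: str) -> np.ndarray:
        """Global offsets (into the pooled code array) of all matches."""
        masks = _motif_masks(pattern)
        L, n = len(masks), len(self.codes)
        if n < L:
            return np.zeros(0, dtype=np.int64)
        hits = (self.codes[: n - L + 1] & masks[0]) != 0
        for j in range(1, L):
            hits &= (self.codes[j : n - L + 1 + j] & masks[j]) != 0
        return np.flatnonzero(hits)

    def occurrences(self, pattern: str):
        """Matches as (protein, variant index, 0-based variant-local offset)."""
        global_offsets = self.scan(pattern)
        seg = np.searchsorted(self.seg_start, global_offsets, side="right") - 1
        out = []
        for g, s in zip(global_offsets, seg):
            out.append(
                (
                    self.proteins[self.seg_protein[s]],
                    int(self.seg_variant[s]),
                    int(g - self.seg_start[s]),
                )
            )
        return out

    def annotate(self, pattern: str):
        """(set of matched proteins, forward occurrence count)."""
        global_offsets = self.scan(pattern)
        if len(global_offsets) == 0:
            return frozenset(), 0
        seg = np.searchsorted(self.seg_start, global_offsets, side="right") - 1
        prot_idx = np.unique(self.seg_protein[seg])
        return frozenset(self.proteins[i] for i in prot_idx), int(len(global_offsets))


@dataclass(frozen=True)
class MotifAnnotation:
    proteins: FrozenSet[str]
    n_occurrences_fwd: int
    n_occurrences_rc: int
    excluded: bool  # |V_m| above the significance cutoff


@dataclass
class AnnotationIndex:
    """Motif -> annotated protein set V_m plus strand occurrence totals."""

    entries: Dict[str, MotifAnnotation]
    max_proteins: int

    def __len__(self):
        return len(self.entries)

    def __contains__(self, motif):
        return motif in self.entries

    def proteins_of(self, motif) -> FrozenSet[str]:
        return self.entries[motif].proteins

    def assessable_motifs(self) -> List[str]:
        return sorted(m for m, e in self.entries.items() if not e.excluded)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "motif": m,
                "n_proteins": len(e.proteins),
                "n_occurrences_fwd": e.n_occurrences_fwd,
                "n_occurrences_rc": e.n_occurrences_rc,
                "excluded": e.excluded,
            }
            for m, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["motif", "n_proteins", "n_occurrences_fwd", "n_occurrences_rc", "excluded"],
        )

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_annotation_index(
    store: UTRStore, motifs: Iterable[str], max_proteins: int = 1500
) -> AnnotationIndex:
    """Annotate proteins with each motif and count strand occurrences.

    A protein enters V_m on at least one forward-strand match; overlapping
    occurrences all count toward the occurrence totals.  Motifs annotating
    more than ``max_proteins`` proteins are flagged excluded from
    significance assessment (they are mostly degenerate and computationally
    prohibitive) but keep their occurrence counts; motifs with no annotated
    protein are dropped.
    """
    if len(store) == 0:
        raise ValueError("empty UTR store")
    pool = SequencePool(store)
    entries: Dict[str, MotifAnnotation] = {}
    for motif in motifs:
        proteins, n_fwd = pool.annotate(motif)
        if not proteins:
            continue
        n_rc = int(len(pool.scan(reverse_complement(motif))))
        entries[motif] = MotifAnnotation(
            proteins=proteins,
            n_occurrences_fwd=n_fwd,
            n_occurrences_rc=n_rc,
            excluded=len(proteins) > max_proteins,
        )
    return AnnotationIndex(entries=entries, max_proteins=max_proteins)


def find_occurrences(store: UTRStore, pattern: str):
    """Forward-strand matches as (protein, variant index, offset) triples."""
    return SequencePool(store).occurrences(pattern)


def scramble_sequences(store: UTRStore, window: int = 10, seed: int = 0) -> UTRStore:
    """Locally scrambled decoy UTRs.

    Each variant's bases are permuted independently within consecutive
    non-overlapping windows of ``window`` nucleotides (a final partial
    window is permuted within itself), preserving local composition such as
    GC content.  Deterministic for a given seed; proteins are processed in
    sorted order.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rng = np.random.default_rng(seed)
    records: Dict[str, Tuple[str, ...]] = {}
    for p in store.proteins:
        variants = []
        for variant in store.records[p]:
            chars = np.frombuffer(variant.encode("ascii"), dtype=np.uint8).copy()
            for start in range(0, len(chars), window):
                chunk = chars[start : start + window]
                chars[start : start + window] = rng.permutation(chunk)
            variants.append(chars.tobytes().decode("ascii"))
        records[p] = tuple(variants)
    return UTRStore(records=records)
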