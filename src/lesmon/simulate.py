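"""Seeded synthetic fixtures: network, UTRs, conservation track, term map.

The generator emulates the statistical structure the pipeline assumes: an
Erdos-Renyi background interaction network with one planted dense module, a
random-composition 5' UTR per protein with a degenerate motif planted
preferentially in module members, a conservation track that covers planted
occurrence midpoints at a controlled rate, and a term map marking module
membership.  Everything is deterministic per seed, and all outputs
round-trip through the package's readers (plain-text FASTA / edge list /
BED3 / TSV).

Defaults mirror the planted-recovery study conditions used throughout the
test suite: 500 proteins, background edge probability 0.01 versus 0.5
inside a 30-protein module, plant rate 0.8 inside versus 0.02 outside.
Degenerate positions of the planted motif are re-instantiated uniformly per
insertion, so the planted signal matches the degenerate pattern without
being a single literal string -- the way real degenerate motifs behave.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Set, Tuple

import networkx as nx
import numpy as np

from .motifs import SYMBOL_MASK, UTRStore

__all__ = ["FixtureSpec", "PlantedOccurrence", "Fixture", "generate_fixture",
           "generate_null_fixture", "write_fixture"]

_CLASS_BASES = {"A": "A", "C": "C", "G": "G", "U": "U", "R": "AG", "Y": "CU", "N": "ACGU"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset (see module docstring)."""

    n_proteins: int = 500
    edge_p: float = 0.01
    module_size: int = 30
    module_edge_p: float = 0.5
    utr_length_min: int = 200
    utr_length_max: int = 500
    composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A C G U
    planted_motif: str = "NNCGCYAU"
    plant_rate_inside: float = 0.8
    plant_rate_outside: float = 0.02
    cons_cover_planted: float = 0.9  # chance a planted midpoint gets an element
    cons_background: float = 0.1  # target background conserved base fraction
    n_background_terms: int = 5
    seed: int = 0

    def validate(self):
        probs = [
            self.edge_p, self.module_edge_p, self.plant_rate_inside,
            self.plant_rate_outside, self.cons_cover_planted, self.cons_background,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0 < self.module_size <= self.n_proteins:
            raise ValueError("module_size must be in 1..n_proteins")
        if not 8 <= self.utr_length_min <= self.utr_length_max:
            raise ValueError("need utr_length_min >= motif-scale and <= utr_length_max")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if any(s not in SYMBOL_MASK for s in self.planted_motif):
            raise ValueError(f"invalid planted motif {self.planted_motif!r}")


@dataclass(frozen=True)
class PlantedOccurrence:
    protein: str
    offset: int  # 0-based, within the (single-variant) UTR
    instance: str  # the literal string inserted


@dataclass
class Fixture:
    spec: FixtureSpec
    network: nx.Graph
    store: UTRStore
    elements: Dict[str, List[Tuple[int, int]]]  # protein -> conserved intervals
    terms: Dict[str, Set[str]]
    module: Tuple[str, ...]
    truth: Tuple[PlantedOccurrence, ...]


def _protein_ids(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _instantiate(pattern: str, rng) -> str:
    """Resolve each degenerate symbol uniformly within its base class."""
    return "".join(
        bases if len(bases) == 1 else bases[rng.integers(len(bases))]
        for bases in (_CLASS_BASES[s] for s in pattern)
    )


def _build_network(spec: FixtureSpec, ids: List[str], module: List[str], rng) -> nx.Graph:
    n = spec.n_proteins
    net = nx.Graph()
    net.add_nodes_from(ids)
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < spec.edge_p
    module_idx = {ids.index(m) for m in module}
    in_module = np.array([i in module_idx and j in module_idx for i, j in zip(iu, ju)])
    present |= in_module & (rng.random(len(iu)) < spec.module_edge_p)
    for i, j in zip(iu[present], ju[present]):
        net.add_edge(ids[i], ids[j])
    # connectivity repair: join each stray component to a uniformly chosen
    # node of the largest component (seeded, hence deterministic)
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    if len(comps) > 1:
        main = sorted(comps[0])
        for comp in comps[1:]:
            u = sorted(comp)[rng.integers(len(comp))]
            v = main[rng.integers(len(main))]
            net.add_edge(u, v)
    return net


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate one synthetic dataset; fully deterministic per ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = _protein_ids(spec.n_proteins)
    module = sorted(rng.choice(spec.n_proteins, size=spec.module_size, replace=False))
    module_ids = [ids[i] for i in module]
    net = _build_network(spec, ids, module_ids, rng)

    # UTR sequences with planted occurrences
    bases = np.array(list("ACGU"))
    comp = np.asarray(spec.composition)
    module_set = set(module_ids)
    records: Dict[str, Tuple[str, ...]] = {}
    truth: List[PlantedOccurrence] = []
    motif_len = len(spec.planted_motif)
    for p in ids:
        length = int(rng.integers(spec.utr_length_min, spec.utr_length_max + 1))
        seq = rng.choice(bases, size=length, p=comp)
        rate = spec.plant_rate_inside if p in module_set else spec.plant_rate_outside
        if rate > 0 and rng.random() < rate:
            instance = _instantiate(spec.planted_motif, rng)
            offset = int(rng.integers(0, length - motif_len + 1))
            seq[offset : offset + motif_len] = list(instance)
            truth.append(PlantedOccurrence(protein=p, offset=offset, instance=instance))
        records[p] = ("".join(seq),)
    store = UTRStore(records=records)

    # conservation track: elements over planted midpoints + random background
    elements: Dict[str, List[Tuple[int, int]]] = {}
    planted_by_protein = {occ.protein: occ for occ in truth}
    elem_len = 20
    for p in ids:
        seq_len = store.weight(p)
        ivals: List[Tuple[int, int]] = []
        occ = planted_by_protein.get(p)
        if occ is not None and rng.random() < spec.cons_cover_planted:
            mid = occ.offset + motif_len // 2
            start = max(0, mid - 4)
            ivals.append((start, min(seq_len, start + 9)))
        n_bg = rng.poisson(seq_len * spec.cons_background / elem_len)
        for _ in range(n_bg):
            start = int(rng.integers(0, max(1, seq_len - elem_len + 1)))
            ivals.append((start, min(seq_len, start + elem_len)))
        if ivals:
            elements[p] = sorted(ivals)

    # term map: the planted module plus random background terms
    terms: Dict[str, Set[str]] = {"planted_module": set(module_ids)}
    for t in range(spec.n_background_terms):
        size = int(rng.integers(10, 51))
        members = rng.choice(spec.n_proteins, size=size, replace=False)
        terms[f"random_term_{t + 1}"] = {ids[i] for i in members}

    return Fixture(
        spec=spec,
        network=net,
        store=store,
        elements=elements,
        terms=terms,
        module=tuple(module_ids),
        truth=tuple(truth),
    )


def generate_null_fixture(spec: FixtureSpec) -> Fixture:
    """Same generator with plant rates forced to zero (no signal anywhere);
    used for p-value uniformity and decoy-FDR calibration."""
    return generate_fixture(replace(spec, plant_rate_inside=0.0, plant_rate_outside=0.0))


def write_fixture(fixture: Fixture, outdir) -> Dict[str, Path]:
    """Write the fixture as plain-text standard formats.

    Emits ``edges.tsv`` (two-column edge list), ``utrs.fasta``,
    ``conserved.bed`` (BED3, sequence-local coordinates keyed by protein),
    ``terms.tsv`` and ``truth.tsv``.  Output is byte-deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("edges", "edges.tsv"), ("fasta", "utrs.fasta"), ("bed", "conserved.bed"),
        ("terms", "terms.tsv"), ("truth", "truth.tsv"),
    ]}
    with open(paths["edges"], "wt", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in fixture.network.edges):
            fh.write(f"{u}\t{v}\n")
    fixture.store.to_fasta(paths["fasta"])
    with open(paths["bed"], "wt", encoding="utf-8") as fh:
        for p in sorted(fixture.elements):
            for start, end in fixture.elements[p]:
                fh.write(f"{p}\t{start}\t{end}\n")
    with open(paths["terms"], "wt", encoding="utf-8") as fh:
        for term in sorted(fixture.terms):
            for p in sorted(fixture.terms[term]):
                fh.write(f"{term}\t{p}\n")
    with open(paths["truth"], "wt", encoding="utf-8") as fh:
        fh.write("protein\toffset\tinstance\n")
        for occ in sorted(fixture.truth, key=lambda o: o.protein):
            fh.write(f"{occ.protein}\t{occ.offset}\t{occ.instance}\n")
    return paths
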