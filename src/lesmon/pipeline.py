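"""End-to-end motif discovery pipeline.

Stages: read and clean the network -> all-pairs distances -> read UTRs ->
enumerate / sample candidate motifs -> annotation index -> TPPD and
clustering p-value per assessable motif -> identical pass on locally
scrambled decoy sequences -> FDR table -> family clustering of significant
motifs -> conservation / strand-specificity / term-enrichment annotation of
family representatives.  All outputs are TSV plus a JSON run manifest; a
rerun with the same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import tppd
from .motifs import (
    AnnotationIndex,
    MOTIF_ALPHABET,
    SequencePool,
    build_annotation_index,
    enumerate_motifs,
    read_utrs,
    scramble_sequences,
)
from .network import (
    all_pairs_shortest_paths,
    largest_connected_component,
    network_hash,
    read_edge_list,
    remove_hubs,
)
from .postprocess import (
    bh_adjust,
    build_family_tree,
    conservation_fold,
    conserved_background_fraction,
    cut_families,
    read_bed,
    read_term_map,
    strand_specificity,
    term_enrichment,
)
from .significance import MotifNotAssessed, NullModel, compute_fdr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "score_motifs", "candidate_motifs"]


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the method's standard settings."""

    network_path: Optional[str] = None
    fasta_path: Optional[str] = None
    bed_path: Optional[str] = None
    terms_path: Optional[str] = None
    output_dir: str = "lesmon_out"
    network_format: str = "plain"
    biogrid_columns: Tuple[str, str] = (
        "Official Symbol Interactor A",
        "Official Symbol Interactor B",
    )
    motif_length: int = 8
    alphabet: str = MOTIF_ALPHABET
    truncate_to: int = 500
    max_degree: int = 1000
    max_proteins: int = 1500
    top_fraction: float = 0.1
    mc_samples_small: int = 10**6
    mc_samples_large: int = 10**5
    k_switch: int = 300
    k_max: int = 1500
    scramble_window: int = 10
    target_families: int = 200
    significance_threshold: float = 1e-6
    # Candidate-motif control: the full 7^8 space is supported in principle
    # but desk-scale runs enumerate exhaustively only up to
    # ``enumerate_limit`` patterns; above that a seeded random sample of
    # ``n_motif_sample`` patterns (plus ``extra_motifs``) is scored.
    enumerate_limit: int = 100_000
    n_motif_sample: int = 200
    extra_motifs: Tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "extra_motifs" in raw and raw["extra_motifs"] is not None:
            raw["extra_motifs"] = tuple(raw["extra_motifs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extra_motifs"] = list(d["extra_motifs"])
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    results: pd.DataFrame  # motif, n_proteins, tppd, pvalue, regime
    fdr_table: pd.DataFrame
    families: pd.DataFrame
    annotations: pd.DataFrame
    manifest: dict
    output_dir: Optional[Path] = None


def candidate_motifs(config: RunConfig) -> List[str]:
    """The motif set to score: full enumeration when the space is small
    enough, otherwise a seeded uniform sample, always including
    ``extra_motifs``."""
    space = len(config.alphabet) ** config.motif_length
    if space <= config.enumerate_limit:
        motifs = list(enumerate_motifs(config.motif_length, config.alphabet))
    else:
        if config.n_motif_sample < 1:
            raise ValueError(
                f"motif space of {space} exceeds enumerate_limit="
                f"{config.enumerate_limit}; set n_motif_sample or extra_motifs"
            )
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
        alphabet = np.array(list(config.alphabet))
        draws = rng.integers(0, len(alphabet), size=(config.n_motif_sample, config.motif_length))
        motifs = sorted({"".join(alphabet[row]) for row in draws})
    seen = set(motifs)
    for m in config.extra_motifs:
        if m not in seen:
            motifs.append(m)
            seen.add(m)
    return motifs


def score_motifs(
    dist, index: AnnotationIndex, null: NullModel
) -> pd.DataFrame:
    """TPPD, core and clustering p-value for every motif in the index.

    Motifs flagged excluded or annotating fewer than 2 network proteins are
    reported with regime "not-assessed" and no p-value.
    """
    network_nodes = set(dist.nodes)
    rows = []
    for motif in sorted(index.entries):
        entry = index.entries[motif]
        members = entry.proteins & network_nodes
        k = len(members)
        if entry.excluded or k < 2:
            rows.append(
                {"motif": motif, "n_proteins": k, "tppd": np.nan,
                 "pvalue": np.nan, "regime": "not-assessed"}
            )
            continue
        result = tppd(dist, members, null.top_fraction)
        try:
            p = null.pvalue(result.statistic, k)
            regime = null.regime(k)
        except MotifNotAssessed:
            p, regime = np.nan, "not-assessed"
        rows.append(
            {"motif": motif, "n_proteins": k, "tppd": result.statistic,
             "pvalue": p, "regime": regime}
        )
    return pd.DataFrame(rows, columns=["motif", "n_proteins", "tppd", "pvalue", "regime"])


def _cores_and_occurrences(dist, store, index, motifs, top_fraction):
    """Per-motif core protein set and core occurrences for conservation."""
    network_nodes = set(dist.nodes)
    cores: Dict[str, frozenset] = {}
    occurrences: Dict[str, List[Tuple[str, int]]] = {}
    pool = SequencePool(store)
    for motif in motifs:
        members = index.proteins_of(motif) & network_nodes
        if len(members) < 2:
            continue
        core = frozenset(tppd(dist, members, top_fraction).core)
        cores[motif] = core
        occurrences[motif] = [
            (protein, offset)
            for protein, _variant, offset in pool.occurrences(motif)
            if protein in core
        ]
    return cores, occurrences


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline per ``config``; see module docstring."""
    stage = "network"
    try:
        net = read_edge_list(config.network_path, fmt=config.network_format,
                             biogrid_columns=tuple(config.biogrid_columns))
        net = remove_hubs(net, config.max_degree)
        net = largest_connected_component(net)
        dist = all_pairs_shortest_paths(net)

        stage = "utrs"
        store = read_utrs(config.fasta_path, truncate_to=config.truncate_to)

        stage = "motifs"
        motifs = candidate_motifs(config)
        index = build_annotation_index(store, motifs, config.max_proteins)

        stage = "significance"
        weights = store.weights(dist.nodes)
        null = NullModel(
            dist=dist,
            weights=weights,
            top_fraction=config.top_fraction,
            k_switch=config.k_switch,
            k_max=config.k_max,
            mc_samples_small=config.mc_samples_small,
            mc_samples_large=config.mc_samples_large,
            seed=config.seed,
        )
        results = score_motifs(dist, index, null)

        stage = "decoy"
        decoy_store = scramble_sequences(
            store, window=config.scramble_window,
            seed=np.random.SeedSequence(config.seed, spawn_key=(2,)),
        )
        decoy_index = build_annotation_index(decoy_store, motifs, config.max_proteins)
        # The network and sampling weights are untouched by scrambling, so
        # the decoy pass reuses the real null model.
        decoy_results = score_motifs(dist, decoy_index, null)

        stage = "fdr"
        real_p = results["pvalue"].dropna().to_numpy()
        decoy_p = decoy_results["pvalue"].dropna().to_numpy()
        fdr_table = compute_fdr(real_p, decoy_p).to_frame()

        stage = "families"
        significant = results[results["pvalue"] < config.significance_threshold]
        sig_motifs = sorted(significant["motif"])
        pvalues = dict(zip(results["motif"], results["pvalue"]))
        if sig_motifs:
            tree = build_family_tree(sig_motifs, index)
            families = cut_families(tree, config.target_families, pvalues).to_frame()
        else:
            families = pd.DataFrame(columns=["motif", "family_id", "representative"])

        stage = "annotation"
        representatives = sorted(families.loc[families["representative"], "motif"]) \
            if len(families) else []
        annotations = _annotate_representatives(config, dist, store, index, representatives)

        stage = "write"
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "network_nodes": int(net.number_of_nodes()),
            "network_edges": int(net.number_of_edges()),
            "network_hash": network_hash(net),
            "n_proteins_with_utr": len(store),
            "n_candidate_motifs": len(motifs),
            "n_annotated_motifs": len(index),
            "n_assessed_motifs": int(results["pvalue"].notna().sum()),
            "n_significant_motifs": len(sig_motifs),
        }
        result = PipelineResult(
            config=config, results=results, fdr_table=fdr_table,
            families=families, annotations=annotations, manifest=manifest,
        )
        if config.output_dir:
            result.output_dir = _write_outputs(result, decoy_results)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _annotate_representatives(config, dist, store, index, representatives) -> pd.DataFrame:
    columns = ["motif", "cons_fraction", "cons_fold", "ss", "ss_pvalue", "ss_padj"]
    if not representatives:
        return pd.DataFrame(columns=columns)
    elements = read_bed(config.bed_path) if config.bed_path else {}
    background_fraction = (
        conserved_background_fraction(store, elements) if elements else np.nan
    )
    cores, occurrences = _cores_and_occurrences(
        dist, store, index, representatives, config.top_fraction
    )
    rows = []
    for motif in representatives:
        entry = index.entries[motif]
        if elements and occurrences.get(motif):
            cons = conservation_fold(
                occurrences[motif], elements, background_fraction, len(motif)
            )
            cons_fraction, cons_fold = cons.cons_fraction, cons.fold
        else:
            cons_fraction = cons_fold = np.nan
        ss = strand_specificity(entry.n_occurrences_fwd, entry.n_occurrences_rc) \
            if entry.n_occurrences_fwd + entry.n_occurrences_rc > 0 else None
        rows.append(
            {"motif": motif, "cons_fraction": cons_fraction, "cons_fold": cons_fold,
             "ss": ss.ratio if ss else np.nan,
             "ss_pvalue": ss.pvalue if ss else np.nan, "ss_padj": np.nan}
        )
    frame = pd.DataFrame(rows, columns=columns)
    assessed = frame["ss_pvalue"].notna()
    if assessed.any():
        frame.loc[assessed, "ss_padj"] = bh_adjust(frame.loc[assessed, "ss_pvalue"].to_numpy())
    if config.terms_path:
        term_map = read_term_map(config.terms_path)
        background = set(store.proteins) & set(dist.nodes)
        enrich_frames = []
        for motif in representatives:
            core = cores.get(motif)
            if not core:
                continue
            enr = term_enrichment(set(core) & background, background, term_map)
            enr.insert(0, "motif", motif)
            enrich_frames.append(enr)
        frame.attrs["enrichment"] = (
            pd.concat(enrich_frames, ignore_index=True) if enrich_frames
            else pd.DataFrame(columns=["motif", "term", "n_term", "n_core", "n_overlap",
                                       "pvalue", "padj"])
        )
    return frame


def _write_outputs(result: PipelineResult, decoy_results: pd.DataFrame) -> Path:
    outdir = Path(result.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    kw = dict(sep="\t", index=False, float_format="%.6g")
    result.results.to_csv(outdir / "results.tsv", **kw)
    decoy_results.to_csv(outdir / "decoy_results.tsv", **kw)
    result.fdr_table.to_csv(outdir / "fdr.tsv", **kw)
    result.families.to_csv(outdir / "families.tsv", **kw)
    result.annotations.to_csv(outdir / "annotations.tsv", **kw)
    enrichment = result.annotations.attrs.get("enrichment")
    if enrichment is not None:
        enrichment.to_csv(outdir / "enrichment.tsv", **kw)
    manifest = dict(result.manifest)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(result.config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
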