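# lesmon

Network-guided discovery of 5′ UTR sequence motifs.

`lesmon` finds short degenerate RNA motifs whose carrier proteins form
unexpectedly dense clusters in a protein–protein interaction (PPI) network.
The premise: if the proteins whose 5′ UTRs share a motif interact far more
tightly than chance predicts, the motif is probably tied to the biological
process that clusters them — a post-transcriptional regulatory element, a
5′ TOP-like translation signal, or a DNA-level element in the UTR's genomic
footprint.

## Who it is for

Computational biologists with (1) an undirected PPI network (edge list or a
BioGRID tab export) and (2) per-protein 5′ UTR sequences (FASTA).  Optional
extras: a conserved-element track (BED3) and a term→gene annotation table
(TSV) for downstream characterization.

## The method

For a motif *m* over the alphabet {A, C, G, U, R, Y, N} (R = A|G, Y = C|U,
N = any), let *V<sub>m</sub>* be the proteins whose truncated 5′ UTR
(first 500 nt) contains a forward-strand match.  Clustering of
*V<sub>m</sub>* in the network *G* is scored by the **top percent pairwise
distance (TPPD)** with core size *l* = 0.1·|*V<sub>m</sub>*| (rounded,
floored at 1, capped at |*V<sub>m</sub>*|−1):

- *D<sup>l</sup>(u)* = sum of the *l* smallest hop distances from *u* to
  other members of *V<sub>m</sub>*;
- core(*V<sub>m</sub>*) = the *l* members with smallest *D*;
- TPPD(*V<sub>m</sub>*) = Σ<sub>u∈core</sub> *D<sup>l</sup>(u)*.

Small TPPD = a tight cluster of at least *l* carriers, robust to the
non-functional motif occurrences that scatter the rest of *V<sub>m</sub>*.

Significance: the null statistic *S<sub>k</sub>* is the TPPD of a random
*k*-set drawn with probability proportional to UTR length (longer UTRs
match more motifs by chance).  *P*(m) = Pr[*S<sub>|V<sub>m</sub>|</sub>* ≤
TPPD(*V<sub>m</sub>*)], estimated empirically by Monte Carlo for
|*V<sub>m</sub>*| ≤ 300 (10⁶ draws by default) and by a Monte Carlo-fitted
normal approximation for 301–1500; larger sets are not assessed.  Multiple
testing over the ~5.8 million motif space is controlled by an empirical
FDR: re-run the identical pipeline on decoy UTRs whose bases are permuted
within 10-nt windows (preserving local composition) and report
FDR(p) = N(p)/M(p), the decoy/real count ratio.  Significant motifs are
grouped into families by carrier-set overlap
(s = |V₁∩V₂|/min(|V₁|,|V₂|), d = 1/s − 1, average linkage, cut to 200
families), and each family representative is annotated with conservation
fold-enrichment, strand specificity, and term enrichment of its core.

## Worked example

Generate a synthetic dataset with a planted module and run the pipeline on
it (everything is seeded and reproducible):

```bash
lesmon simulate --seed 11 --out fixture/
cat > config.yaml <<EOF
network_path: fixture/edges.tsv
fasta_path: fixture/utrs.fasta
bed_path: fixture/conserved.bed
terms_path: fixture/terms.tsv
output_dir: run/
n_motif_sample: 60
extra_motifs: [NNCGCYAU]
mc_samples_small: 2000
mc_samples_large: 2000
significance_threshold: 1.0e-3
target_families: 5
seed: 5
EOF
lesmon run --config config.yaml
```

The fixture plants the degenerate motif `NNCGCYAU` into 80% of a dense
30-protein module (and 2% of the other 470 proteins).  `run/results.tsv`
then contains, for the planted motif:

```
motif     n_proteins  tppd  pvalue       regime
NNCGCYAU  99          100   4.23719e-14  empirical
```

99 carrier proteins whose 10-member core achieves the minimum possible
TPPD of 100 (= l², a perfect distance-1 core): none of the 2000 Monte
Carlo draws comes close, so the p-value falls back to the fitted normal
tail.  98% of the 60 unplanted control motifs score p ≥ 0.05.
`families.tsv` makes `NNCGCYAU` the representative of its own family, and
`annotations.tsv` reports a conservation fold-enrichment of 9.11 (90% of
core occurrence midpoints are in conserved elements vs a ~10% background)
and strand specificity 1.23; `enrichment.tsv` shows the core is enriched
for the planted module term at p = 1.2×10⁻¹³.

Python API mirroring the same flow:

```python
from lesmon import (FixtureSpec, generate_fixture, all_pairs_shortest_paths,
                    build_annotation_index, tppd, NullModel)

fix = generate_fixture(FixtureSpec(seed=11))
dist = all_pairs_shortest_paths(fix.network)
index = build_annotation_index(fix.store, ["NNCGCYAU"])
members = index.proteins_of("NNCGCYAU")
null = NullModel(dist=dist, weights=fix.store.weights(dist.nodes),
                 mc_samples_small=10_000, seed=1)
print(null.pvalue(tppd(dist, members).statistic, len(members)))
```

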