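# ligsel

Analysis toolkit for **ligand-selective early B cell activation**:
how the transcriptional landscape of resting splenic B cells diverges
within two hours of stimulation through the B cell receptor (BCR,
anti-IgM) versus TLR4 (LPS).  The package is aimed at computational
biologists working with TSS-anchored ChIP-seq coverage and normalized
expression tables who want the full pipeline — gene-set definition
through chromatin readouts — as tested, scriptable components.

## What it computes

* **Gene-set classification** from a normalized expression table.  With
  fold change `f = (stim + c)/(rest + c)` and twofold threshold `t = 2`
  (boundary inclusive), a gene changed by exactly one response is
  *preferential*; a gene changed by both is still preferential when the
  non-preferred fold lies in `[t, t²]` and the preferred fold is at
  least `t` times it, otherwise *shared*; genes changed by neither are
  *unchanged* (or *low_expressed* below a resting minimum).
* **Metagene profiles**: strand-aware per-offset mean RPM around TSSs
  (±2 kb for Pol II/H3K4me3, ±4 kb for H3K27me3), anchored at every
  transcript TSS or at the TSS with the highest Pol II occupancy, plus
  ±1 kb per-gene sums compared across conditions with the Wilcoxon
  rank-sum test.
* **Traveling ratio**: `TR = RPM_body / RPM_promoter` with promoter
  −300..+300 and body +301..+2250 bp, taken on set-level means and
  reported normalized to rest (`TR_activation / TR_rest`).  Low TR =
  promoter-paused Pol II (the BCR signature); high TR = transition to
  elongation (the LPS signature).
* **Promoter motif enrichment**: log-odds PWM scanning of −1000/+1000
  promoters, ZOOPS counting, upper-tail hypergeometric p against the
  unchanged-gene background, and lowest-30-p overlap comparisons.
* **miRNA categorization** by the plain twofold rule per stimulation,
  including the opposing-direction categories.
* **CpG-island proximity**: a promoter is CpG-associated when its TSS
  is inside or within 200 bp of an island.
* **A seeded synthetic-data generator** producing annotation (GTF /
  BED12), nine bedGraph coverage tracks (Pol II, H3K4me3, H3K27me3 ×
  rest/BCR/LPS), expression and miRNA tables, a genome FASTA with
  planted promoter motifs, a PWM library, CpG islands, and the ground
  truth — so every stage is testable without external downloads.

See `docs/methods.md` for the models, parameter defaults and design
choices.

## Worked example

```python
from ligsel import (SimConfig, generate_dataset, classify_table,
                    traveling_ratio, normalize_tr)

cfg = SimConfig(seed=1, library_size=2e6)   # 240 genes, 4 planted classes
ds = generate_dataset(cfg)

print(classify_table(ds.expression)["label"].value_counts().to_string())

sets = {c: [g for g in ds.genes if ds.truth.gene_class[g.gene_id] == c]
        for c in ("bcr_pref_up", "lps_pref_up")}
for cls, genes in sets.items():
    rest = traveling_ratio(ds.tracks["polII_rest"], genes)
    for cond in ("BCR", "LPS"):
        r = traveling_ratio(ds.tracks[f"polII_{cond}"], genes)
        print(f"{cls:12s} {cond}: TR={r.tr:.3f} "
              f"TR/TRrest={normalize_tr(r.tr, rest.tr):.2f}")
```

prints

```
label
lps_pref_up      79
bcr_pref_up      67
unchanged        39
shared_up        35
lps_pref_down    10
bcr_pref_down    10
bcr_pref_up  BCR: TR=0.057 TR/TRrest=0.64
bcr_pref_up  LPS: TR=0.089 TR/TRrest=1.00
lps_pref_up  BCR: TR=0.073 TR/TRrest=0.88
lps_pref_up  LPS: TR=0.143 TR/TRrest=1.73
```

The classifier recovers the four planted 60-gene classes (the spillover
between neighbouring labels comes from the negative-binomial noise; at
dispersion 0 recovery is exact).  The traveling ratios show the two
activation signatures: at BCR-preferential genes BCR stimulation piles
Pol II onto promoters and the rest-normalized TR drops to 0.64, while
at LPS-preferential genes LPS stimulation doubles gene-body occupancy
and the normalized TR rises toward 2.

## Command line

```bash
ligsel simulate --seed 3 --out data/                # write a synthetic dataset
ligsel classify --expr data/expression.tsv --out classes.tsv
ligsel tr --track data/polII_LPS.bedgraph --rest data/polII_rest.bedgraph \
          --genes classes.tsv --annotation data/annotation.gtf \
          --set lps_pref_up --out tr.tsv
ligsel run --config pipeline.yaml --out results/    # the whole pipeline
```

`ligsel run` takes a YAML config with either a `simulate:` section
(generator parameters) or an `inputs:` section (paths to GTF, bedGraph
tracks, expression/miRNA TSVs, genome FASTA, PWM text, CpG BED), plus
an optional `params:` section; it writes per-module tables and a
`summary.json` with every parameter echoed.  Runs are byte-identical
given the same config and seed.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch: it simulates
a four-class dataset at the given seed, runs the complete pipeline
(classification, profiles, traveling ratios, motif enrichment, miRNA
categories, CpG proportions) into `results/acceptance_run/`, and writes
the result JSON to `--out`.
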