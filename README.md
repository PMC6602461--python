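# overrep

Functional enrichment analysis of gene lists, self-contained and offline.

`overrep` answers the routine question of high-throughput biology: *given a
list of genes from an experiment, which annotated biological categories —
GO terms, pathways, complexes, or any user-supplied gene sets — contain more
of those genes than chance would allow?* It is built for analysts who want
the classical over-representation workflow (the kind hosted enrichment web
services provide) as a library and command-line tool that runs on their own
GMT files, mapping tables and backgrounds, with fully reproducible output.

## The statistic

For a background (universe) of `N` genes, a term annotating `K` of them, and
a query of `n` genes of which `k` fall in the term, significance is the
upper-tail cumulative hypergeometric probability

```
P(X ≥ k) = Σ_{j=k..min(n,K)}  C(K,j) · C(N−K, n−j) / C(N,n)
```

Three query flavours are supported:

* **unordered** — one test per term, as above;
* **ordered** — for a ranked list, every prefix (length 1..n) is tested and
  each term is reported at the prefix length minimizing its p-value, so
  specific terms can peak early and broad terms late;
* **multi-list** — several named lists (`>name` headers) analysed against
  the same background, with a joint table over terms significant in at
  least one list.

Because thousands of overlapping terms are tested at once, only adjusted
p-values are reported. Besides Bonferroni and Benjamini–Hochberg FDR, the
default correction (tag `gscs`) is an empirical **min-p resampling**
family-wise correction: random queries drawn from the background yield the
null distribution of the *minimum* p-value over the whole term collection,
and each observed p is ranked against those minima. Because the null is
simulated on the actual term collection, the correlation induced by term
overlap is accounted for — the correction is more conservative than
Benjamini–Hochberg but less strict than Bonferroni under dependence. See
`docs/methods.md` for the construction and its guarantees.

Around the statistical core sits the interoperability layer: mixed
identifier resolution through alias→reference mapping tables (case
insensitive, ambiguity surfaced rather than guessed), namespace conversion,
two-step ortholog mapping, and BED-interval→gene assignment (0-based
half-open, overlap of at least one base). Outputs are deterministic CSV and
GEM (Cytoscape EnrichmentMap) tables and a Manhattan plot whose term
positions are fixed by the annotation store — never by the p-values — so
plots of different queries are directly comparable.

## Worked example

```python
import io
from overrep import (GeneUniverse, build_store, parse_gmt,
                     query_from_identifiers, run_unordered)

gmt = """\
CellCycle\tcell cycle control\tCDK1\tCDK2\tCCNB1\tPLK1\tAURKB\tBUB1
Apoptosis\tprogrammed cell death\tTP53\tBAX\tCASP3\tCASP9\tBCL2
DNARepair\tDNA damage response\tTP53\tBRCA1\tBRCA2\tRAD51\tATM\tATR\tCHEK2
"""
parsed = parse_gmt(io.StringIO(gmt))
universe = GeneUniverse.from_genes(
    sorted({g for r in parsed.records for g in r.members}
           | {f"BG{i}" for i in range(85)}))          # 102-gene background
store, _ = build_store(parsed.records, universe)

query, dropped = query_from_identifiers(
    "damage_response",
    ["TP53", "BRCA1", "BRCA2", "RAD51", "ATM", "CHEK2", "MYC_X"],
    universe)
records = run_unordered(query, store, method="gscs", seed=7, R=1000)

print(f"dropped (not in background): {dropped}")
for r in sorted(records, key=lambda r: r.p_adj):
    print(f"{r.term_id:<10} N={r.N} K={r.K} n={r.n} k={r.k} "
          f"p_adj={r.p_adj:.3g} significant={r.significant}")
```

prints

```
dropped (not in background): ('MYC_X',)
DNARepair  N=102 K=7 n=6 k=6 p_adj=0.000999 significant=True
Apoptosis  N=102 K=5 n=6 k=1 p_adj=0.33 significant=False
CellCycle  N=102 K=6 n=6 k=0 p_adj=1 significant=False
```

The query token `MYC_X` is outside the background, so it is dropped and
reported; the effective query size is `n = 6`. Six of the seven DNA-repair
genes are in the query, an overlap essentially impossible under random
sampling from 102 genes — the raw tail is ≈ 2·10⁻⁹, and after the min-p
correction with `R = 1000` resampled null queries the adjusted value is the
resolution floor `1/(R+1) ≈ 0.000999`, clearly significant at α = 0.05.
The single apoptosis gene (`k = 1`, expected ≈ 0.3 by chance) and the empty
cell-cycle overlap are not significant.

The same analysis from the shell:

```sh
overrep gost --gmt sets.gmt --query genes.txt \
        --correction gscs --seed 7 --out-prefix results/run
```

writes `run.results.csv`, `run.gem`, `run.layout.tsv`, `run.png` and
`run.report.json` (the report echoes every parameter, so a run can be
reproduced byte-for-byte). `overrep convert`, `overrep orth` and
`overrep fixture` expose identifier conversion, ortholog mapping and the
synthetic-data generator.

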