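# riverweb

Tools for analysing binary river food webs — *connectance webs*, which
record only the presence or absence of predator–prey links. The package
covers the full workflow used in comparative river food-web studies:

1. **Compilation** — read per-section predator→prey edge lists, merge
   them into a master web.
2. **Taxonomic aggregation** — lump nodes in five cumulative steps
   (size/age variants → species → fish families → fish orders →
   invertebrate groups → a single Producers node, with detritus kept
   separate) and track how network structure responds.
3. **Network metrics** — global: node count *N*, directed link count
   *L*, density *D* = 2*L*′/*N*(*N*−1) on the symmetrized web,
   degree-weighted clustering coefficient *CL*, mean geodesic distance
   *d*, and the small-world index *SW* = *CL*/*d*; local: normalized
   degree centrality nDC = deg/(N−1) and normalized betweenness
   centrality nBC (percent of shortest paths through a node).
4. **Trophic guilds** — REGE regular-equivalence similarity on the
   directed web, hierarchically clustered into guild dendrograms
   (exported as Newick).
5. **Two-web comparison** — harmonize the nodes two rivers share
   (normalized labels + an explicit synonym list) and compare their
   centralities with Mann–Whitney tests on midranks, reporting
   U = min(U₁, U₂) and a tie-corrected two-sided asymptotic p.

It ships a niche-model generator (and an Erdős–Rényi null) plus a
layered-taxonomy generator so every stage is testable without external
data, and embeds the published Po/Danube shared-node centrality tables
as fixtures.

## Worked example

Compare the Po and Danube master webs over their 30 shared nodes using
the embedded tables:

```python
from riverweb import compare_tables, load_fixture

po = load_fixture("table3_po")
danube = load_fixture("table3_danube")
synonyms = load_fixture("synonyms_po_danube")
result = compare_tables(po, danube, synonyms)
print(result.n, result.medians, result.tests)
```

prints (reformatted):

```
30
medians: ndc Po 0.110 / Danube 0.008, nbc Po 0.5705 / Danube 0.0825
tests:   ndc U=52.5  p=3.6e-09   nbc U=339.0  p=0.099
```

The degree comparison separates almost completely (U = 52.5 of a
possible 450, p ≪ 0.0001): the Po web records far richer neighborhoods
for the shared taxa. Betweenness does not differ significantly
(U = 339, p ≈ 0.10): the bridging roles are comparable.

The same from the shell:

```sh
riverweb compare src/riverweb/fixtures/table3_po.csv \
                 src/riverweb/fixtures/table3_danube.csv \
                 --synonyms src/riverweb/fixtures/synonyms_po_danube.csv
```

A fully synthetic end-to-end run:

```sh
riverweb simulate --n-species 40 --seed 1 --out sim/
riverweb metrics sim/edges.csv
# N=43 L=144 D=0.155 CL=0.246 d=2.281 SW=0.108
riverweb rege sim/edges.csv --iterations 3 --out guilds.nwk
riverweb run --config config.yaml --out report/   # full bundle
```

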