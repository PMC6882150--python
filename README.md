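# mprclust

Hierarchical clustering of the space of maximum parsimony reconciliations
(MPRs) in the duplication–transfer–loss (DTL) model.

## The problem

Reconciling a gene tree *G* with a species tree *S* under the DTL model
explains their discordance by speciation, duplication, horizontal transfer
and loss events, each with a cost (speciation is free).  A *maximum
parsimony reconciliation* is a mapping of gene-tree vertices onto
species-tree vertices of minimum total event cost.  The optimum is rarely
unique: the number of co-optimal MPRs can grow exponentially with tree
size, and co-optima can disagree substantially, so conclusions drawn from
a single MPR may be contradicted by others.

`mprclust` addresses this by:

1. computing the MPR cost with the standard O-polynomial dynamic program
   and compactly encoding **all** MPRs in a *reconciliation graph* — a DAG
   of mapping nodes (g, s) and event nodes 𝕊/𝔻/𝕋/𝕃/ℂ whose traversals are
   in bijection with MPRs;
2. computing exact statistics of any sub-space of MPRs without
   enumeration: MPR counts (arbitrary precision), per-event *support*
   (the fraction of MPRs containing an event), the mean pairwise
   *symmetric distance* |E(R₁) ⊕ E(R₂)| between MPRs, *median* MPRs, and
   uniform random samples;
3. clustering MPR space agglomeratively.  Initial clusters come from
   depth-L subtraversals of the graph (the smallest L giving at least the
   requested number of clusters); clusters are reconciliation subgraphs
   and merging is subgraph union.  Two linkage criteria are provided:

   * **support**: greedily maximize the weighted average support
     WAS(𝒞) = Σᵢ |Cᵢ| σᵢ / Σᵢ |Cᵢ|, where σᵢ is cluster *i*'s mean event
     support and |Cᵢ| its MPR count;
   * **distance**: greedily minimize the weighted average distance
     WAD(𝒞) = Σᵢ |Cᵢ| μᵢ / Σᵢ |Cᵢ|, where μᵢ is the mean pairwise
     symmetric distance within cluster *i*.

   The full merge history down to one cluster is recorded, together with
   *improvement* scores (objective at k clusters vs. no clustering) and
   *local improvement* scores (k vs. k−1) that help choose k.  A median
   reconciliation is reported per cluster as its representative.

Intended users: researchers in phylogenetics / cophylogenetics analyzing
gene–species, host–parasite or symbiont tree pairs who need a small set
of representative reconciliations when MPR space is large and diverse.

## Worked example

The bundled fixture `toy3` has gene tree `(a,c)`, species tree
`((A,B),C)`, leaf mapping a→A, c→C and unit costs (d=t=ℓ=1):

```sh
python - <<'EOF'
import mprclust as m
from mprclust.instance import write_newick
from pathlib import Path
inst = m.fixture("toy3")
Path("s.nwk").write_text(write_newick(inst.species_tree) + "\n")
Path("g.nwk").write_text(write_newick(inst.gene_tree) + "\n")
Path("m.tsv").write_text("".join(f"{a}\t{b}\n" for a, b in inst.mapping.items()))
EOF
mprclust reconcile --species s.nwk --gene g.nwk --mapping m.tsv \
    -d 1 -t 1 -l 1 --outdir out
cat out/reconcile.json
```

prints

```json
{
  "mean_event_support": 0.3333333333333333,
  "mean_pairwise_distance": 2.6666666666666665,
  "mpr_count": 3,
  "n_graph_edges": 13,
  "n_graph_nodes": 12,
  "n_sources": 3,
  "opt_cost": 1.0
}
```

There are three cost-1 MPRs: a speciation at the species root with a loss
on the (A,B) lineage, and two transfers (the gene root placed at A sending
c to C, or placed at C sending a to A).  Each of the four non-leaf events
appears in exactly one MPR (support 1/3), and two MPRs differ by 8/3
events on average.  Clustering with the support criterion,

```sh
mprclust cluster --species s.nwk --gene g.nwk --mapping m.tsv \
    -d 1 -t 1 -l 1 --criterion support --min-init-clusters 2 --k 2 --outdir outc
cat outc/clusters_per_k.csv
```

```
k,was,wad,improvement_support,improvement_distance,local_improvement
3,1.0,0.0,3.0,inf,2.0
2,0.6666666666666666,2.0,2.0,1.3333333333333333,2.0
1,0.3333333333333333,2.6666666666666665,1.0,1.0,
```

Read: the three initial clusters are single MPRs (WAS 1.0); merging to
k=2 keeps WAS at 2/3, twice the unclustered mean support of 1/3
(improvement 2.0), and each cluster's median reconciliation is written to
`outc/cluster*_median.txt`.

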