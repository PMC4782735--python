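# nerclust

Clustering of species assemblage data for biogeography — built for
palaeoecologists and biogeographers who need to delimit faunal regions
from site-by-species occurrence tables, where the data are sparse,
presence/absence based, and non-Euclidean.

## What it implements

**Non-Euclidean Relational Clustering (NERC)** partitions an n×n
dissimilarity matrix *D* into *k* groups (2 ≤ k ≤ n/2) without building a
tree or embedding the data in Euclidean space. One restart: seed *k*
clusters with random samples; grow them greedily by repeatedly joining
the unassigned sample with the globally smallest dissimilarity to any
assigned sample (re-seeding if a group ends up a singleton); then
optimize by moving one misplaced sample at a time — a sample *i* in
cluster *C* is misplaced when

&nbsp;&nbsp;&nbsp;&nbsp;mean<sub>j∈C'</sub> D<sub>ij</sub> &lt; mean<sub>j∈C∖{i}</sub> D<sub>ij</sub> for some cluster C' ≠ C

— until no sample is misplaced. Over many restarts the partition with the
smallest pooled mean within-group distance wins. Moves that would leave a
cluster with fewer than two members are forbidden, which is what protects
NERC from the outlier-wastes-a-cluster pathology of cut trees.

Around it: the Sørensen (Dice) dissimilarity d = 1 − 2a/(2a+b+c) on
presence/absence data; single/complete/UPGMA linkage with tree cutting;
k-means on a principal-coordinates embedding (Sørensen or Euclidean
input); a species-occurrence simulator with regional endemic/cosmopolitan
pools and log-normal abundances; Rand and Adjusted Rand indices; and a
paired simulation benchmark of all six method/metric combinations. See
`docs/methods.md` for the full model description.

## Worked example

Simulate 3 regions × 30 sites from a 100-species pool, half of them
endemic, 50 specimens per locality; cluster the Sørensen matrix three
ways and score each against the known regions:

```sh
$ nerclust simulate --species 100 --regions 3 --sites-per-region 30 \
    --endemicity 0.5 --specimens 50 --seed 42 --out occ.csv --truth truth.csv
wrote 100 species x 90 sites to occ.csv
$ nerclust dist --occ occ.csv --out d.csv
wrote 90 x 90 Sørensen matrix to d.csv
$ nerclust nerc --dist d.csv --k 3 --restarts 200 --seed 7 --out labels.csv -v
mean within-group distance 0.681489 over 200 restarts (86 reassignments, converged=True)
wrote 90 cluster labels to labels.csv
$ nerclust evaluate --pred labels.csv --truth truth.csv
0.868252
$ nerclust kmeans --occ occ.csv --metric sorensen --k 3 --seed 7 --out km.csv \
    && nerclust evaluate --pred km.csv --truth truth.csv
0.868252
$ nerclust linkage --dist d.csv --method upgma --k 3 --out upgma.csv \
    && nerclust evaluate --pred upgma.csv --truth truth.csv
0.354531
```

An Adjusted Rand Index of 1 is a perfect match to the true regions and 0
is chance-level agreement. At this moderate endemicity NERC and
Sørensen-based k-means recover the regions well (ARI 0.87) while UPGMA
with tree cutting recovers far less (0.35) — the qualitative gap the
benchmark quantifies. `converged=True` means the partition is an exact
fixed point: no site is on average closer to a foreign cluster.

The same machinery is available as a library, in scikit-learn style:

```python
from nerclust import NERC, sim_occ, sorensen_dissimilarity, to_presence_absence
from nerclust.simulate import SimParams

m = sim_occ(SimParams(endemicity=0.5, seed=42))
d = sorensen_dissimilarity(to_presence_absence(m))
est = NERC(n_clusters=3, n_restarts=200, random_state=7).fit(d)
est.labels_            # cluster per site
est.mean_within_distance_
```

Full benchmark sweeps (the simulation experiments over endemicity and
sampling intensity, 100 replicates per level by default):

```sh
nerclust benchmark --experiment endemicity --reps 100 --seed 1 \
    --out endemicity.csv --plot endemicity.png
```

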