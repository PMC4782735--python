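"""Simulation benchmark: cluster-recovery accuracy of six methods.

Each replicate simulates one occurrence matrix with known regional truth
and feeds the *same* matrix to all six method/input combinations —

* single, complete and UPGMA linkage on the Sørensen dissimilarity matrix,
  cut to k groups;
* k-means on a PCoA embedding, once of Euclidean distances between
  presence/absence site vectors and once of the Sørensen matrix;
* NERC on the Sørensen matrix —

scoring each partition against the true regions with the Adjusted Rand
Index. Sweeps vary either the endemicity proportion (cluster
distinctiveness) or the specimens-per-site count (sampling intensity),
averaging ARI over many paired replicates per level. Per-replicate seeds
derive deterministically from (master seed, level, replicate), so reruns
and parallel execution agree and method differences are never simulation
noise.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .baselines import kmeans_cluster, linkage_cluster, pcoa
from .compare import adjusted_rand_index
from .distances import euclidean_distance, sorensen_dissimilarity, to_presence_absence
from .nerc import nerc
from .simulate import SimParams, sim_occ

__all__ = ["METHODS", "run_replicate", "run_sweep", "plot_sweep"]

METHODS = ("single", "complete", "upgma", "kmeans_euclidean", "kmeans_sorensen", "nerc")

#: restarts used inside the benchmark (per replicate); the standalone
#: defaults are larger, but averaged over many replicates 100 k-means and
#: 100 NERC restarts are ample for 90 sites
KMEANS_RESTARTS = 100
NERC_RESTARTS = 100


def run_replicate(
    params: SimParams,
    k: int | None = None,
    seed: int | None = None,
    nerc_restarts: int = NERC_RESTARTS,
    kmeans_restarts: int = KMEANS_RESTARTS,
) -> dict[str, float]:
    """Simulate one matrix, apply all six methods to it, return method -> ARI.

    k defaults to the simulated number of regions. The four distance-based
    methods share one Sørensen matrix. A method failure records NaN rather
    than aborting the replicate.
    """
    if k is None:
        k = params.n_regions
    ss = np.random.SeedSequence(seed)
    sim_seed, kmeans_e_seed, kmeans_s_seed, nerc_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    m = sim_occ(replace(params, seed=sim_seed))
    truth = m.true_regions
    binary = to_presence_absence(m)
    d_sor = sorensen_dissimilarity(binary)

    out: dict[str, float] = {}

    def record(name, fn):
        try:
            out[name] = adjusted_rand_index(fn(), truth)
        except Exception:
            out[name] = float("nan")

    for method in ("single", "complete", "upgma"):
        record(method, lambda method=method: linkage_cluster(d_sor, method, k))
    record(
        "kmeans_euclidean",
        lambda: kmeans_cluster(
            pcoa(euclidean_distance(binary)), k, restarts=kmeans_restarts, random_state=kmeans_e_seed
        ),
    )
    record(
        "kmeans_sorensen",
        lambda: kmeans_cluster(
            pcoa(d_sor), k, restarts=kmeans_restarts, random_state=kmeans_s_seed
        ),
    )
    record("nerc", lambda: nerc(d_sor, n_clusters=k, n_restarts=nerc_restarts, seed=nerc_seed).labels)
    return out


def run_sweep(
    experiment: str,
    levels,
    base: SimParams | None = None,
    n_reps: int = 100,
    master_seed: int | None = None,
    nerc_restarts: int = NERC_RESTARTS,
    kmeans_restarts: int = KMEANS_RESTARTS,
) -> pd.DataFrame:
    """Mean and standard error of ARI per method over a parameter sweep.

    ``experiment`` is ``"endemicity"`` (levels are endemicity proportions)
    or ``"sampling"`` (levels are specimens-per-site counts). Returns a
    tidy table with columns experiment, level, method, mean_ari, n_reps,
    se_ari; every method's row at a level averages the same ``n_reps``
    paired replicates.
    """
    if experiment not in ("endemicity", "sampling"):
        raise ValueError("experiment must be 'endemicity' or 'sampling'")
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("a sweep needs at least two levels")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if base is None:
        base = SimParams()

    rows = []
    for li, level in enumerate(levels):
        if experiment == "endemicity":
            p = replace(base, endemicity=float(level))
        else:
            p = replace(base, specimens_per_site=int(level))
        aris = {method: [] for method in METHODS}
        for rep in range(n_reps):
            rep_seed = int(
                np.random.SeedSequence([0 if master_seed is None else master_seed, li, rep])
                .generate_state(1)[0]
                % (2**31)
            )
            result = run_replicate(
                p, seed=rep_seed, nerc_restarts=nerc_restarts, kmeans_restarts=kmeans_restarts
            )
            for method in METHODS:
                aris[method].append(result[method])
        for method in METHODS:
            vals = np.asarray(aris[method], dtype=float)
            ok = vals[~np.isnan(vals)]
            rows.append(
                {
                    "experiment": experiment,
                    "level": level,
                    "method": method,
                    "mean_ari": float(ok.mean()) if ok.size else float("nan"),
                    "n_reps": n_reps,
                    "se_ari": float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, path=None):
    """Line plot of mean ARI (±2 SE) versus the swept parameter, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    experiment = table["experiment"].iloc[0]
    for method in METHODS:
        sub = table[table["method"] == method].sort_values("level")
        if sub.empty:
            continue
        ax.errorbar(sub["level"], sub["mean_ari"], yerr=2 * sub["se_ari"], label=method, marker="o")
    ax.set_xlabel("endemicity proportion" if experiment == "endemicity" else "specimens per site")
    ax.set_ylabel("mean Adjusted Rand Index")
    ax.set_ylim(-0.1, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
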