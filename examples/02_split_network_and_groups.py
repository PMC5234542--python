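"""Build NeighborNet split networks and delineate genotype clusters.

Runs p-distances + NeighborNet on both the full scored matrix and the
reproducible-only matrix, writes SplitsTree-compatible NEXUS files, and
extracts k=3 groups. The between/within distance ratio shows why filtering
matters: unfiltered scoring error inflates apparent within-cluster variation.
"""

from pathlib import Path

import numpy as np

from aflp_delimit import (
    extract_groups,
    filter_scoring_errors,
    neighbor_net,
    p_distance_matrix,
    study_preset,
    simulate_aflp,
)
from aflp_delimit.synthetic_data import adjusted_rand_index, score_simulated

out = Path("scratch/example_networks")
out.mkdir(parents=True, exist_ok=True)

cfg = study_preset(seed=7)
table, reps, truth = simulate_aflp(cfg)
calls = score_simulated(table, cfg)
reduced, _ = filter_scoring_errors(calls, reps)

for name, matrix in (("full", calls), ("reduced", reduced)):
    dm = p_distance_matrix(matrix)
    ss = neighbor_net(dm)
    ss.to_nexus(out / f"splits_{name}.nex")
    ga = extract_groups(dm, k=3)
    truth_labels = [truth.cluster_of[truth.entry_sample[e]] for e in dm.labels]
    ours = [ga.assignment[e] for e in dm.labels]
    within, between = [], []
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            (within if truth_labels[i] == truth_labels[j] else between).append(
                dm.d[i, j]
            )
    print(f"{name} matrix ({matrix.n_bins} bins): {len(ss.splits)} splits, "
          f"fit {ss.fit:.2f}% of squared distance explained")
    print(f"  groups recovered vs truth: adjusted Rand index "
          f"{adjusted_rand_index(truth_labels, ours):.2f}")
    print(f"  mean between-cluster / within-cluster distance: "
          f"{np.mean(between) / np.mean(within):.1f}x")
print(f"split networks written to {out}/ (open in SplitsTree)")
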