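"""Sample the quasi-energy landscape around marker-derived attractors.

Stores one attractor per cell type, perturbs each with sign-flip noise,
and projects all sampled states onto the attractors' first two principal
components — the (x, y, E) table a contour plot would consume.
"""

from cellsort import (build_attractors, build_model, normalize_and_restrict,
                      project_landscape, sample_basins, synth_marker_table)

table = synth_marker_table(n_types=6, markers_per_type=6, n_shared=3,
                           n_negative=4, seed=5)
normalized = normalize_and_restrict(table, table.genes)
attractors = build_attractors(normalized)

# landscape couplings keep the (complete-graph) adjacency, omit Q
model = build_model(attractors, use_q=False)
sample = project_landscape(
    sample_basins(model, n_per_attractor=500, seed=6), model)

frame = sample.to_frame()
attractor_rows = frame[frame["flip_rate"] == 0]
print("attractor coordinates and quasi-energies (landscape minima):")
print(attractor_rows[["attractor", "x", "y", "energy"]].to_string(index=False))

by_rate = frame.groupby("flip_rate")["energy"].mean()
print("\nmean sampled energy by flip rate (noise degrades E monotonically):")
print(by_rate.to_string())

frame.to_csv("landscape.csv", index=False)
print(f"\n{len(frame)} sampled states written to landscape.csv")
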