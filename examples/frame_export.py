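"""Headless frame stack: time-resolved visibility of a hub ego network.

Simulates a small cohort, thresholds the smoothed expression at -0.2 log2
units (inclusive), and exports one frame per sampled timepoint for a hub's
1-step ego network: a node is visible when its expression is at or above
threshold, and an edge only when both endpoints are visible.
"""

import tempfile
from pathlib import Path

from hubcycle import (
    HubSpec,
    SimulationConfig,
    activity_mask,
    ego_network,
    export_frames,
    read_frames,
    simulate_cohort,
    smooth_matrix,
)

config = SimulationConfig(
    seed=3,
    experiments=((119.0, 18),),
    hub_specs=(HubSpec(2, 5, "dynamic_competitive"),),
    n_background_genes=0,
)
network, matrices, truth = simulate_cohort(config)
sm = smooth_matrix(matrices[0])
mask = activity_mask(sm, threshold=-0.2)

ego = ego_network(network, "HUB01", steps=1)
out = Path(tempfile.mkdtemp()) / "frames.jsonl"
export_frames(ego, mask, out)
frames = read_frames(out)

print(f"exported {len(frames)} frames to {out.name}")
for fr in frames[:6]:
    nodes = ", ".join(sorted(fr.visible_nodes)) or "(none)"
    print(f"  t={fr.time:5.1f} min  visible: {nodes}  edges: {len(fr.visible_edges)}")
# The dynamic hub drops out of the network during its expression trough,
# taking all of its interaction edges with it, while its static partners
# stay visible throughout.
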