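"""Simulate the simplified osmotic-stress (HOG) pathway.

The pathway has two modules: a phosphorelay that senses turgor and a
MAP kinase cascade that responds to its loss.  We run the classic
stress/recovery protocol — turgor present, lost at t=27, restored at
t=50 — and print the phases, then render the clustered heat map of the
free-running oscillation.
"""

from bibool import (
    PerturbationEvent,
    PerturbationSchedule,
    build_bipartite,
    default_init,
    run_sync,
)
from bibool.fixtures import simplified_hog
from bibool.io import trajectory_heatmap

bm = build_bipartite(simplified_hog())

schedule = PerturbationSchedule([
    PerturbationEvent(0, "[Turgor]", True, clamp=True),
    PerturbationEvent(27, "[Turgor]", False, clamp=True),
    PerturbationEvent(50, "[Turgor]", True, clamp=True),
])
traj = run_sync(bm, default_init(bm), schedule, max_steps=200)
frame = traj.to_frame()

# the run stops as soon as the post-recovery attractor is reached
last = frame.columns[-1]
for label, t in [("settled, turgor on", 26), ("stress response", 40),
                 ("recovered", last)]:
    active = [v for v in ("Ssk1--Ssk2", "Pbs2-{P}", "Hog1-{P}", "Hot1-{P}")
              if frame.loc[v, t] == 1]
    print(f"t={t:3d} ({label}): active = {active or 'none'}")
print("attractor:", traj.attractor)

# free-running (turgor driven by the feedback itself): a sustained
# oscillation; the heat map orders variables by profile similarity
free = run_sync(bm, default_init(bm), max_steps=120)
print("free-running attractor:", free.attractor)
matrix = trajectory_heatmap(free, image_path="hog_heatmap.png")
print(f"heat map: {matrix.shape[0]} changing variables -> hog_heatmap.png")
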