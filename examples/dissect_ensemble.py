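"""Dissect synthetic peptide trajectories into conformational sub-ensembles.

Generates a Pro-trans and a Pro-cis marker-distance trajectory (the distance
between the Tyr2 and Arg8 eta-hydrogens), realizes them as coarse 3-D
ensembles, classifies every frame and characterizes the distance
distributions with a Gaussian mixture.
"""

from collections import Counter

from vcss import (TrajectoryParams, fit_distance_mixture, gen_distance_series,
                  gen_toy_trajectory, label_frames)

for state in ("trans", "cis"):
    params = TrajectoryParams(state=state, n_frames=4000, seed=1)
    series, _ = gen_distance_series(params)
    traj = gen_toy_trajectory(series, state, seed=2)
    labeled = label_frames(traj)
    counts = Counter(str(l) for l in labeled.labels)
    fit = fit_distance_mixture(series, seed=1)
    print(f"Pro7-{state}: {dict(counts)}")
    modes = ", ".join(f"{m:.3f} nm (w={w:.2f})"
                      for m, w in zip(fit.means, fit.weights))
    print(f"  distance modes: {fit.n_components} -> {modes}")

print("\nThe trans ensemble splits into a compact (~0.5 nm, back-folded tail)")
print("and an extended (~1.9 nm) mode; the cis ensemble has a single extended")
print("mode near 2.2 nm and no compact sub-ensemble.")
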