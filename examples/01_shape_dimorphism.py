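"""Sexual shape dimorphism (SShD) from landmark configurations.

Generates a small two-sex population of 72-point facial configurations
with a known male mean-shape displacement, symmetrizes each face,
jointly Procrustes-aligns both sexes, and scores every face by
projecting its shape coordinates onto the axis joining the female-mean
and male-mean shapes.
"""

import numpy as np

from facedim import (
    PopulationSpec,
    assemble_sshd_matrix,
    build_axis,
    generate_landmarks,
    gpa,
    mean_distance,
    project_scores,
    symmetrize,
)

spec = PopulationSpec(name="demo", n_female=30, n_male=30, seed=42)
configs = [symmetrize(c) for c in generate_landmarks(spec)]
aligned = gpa(configs)
print(f"GPA converged in {aligned.iterations_run} iterations")

X = assemble_sshd_matrix(aligned)
axis = build_axis(X)
scores = project_scores(X, axis)
by_sex = scores.groupby("sex")["score"].mean()

print(f"between-sex mean shape distance: {mean_distance(X):.4f} (Procrustes units)")
print(f"mean SShD score  F: {by_sex['F']:.6f}   M: {by_sex['M']:.6f}")
print(f"M - F score gap: {by_sex['M'] - by_sex['F']:.6f} = ||axis||^2 = {axis.length**2:.6f}")

# Higher scores are more male-typical.  The distance (~0.02-0.04 for real
# faces) summarizes how far apart the average female and male shapes sit
# in Procrustes shape space; the score gap equals its square exactly.
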