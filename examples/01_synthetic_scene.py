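"""Generate a synthetic deforestation-frontier scene and summarise it.

Builds a 200x200-cell (6 x 6 km at 30 m) two-epoch landscape whose
forest→agriculture conversion follows a known logit-linear process, then
prints the between-epoch transition matrix.  The forest-row/agriculture-
column entry is the per-pixel conversion probability over the epoch
(about 0.05 under the default coefficients).
"""

from lucfrontier import GeneratorConfig, make_scene, transition_matrix

scene = make_scene(GeneratorConfig(seed=1))

forest0 = scene.map_t0.class_mask("forest")
converted = forest0 & scene.map_t1.class_mask("agriculture")
print(f"forest share at t0:           {forest0.mean():.3f}")
print(f"realized conversion rate:     {converted.sum() / forest0.sum():.4f}")
print(f"true covariates with signal:  "
      f"{[t for t in scene.truth.beta if t != 'intercept']}")

tm = transition_matrix(scene.map_t0, scene.map_t1)
print("\ntransition probabilities (rows: t0 class, columns: t1 class):")
print(tm.to_frame().round(3))

# the scene can be exported as plain-text grids + GeoJSON + truth JSON:
# scene.save("scene_dir")
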