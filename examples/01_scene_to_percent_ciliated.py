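"""Generate a synthetic field of cells and quantify its ciliation.

Renders a scene of 20 cells, 60% of them bearing a cilium a few pixels
from their basal body, then runs the full detection pipeline and prints
the recovered counts next to the planted ground truth.
"""

from ciliaquant import SceneSpec, generate_scene, measure_image
from ciliaquant.synthgen import DEFAULT_BB_PARAMS, DEFAULT_CILIA_PARAMS

spec = SceneSpec(n_cells=20, ciliated_fraction=0.6, noise_sigma=0.1, seed=7)
cilia, basal, nuclei, truth = generate_scene(spec)

m = measure_image(cilia, basal, DEFAULT_CILIA_PARAMS, DEFAULT_BB_PARAMS,
                  image_id="demo_scene")

print(f"planted: {truth.planted_ciliated_count} ciliated cells / "
      f"{len(truth.basal_body_centers)} basal bodies "
      f"-> expected {truth.expected_percent:.1f}% ciliated")
print(f"measured: {m.n_cilia_confirmed} confirmed cilia / "
      f"{m.n_basal_bodies} basal bodies "
      f"-> {m.percent_ciliated:.1f}% ciliated")
print(f"mean cilium length (half-perimeter): {m.mean_cilium_length:.1f} px")
# The measured percentage should equal the planted one: every confirmed
# cilium had a single basal body strictly within 12 px of its boundary.
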