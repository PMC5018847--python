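"""Measure the camouflage of a single synthetic clutch photograph.

Renders a calibrated scene (sRGB, 37.6 px/cm), derives the three analysis
regions around the clutch outline, runs the edge detector, and prints the
full metric record.  Audit images (regions, edges) go to scratch/.
"""

from pathlib import Path

from nestcam import io as nio
from nestcam.pipeline import RunConfig, analyze_scene
from nestcam.synthetic import SceneTruth, make_scene

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)

truth = SceneTruth(seed=42)
scene, mask, _ = make_scene(truth)
record, artifacts = analyze_scene(scene, mask, RunConfig(), nest_id="demo", species="plover")

print("ground truth:", truth.n_eggs, "eggs,", f"speckle density {truth.speckle_density}/cm^2")
for key, value in record.as_row().items():
    if isinstance(value, float):
        print(f"  {key:28s} {value:.4f}")

nio.write_scene(out / "scene.png", scene)
nio.write_region_labels(out / "regions.png", artifacts["regions"])
nio.write_edge_png(out / "edges.png", artifacts["edge_map"])
print("audit images written to", out)
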