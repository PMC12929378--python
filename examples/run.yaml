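# Full perception -> prescription run on synthetic imagery.
# Scenes are laid out west -> east from the anchor coordinate; all stages
# derive their randomness from `seed`.
seed: 5
out_dir: runs/demo
n_scenes: 2           # synthetic orthophoto frames
scene_width: 1440     # px (study source frames are 5280 x 3956)
scene_height: 960
tile_size: 480        # sliding-window tile edge, px
weed_density: 2.0     # weeds per square metre
augment_multiplicity: 4
label_format: labelme
write_dataset: true
use_model: false      # true: smoke-train a model and use its detections
cell_size: 12.0       # sprayer working width, m
baseline_rate: 120.0  # L/hm^2 for the densest tier
classification: fixed # or "jenks"
lat: 48.78
lon: 125.41
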