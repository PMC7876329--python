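# bloomcount

Counting and localizing flowering plants in aerial field imagery by
density estimation.

Point annotations (one click per flowering plant) are smoothed into
Gaussian density maps; a fully-convolutional encoder–decoder regresses
those maps from RGB patches; integrating a predicted map yields a count
and peak extraction yields clickable discrete locations. A CountDiff
(integrated count minus peak count) ranking prioritizes samples for
annotation in an active-learning loop, and tiled inference stitches
density maps over arbitrarily large field mosaics with a yellow-to-red
overlay.

The whole pipeline is exercised against a built-in synthetic field
generator (green plant beds, road gaps, reddish inflorescence blobs with
exact ground-truth points), so everything is testable offline.

## Layout

| module | role |
| --- | --- |
| `bloomcount.synthetic_field` | synthetic fields + datasets with known point annotations |
| `bloomcount.density_targets` | Gaussian density targets, rotation/crop augmentation, tiling |
| `bloomcount.unet_model` | the encoder–decoder density regressor (pure numpy, manual backprop) |
| `bloomcount.trainer` | MSE training loop with Adam + early stopping; MAE/MAPD evaluation |
| `bloomcount.counting_peaks` | count by integration; thresholded minimum-distance peak extraction |
| `bloomcount.active_learning` | CountDiff ranking, oracle-correction ingestion, data-quantity experiment |
| `bloomcount.mosaic_inference` | tiled mosaic inference, stitching, overlays, per-block reports |
| `bloomcount.annotation_io` | annotation/peak/manifest CSV and GeoJSON dialects |

The network and optimizer are implemented in numpy (`bloomcount.nn`)
because no deep-learning framework is assumed at runtime; every layer's
backward pass is checked against finite differences in the test suite.

## CLI

```bash
# synthetic dataset (images + annotation CSVs + manifest)
bloomcount generate --config gen.yaml --out data/

# density targets from annotations
bloomcount targets --annotations ann.csv --images data/images --sigma 6 --out targets/

# train (YAML holds TrainingConfig + ModelSpec keys)
bloomcount train --config train.yaml --manifest data/manifest.csv --out run/

# counts and peaks from a density map
bloomcount count --density run/density.tif
bloomcount peaks --density run/density.tif --gamma 0.05 --delta 4 --out peaks.csv

# active learning utilities
bloomcount rank --model run/model --images pool/ --out priorities.csv
bloomcount experiment --levels 50,100,250,500,650 --config train.yaml \
    --manifest data/manifest.csv --out ledger.csv

# field-scale tiled inference + overlay
bloomcount infer --model run/model --mosaic field.png --tile 256 --out field_out/
```

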