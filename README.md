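# picmontage

Headless montage builder for multichannel fluorescence microscopy
experiments.

From an experiment directory that contains one subdirectory per condition
(each holding the condition's multichannel images), picmontage produces:

* **preview mode** — one montage per condition, gathering *all* of its
  images: for every field of view, a row of grayscale single-channel tiles
  plus one color merge tile;
* **summary mode** — one experiment-wide montage with a single
  representative image per condition (by default the first one, or chosen
  by name/index).

Each run also writes a plain-text log — parameters, directory contents,
selected/skipped files and contrast bounds — tagged with the same
`YYYYMMDD-HHMMSS` timestamp as the montages, so outputs and logs pair
unambiguously. All outputs land in the parent directory; re-running never
overwrites previous outputs.

## Features

* Two dataset layouts: all channels in one TIFF/OME-TIFF per field of view,
  or one single-channel file per channel whose names differ only by a
  channel-identifier substring (e.g. `img01_DAPI.tif` / `img01_GFP.tif`).
* Non-compliant files (wrong extension or channel count, z-stacks,
  time-lapses, multi-series files, unreadable files) are skipped with a
  logged diagnostic, never a crash.
* Contrast enhancement by histogram stretching: `none`, `autoscale`
  (per-image min-max), or per-channel user-defined settings with a
  saturation percentage (0 / 0.01 / 0.1 / 0.4 / 1 %) and a scope —
  `joint` (one stretch for all images of a montage, preserving
  inter-image comparability) or `individual` (each image's own range).
* Seven-color palette (red, green, blue, gray, cyan, magenta, yellow) for
  the merge, optional tile labels (`C1 <folder> <file>`), horizontal or
  vertical montages, PNG / JPEG / TIFF export, per-channel omission from
  the single columns or the merge.
* A seeded synthetic-dataset generator (`picmontage.fixtures`) for testing
  and demos, including a four-picture "contrast pitfall" scene of flat
  squares with known mean intensities.
* Optional reader hook to plug in proprietary-format readers.

## CLI

```bash
# generate a demo experiment: 2 conditions x 3 images x 3 channels
picmontage make-dataset /tmp/Experiment001 --subfolders 2 --images 3 --channels 3 --seed 1

# one montage per condition
picmontage preview /tmp/Experiment001 --channels 3

# experiment digest with chosen representatives
picmontage summary /tmp/Experiment001 --channels 3 \
    --representatives cond01=img03,cond02=1

# per-channel contrast, custom palette, vertical jpeg montage
picmontage preview /tmp/Experiment001 --channels 3 \
    --contrast custom --saturation c1=0.1,c2=0,c3=off --scope c2=joint \
    --palette c1=blue,c2=green,c3=red --orientation vertical --format jpeg
```

Separated-channel datasets need `--structure separated` and
`--identifiers DAPI,GFP,...`. Every option can also live in a YAML file
(`--config run.yaml`); explicit flags override the file. Saturation values
on the CLI are percentages.

## Library

```python
from picmontage import (
    DatasetSpec, ContrastPolicy, ChannelContrast, RenderOptions,
    RunConfig, run,
)

spec = DatasetSpec(parent_path="/data/Experiment001", n_channels=3)
policy = ContrastPolicy(
    mode="user_defined",
    channels=(
        ChannelContrast(saturation_fraction=0.001, scope="individual"),
        ChannelContrast(saturation_fraction=0.0, scope="joint"),
        ChannelContrast(enhance=False),
    ),
)
result = run(RunConfig(mode="preview", spec=spec, contrast=policy,
                       render=RenderOptions(orientation="horizontal")))
print(result.montage_paths, result.log_path)
```

## Tests

```bash
python -m pytest -q tests/
```

The suite covers every module (unit tests, hypothesis property tests for
the contrast engine and file grouping, and an acceptance suite checking
montage composition counts, the log contract and the contrast-pitfall
reproduction).

## Notes on semantics

* The saturation fraction is split equally between the histogram tails
  (`floor(N*f/2)` pixels clipped per tail); all pixels at the boundary
  intensity clip together.
* Full scale is `2^bit_depth - 1` (255 / 65535); stretched values are
  rounded half-up and stay at the input bit depth.
* The merge is saturating additive blending (component-wise sum clamped
  to 255).
* Constant (blank) planes pass through contrast enhancement unchanged, so
  montages still build for empty control images.
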