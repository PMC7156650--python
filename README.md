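# endoescape

Quantification of endosomal escape from live-cell microscopy, using
cytosolic galectin-9 as a sensor of endolysosomal membrane damage.

When an endocytic vesicle is ruptured — for instance by a cationic
amphiphilic drug such as chloroquine, siramesine, or loperamide — cytosolic
galectin-9 binds the luminal glycans exposed on the damaged membrane and
forms a bright focus within seconds. `endoescape` turns that signal into
numbers: it detects the onset frame *t₀* of galectin recruitment in
multi-channel time-lapse z-stacks, tracks the damaged vesicle in 4D,
measures how much of its cargo (cholesterol-conjugated siRNA or dextran)
escapes to the cytosol, classifies the compartment identity of the damaged
vesicle from an endosomal marker channel (LAMP1, Rab5, Rab7, CD63, …), and
computes per-cell and spheroid-level summary measurements. A built-in
simulator generates movies with planted ground truth, so every stage of the
pipeline is verifiable end to end.

Intended users: cell biologists and image analysts studying oligonucleotide
delivery, lysosomal membrane permeabilization, or galectin biology, who
have time-lapse TIFF movies and approximate event coordinates and want
reproducible, scriptable event-level quantification.

## The measurements

**Onset detection.** From a seed coordinate (x, y, t) near a de novo
galectin focus, the detector scans frames starting 25 frames before the
seed frame. At each frame it fits a 6 px diameter circular mask to the
position maximizing the mask-mean intensity over the full z volume within
±6 px of the seed. A measurement strictly above the adaptive threshold

  θ = mean + 5 × s.d. of all prior scan measurements

marks a candidate t₀, confirmed only if forward tracking (±12 px in x/y,
±5 z-planes per step) stays above the frozen θ for 5 consecutive frames.

**Release fraction.** Vesicle traces are local-background subtracted (median
over a ring ~0.8 µm outside the mask, smoothed by an 11-frame centered
rolling average), aligned so t₀ ↦ 0, and cargo traces normalized to their
mean ~3–60 s before onset. The released fraction of a single vesicle is

  f = 1 − I(+45 s) / I(−15 s)

from single-frame measurements nearest those offsets.

**Marker identity.** Marker-object pixels of a cell are those whose log₁₀
intensity exceeds the cell mean + 1 s.d. (log scale); a linear reference
through the first/last-frame object means corrects photobleaching. Cells
with marker SNR < 50 are excluded. A vesicle is marker-positive when its
normalized marker trace averaged over five measurements ~3–16 s after onset
exceeds 0.5; positives with trace s.d./mean > 1 are reclassified negative.

**Population and spheroid measurements.** Galectin-foci counts per cell,
vesicle-masked median cytosolic dextran, eroded-mask chol-siRNA uptake,
LAMP1 colocalization fractions, flow-cytometry knockdown normalization
(`(sample − wildtype)/(control − wildtype)`), and radial shell profiles of
spheroid sections scaled to a 200 px equivalent radius with the uint16
export transform `round(1000·log₁₀(10⁴·ratio))`.

## Worked example

Simulate a two-event movie, detect the onsets from the exported seed
calls, and quantify release:

```sh
endoescape simulate --seed 11 --out-dir demo/sim --n-events 2 --n-frames 60 --n-z 6
# wrote movie with 2 planted event(s) to demo/sim
endoescape detect --movie demo/sim/movie.tif --seeds-csv demo/sim/seeds.csv --out-dir demo/det
# confirmed 2 event(s) from 2 seed(s)
endoescape release --movie demo/sim/movie.tif --tracks demo/det/tracks.csv --out-dir demo/rel
# wrote release metrics for 2 event(s)
```

`demo/det/detections.csv` then holds, per seed, the detected onset frame
and the adaptive threshold that confirmed it:

```
seed_index,detected,t0_frame,threshold
0,True,32,109.66051114248594
1,True,32,109.50341279160794
```

Both planted events (true onset frame 32) are recovered exactly; the
threshold sits ≈110 counts, i.e. mean + 5 s.d. of the pre-onset scan at a
background of ~100 counts. `demo/rel/release.csv` gives the event-level
release read-out:

```
event_id,t0_frame,cargo_present,pre_intensity,post_intensity,released_fraction
0,32,True,1.0345…,0.2530…,0.7553…
1,32,True,1.1900…,0.2820…,0.7629…
```

Both vesicles contained cargo before damage and released ~76% of it —
single-frame noisy read-outs of the planted 80% release step. The same
library calls are available in Python (`endoescape.detect_t0`,
`endoescape.traces.release_fraction`, …); see the module docstrings.

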