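# vesselquant

Quantification stack for 3D microvessel-on-chip imaging experiments:
vessel-network morphometry from confocal stacks, apparent transendothelial
permeability from dextran time-lapse series, and neutrophil (PMN)
track-speed / extravasation classification — validated end-to-end against a
synthetic phantom generator with exact ground truth.

## Who this is for

Labs growing self-assembled microvascular networks in microfluidic devices
(endothelial cells plus stromal cells in a fibrin gel) and imaging them by
confocal microscopy face the same quantification chain over and over:
segment the endothelial channel, skeletonize it, report coverage / branch
geometry / connectivity; perfuse fluorescent dextran and estimate barrier
permeability; perfuse leukocytes and score their speed and fate.  The
individual steps are usually stitched together from ImageJ macros and
commercial trackers, which makes them hard to audit.  `vesselquant`
implements the whole chain as a tested Python library, and — because raw
microscopy from such studies is rarely deposited — ships a phantom
generator that produces images with *known* topology, permeability and
particle fates, so every stage can be proven to recover the truth.

## The quantities

**Morphometry** (per field of view, from a binary projection mask):
area coverage (% of the field that is vessel), skeleton branch count and
geodesic branch lengths, junction count J and endpoint count E, the
connectivity ratio J/E (higher = more interconnected network), and mean
vessel diameter measured wall-to-wall through each centerline pixel.

**Apparent permeability.**  With intensity linear in concentration,
negligible flux across the imaging boundary, and constant transendothelial
flux, the permeability of the vessels to a tracer is

```
P = A_T (I_Tf − I_T0) / (p_v · t · (I_V0 − I_T0))      [cm/s]
```

where `A_T` is the extravascular tissue area (cm²), `p_v` the vessel
perimeter (cm), `I_V0`/`I_T0` the mean intravascular/extravascular
intensities at t = 0, and `I_Tf` the extravascular mean at elapsed time
`t` (s).  A time-lapse yields one estimate per interval; the reported P is
their mean.

**Tracking.**  Spots are detected per frame (intensity-weighted centroids),
linked by greedy mutual-nearest-neighbour matching, speeds measured as
summed step displacement over elapsed time (µm/min), and each track's fate
classified at the final frame against the vessel mask: *intravascular*,
*transmigrating* (within a contact distance of the wall, either side), or
*extravasated* (fully outside).

## Worked example

```python
from vesselquant import phantom, imgproc, morphometry

spec = phantom.random_tree_network(seed=3)       # random vessel tree
stack, truth = phantom.generate_network_phantom(spec)

mask = imgproc.preprocess(stack, "EC")           # project → despeckle → smooth → binarize
record = morphometry.morphometry_record(mask)
print(record.as_dict())
```

The same pipeline through the CLI:

```
$ vesselquant phantom --seed 3 --out demo/
$ vesselquant preprocess --image demo/phantom_EC.tiff --channel image --out demo/mask.tiff
mask written to demo/mask.tiff (threshold 84.7)
$ vesselquant morph --mask demo/mask.tiff --out demo/morph.csv
$ cat demo/morph.csv
field_id,coverage_pct,branch_count,mean_branch_length_um,n_junctions,n_endpoints,connectivity_ratio,mean_diameter_um,flags
fov0,5.6488037109375,5,78.77063667463028,2,4,0.5,9.337841259140927,
```

This phantom was built with 2 junctions, 4 endpoints and 5 branches of
radius 3.5–4.5 px; the measured record reproduces the topology exactly
(connectivity ratio 2/4 = 0.5), covers 5.6 % of the field, and reads a
mean diameter of 9.3 µm — within the half-pixel rasterization uncertainty
of the constructed tubes.

The numbered drivers under `analysis/` run the full validation studies
(morphometry recovery, preprocessing oracles, permeability inversion, PMN
tracking, statistical calibration) and write their tables to `results/`.

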