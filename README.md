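# bgconnect

Post-tractography connectivity quantification for the deep-brain nuclei of
the basal ganglia: the subthalamic nucleus (STN), substantia nigra pars
compacta and reticulata (SNc, SNr), and the external and internal globus
pallidus (GPe, GPi).

Given a tractogram (MRtrix `.tck`, world-mm streamlines) and an integer
label volume (NIfTI-1) segmenting these nuclei plus any auxiliary ROIs
(internal capsule, red nucleus, named fibre paths, ...), `bgconnect`
computes:

* **track selection** — only tracks intersecting a seed structure
  (STN, SN = SNc ∪ SNr, GP = GPe ∪ GPi) enter the analysis;
* **seed-target connectivity tables** — for each nucleus, the percentage
  of its tracks that also intersect every other structure (each track
  counted once per pair, direct and indirect connections alike, with a
  configurable ≥ 1% inclusion threshold);
* **direct-connection matrices** — tracks cut into segments joining two of
  the five nuclei *without passing through a third* (auxiliary ROIs are
  transparent); symmetric segment counts and column-normalised, hence
  asymmetric, percentages whose nonzero columns each sum to 100;
* **voxel projection maps** — per voxel of a nucleus, the percentage of
  traversing tracks that reach a chosen target (NaN where no track
  passes), localising where projections originate;
* **structure volumes** and **anteromedial/posterolateral splits** along a
  structure's principal axis.

Because the kind of post-mortem specimen data this method was designed for
is generally not shareable, the package includes a **phantom** module:
synthetic label volumes and streamline bundles with *declared* visit paths
(straight corridors, arcs circling an obstacle, straight crossings through
it), from which every expected table follows in closed form. All analysis
stages are tested against these phantoms by exact integer equality.

The science behind the counting rules is documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import bgconnect as bg

# a synthetic scene mimicking the real acquisition: 0.5 mm voxels, five
# nuclei at realistic volume ratios, a capsule obstacle, 600 streamlines
spec = bg.paper_like_spec(n_tracks=600, rng_seed=0)
res = bg.make_phantom(spec)

ids, seqs = bg.select_seed_tracks(res.tractogram, res.volume, res.structures)
print(f"selected {len(ids)} of {res.tractogram.count} tracks")

matrix, segments = bg.direct_matrix(seqs, res.structures)
print(f"{len(segments)} direct segments")
print(matrix.percent.round(1))
```

prints

```
selected 600 of 600 tracks
678 direct segments
      STN   SNc   SNr   GPe   GPi
STN   0.0  40.4  29.8  31.6  25.6
SNc  34.5   0.0  48.9   5.3   7.7
SNr  25.5  48.9   0.0  10.5  15.4
GPe  21.8   4.3   8.5   0.0  51.3
GPi  18.2   6.4  12.8  52.6   0.0
```

Read column-wise: of all direct segments touching the STN, 40.4% join it
to the SNc. Columns are each nucleus's share of direct connections, so
the matrix is asymmetric although the underlying segment counts are
symmetric. The seed-target table (direct *and* indirect connections,
counted once per track) comes from the same label sequences:

```python
table = bg.apply_inclusion_threshold(bg.seed_target_table(seqs, res.structures), 1.0)
print(table.percent.round(1))
print("matches ground truth:", matrix.counts.equals(res.ground_truth.direct_counts))
```

```
          STN   SNc   SNr   GPe   GPi
STN       NaN  45.2  40.4  31.6  25.6
SNc      40.4   NaN  48.9   5.3  17.9
SNr      40.4  54.8   NaN  21.1  15.4
GPe      25.5   4.8  17.0   NaN  51.3
GPi      21.3  16.7  12.8  52.6   NaN
capsule  17.0   4.8  23.4  36.8   7.7
SN       70.2   NaN   NaN  26.3  33.3
GP       46.8  21.4  29.8   NaN   NaN
matches ground truth: True
```

Here 70.2% of STN tracks reach the SN; that is less than the SNc and SNr
entries summed because a track touching both counts once for SN (union
semantics). Column sums exceed 100% by design — one track connects a seed
to several targets. Blank cells mean target and seed overlap.

## Command line

```bash
bgconnect phantom make --preset paper-like --n-tracks 600 --seed 0 --out phantom/
bgconnect select --tck phantom/phantom.tck --labels phantom/labels.nii.gz \
    --structures phantom/structures.yaml --sequences sequences.json
bgconnect direct --sequences sequences.json --structures phantom/structures.yaml
bgconnect table  --sequences sequences.json --structures phantom/structures.yaml
bgconnect voxmap --tck phantom/phantom.tck --labels phantom/labels.nii.gz \
    --structures phantom/structures.yaml --structure SNc --target STN --out snc_to_stn.nii.gz
bgconnect run --config config.yaml     # end-to-end with report.json provenance
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch on the
paper-like phantom preset at full scale (9000 tracks, 0.05 mm steps):
generation, selection, direct-segment cutting with a seeded 9000-track
subsample, table construction with the 1% threshold, and a voxel
projection map, verifying each stage against the phantom's closed-form
ground truth. It exits non-zero if any check fails.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
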