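# readrsa

Model-based representational similarity analysis of word reading, end to
end on synthetic data:

- **lexicon** (`readrsa.lexicon`) — onset/vowel/coda slot schemes and binary
  orthographic (105-unit) / phonological (61-unit) word encodings, with TSV
  round-trip I/O. Multi-letter graphemes and compound phonemes activate
  their same-group constituents.
- **ann** (`readrsa.ann`) — a 105–100–61 logistic feedforward reading
  network trained by online backpropagation of cross-entropy, with a
  frequency-driven external input on target phoneme units that ramps up
  over training. Word scoring (exact), nonword scoring (Jaccard
  nearest-neighbor or exact over acceptable pronunciations), hidden-layer
  stimulus representations.
- **gpc** (`readrsa.gpc`) — a serial left-to-right grapheme–phoneme rule
  route (largest matching grapheme first, position classes respected); the
  word representation is the sparse indicator vector of fired rules, with
  an optional one-hot lexical extension.
- **rdm** (`readrsa.rdm`) — correlation-distance RDMs over z-scored
  features, RDM averaging, rank-based second-order comparison (Spearman and
  partial Spearman) and a pairwise model correlation table.
- **searchlight** (`readrsa.searchlight`) — spherical searchlight mapping
  over masked beta-series volumes (radius 3 voxels, 123-voxel spheres),
  Gaussian smoothing, Fisher transform, group one-sample t test and
  cluster-extent thresholding. NIfTI I/O via nibabel.
- **synth** (`readrsa.synth`) — synthetic inputs: Zipfian artificial
  lexicons with controlled spelling–sound consistency, nonwords with
  multiple acceptable pronunciations, rule tables, and multi-subject beta
  volumes with planted representational geometry.
- **pipeline / cli** (`readrsa.pipeline`, `readrsa.cli`) — config-driven
  orchestration with a JSON run report.

## CLI

```sh
readrsa all config.yaml         # simulate -> train-models -> rsa -> report
readrsa simulate config.yaml    # just write the synthetic dataset
readrsa train-models config.yaml
readrsa rsa config.yaml         # reuses cached RDMs from train-models
readrsa report config.yaml
```

Minimal config:

```yaml
seed: 3
output_dir: out
n_instantiations: 20
ann: {epochs: 400}
searchlight: {radius: 3}
inference: {fwhm_mm: 6.0, voxel_p: 0.001, cluster_extent_mm3: 234.9}
analyses:
  - {name: ann, model: ann_hidden}
  - {name: gpc, model: gpc}
  - {name: gpc_ctrl_ann, model: gpc, control: ann_hidden}
  - {name: ann_ctrl_gpc, model: ann_hidden, control: gpc}
simulate:
  lexicon: {n_words: 200, exception_proportion: 0.1}
  grid_shape: [24, 24, 24]
  mask_semi_axes: [9.0, 9.0, 9.0]
  rois:
    - {center: [12, 12, 12], radius: 4, source: ann_hidden, gain: 1.0}
  n_subjects: 18
```

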