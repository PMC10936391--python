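# synemclass

Synapse detection and neurotransmitter-valence prediction from
serial-section electron-microscopy (EM) image patches.

Building a connectome from serial-section EM means finding thousands of
chemical synapses by eye, and even a finished wiring diagram does not say
whether a connection is excitatory or inhibitory.  `synemclass`
implements a desk-scale version of a deep-learning workflow for both
problems, aimed at the *Ciona intestinalis* larval brain but applicable
to any serial-section dataset annotated with per-synapse point markers:

1. **Patch extraction** (`reconstruct_io`) — parse synapse "arrow"
   annotations (seven points per synapse, named `preID-postID`), map them
   from section coordinates through invertible per-section transforms
   (inverse trace transform, then forward image transform), and crop a
   fixed-size patch (500 × 500 px at full scale, 3.85 nm/px) around the
   arrow centroid.
2. **Synthetic EM generator** (`synthetic_em`) — because volume-scale EM
   data is rarely shareable, a first-class generator renders EM-like
   patches: dark membranes, presynaptic vesicle clusters with
   class-conditional count/size distributions, postsynaptic density
   bands, plus non-synaptic distractors (coated vesicles, botrysomes,
   autophagosomes), with 3–10 correlated z-frames per synapse.
3. **Leakage-free splits** (`dataset`) — near-duplicate removal
   (bounding-box IoU + pixel hashing) and train/val/test splitting
   grouped by (presynaptic, postsynaptic) cell-ID pairs so no connection
   straddles a split.
4. **Two-phase transfer training** (`model`) — a classifier ending in
   global average pooling (GAP) and a *bias-free* linear head.  Session
   one freezes the convolutional body and fits only the head; session
   two unfreezes everything at a lower learning rate.  The best model is
   the checkpoint with maximum validation accuracy.  A self-contained
   numpy CNN (`small_cnn`) runs everywhere; a ResNeXt-50 path is exposed
   for environments with the optional `torch` extra.
5. **Voting** (`neuron_vote`) — frame predictions are aggregated per
   synapse (majority, ties by mean probability), synapse calls are
   tallied per presynaptic neuron, and a neuron is called excitatory or
   inhibitory only when it has ≥ 3 votes *and* the winning count is
   strictly more than 1.5× the losing count; otherwise *inconclusive*.
6. **Explanation** (`cam_analysis`, `embedding`) — class activation maps
   `CAM_c(h, w) = Σ_k w_ck · F_k(h, w)` whose spatial mean equals the
   class logit exactly (the reason the head is bias-free), decomposed by
   Otsu-seeded watershed into regions filtered at 5,000 px (full scale)
   with centroid and mean activation per region; and per-synapse
   frame-averaged deep features reduced by PCA (20 dims) + t-SNE to 2-D.

## Worked example

Run the end-to-end synthetic workflow (generate → split → train →
predict → vote → CAM → embed) with strong class effects:

```python
from synemclass.cli import RunConfig, run_pipeline

cfg = RunConfig(seed=7, outdir="run", n_cells=12, synapses_per_cell=(4, 7),
                frames_per_synapse=(3, 4), epochs_phase1=5, epochs_phase2=10,
                effect="strong")
run_pipeline(cfg)
```

This prints per-stage logs and writes `run/summary.json` and
`run/votes.csv`.  With the seed above it reports

```
patch acc 1.0  synapse acc 1.0  best val 1.0  runtime ~6 s
```

and the vote table

```
   cell  n_excitatory  n_inhibitory     decision
cell000             0             3   inhibitory
cell001             2             0 inconclusive
cell003             1             0 inconclusive
cell004             0             2 inconclusive
cell005             3             0   excitatory
cell006             0             1 inconclusive
cell007             1             0 inconclusive
cell008             0             3   inhibitory
cell010             0             2 inconclusive
```

Cells with fewer than three test synapses are inconclusive by rule, not
by model uncertainty: the held-out split only sees part of each neuron's
connections.  The same workflow is available from the shell:

```bash
synemclass synth --out data --patch-size 128 --n-cells 12 --seed 7
synemclass train --data data --epochs1 5 --epochs2 10 --out run
synemclass predict --checkpoint run/checkpoint.npz --data data --out preds.csv
synemclass vote --predictions preds.csv --out neurons.csv
synemclass cam --checkpoint run/checkpoint.npz --data data --out cams
synemclass embed --checkpoint run/checkpoint.npz --data data --out emb
```

See `docs/methods.md` for the model, the generator's assumptions, and
every numerical choice.

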