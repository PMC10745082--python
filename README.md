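# taskdecode

Decoding multitask fMRI brain states with a hybrid of stacked-RBM (deep
belief network) temporal feature learning and two-stage sparse
representation, plus ratio-of-activation (ROA) component ranking.

The pipeline:

1. **Data preparation** (`taskdecode.preproc`) — extract masked voxel time
   series from 4D volumes, truncate all tasks to a common frame count
   (leading frames kept), normalize every voxel to zero mean / unit L2 norm,
   spatially concatenate tasks per subject, and draw a seeded uniform voxel
   subsample (Fisher–Yates permutation) for group-level training.
2. **Temporal dictionaries** (`taskdecode.dbn`) — train a stack of RBMs
   (Gaussian visible units on layer 1, Bernoulli above; CD-1 with momentum
   and weight decay) on voxel time series, form multilevel temporal features
   by successive weight-matrix products, and column-normalize each level
   into a temporal dictionary.
3. **Two-stage sparse coding** (`taskdecode.sparse`) — stage 1: L1-coded
   loadings of each subject/task signal matrix on the temporal dictionary
   (lambda1 = 0.1); stage 2: dictionary learning on the aggregated
   transposed loadings (atoms constrained to the unit L2 ball,
   lambda2 = 0.05), yielding group spatial atoms and sparse codes used as
   classification features. Held-out subjects are coded with the trained
   dictionaries only.
4. **Evaluation** (`taskdecode.classify`, `taskdecode.metrics`,
   `taskdecode.roa`) — subject-level k-fold cross-validation with a linear
   one-vs-one SVM; Pearson matching of temporal atoms to HRF-convolved task
   regressors and of spatial atoms to activation templates; ROA ranking
   (per-component population SD of per-task nonzero counts) with an
   incremental top-m classification experiment.
5. **Synthetic cohorts** (`taskdecode.synth`) — block designs, canonical
   double-gamma HRF, and simulated cohorts with planted task-specific
   networks, shared artifact components (edge/"movement" and slab/"cardiac"
   proxies) and Gaussian noise, so the whole pipeline is testable without
   external data.

Full-scale defaults mirror the method configuration (4 layers x 128
neurons, lambda1 = 0.1, lambda2 = 0.05, fivefold CV, 10% voxel subsample);
`RunConfig.desk_scale()` provides a small configuration for synthetic runs.

## CLI

Stages operate on a run directory:

```sh
taskdecode simulate   --out run/ --subjects 10 --tasks 3 --seed 1
taskdecode preprocess --run-dir run/
taskdecode train      --run-dir run/ --fold 0
taskdecode code       --run-dir run/ --fold 0
taskdecode classify   --run-dir run/ --fold 0
taskdecode roa        --run-dir run/ --fold 0 --steps 1,2,4,8,16
taskdecode report     --run-dir run/        # aggregates all classified folds
```

Configuration lives in `run/config.yaml`; every stage derives its
randomness from the single seed there.

Python API:

```python
from taskdecode import RunConfig, run_all
from taskdecode.synth import default_designs, simulate_cohort

cohort = simulate_cohort(10, default_designs(3), (8, 8, 8),
                         n_networks=3, n_artifacts=2, snr=2.0, seed=1)
report = run_all(cohort, RunConfig.desk_scale(seed=1))
```

## Notes

- Voxel linearization is F-order (first axis fastest) and round-trips
  exactly between vectors and volumes.
- Truncation keeps *leading* frames (which frames to keep is otherwise
  unspecified; leading frames preserve early blocks of every task).
- Temporal/spatial matching maximizes |r| and records the sign, since RBM
  weight columns and learned atoms have arbitrary sign.
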