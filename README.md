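# dscnl — dual-stage clean-sample selection for class-incremental learning under noisy labels

`dscnl` implements a rehearsal-based class-incremental learning (CIL)
pipeline for image classification streams — the setting of medical imaging
benchmarks such as blood-cell and pathology tile collections — in which a
fraction ρ of the training labels is wrong.  Label noise is doubly harmful
in CIL: it degrades learning of the current task *and* poisons the replay
buffer, so the noise bias compounds across tasks and amplifies catastrophic
forgetting.  The package targets researchers studying noisy-label continual
learning who want a compact, fully deterministic CPU implementation with a
synthetic stream generator, a forgetting baseline and the benchmark metric
arithmetic built in.

## The method

Tasks t = 1..T introduce disjoint class sets K_t.  The model f_θ has a
single unified output head over all classes and no task identifier at
inference.  Per task, three stages run in order:

1. **Clean-sample filtering.**  A fresh auxiliary expert network is
   warm-up trained on the raw noisy task data D̃_t while a history
   accumulates, per sample, C_i = Σ_epochs p(y = ỹ_i | x_i) — the softmax
   probability of the sample's *own* observed label.  Networks fit clean
   structure before memorising noise, so within each class the average
   confidence C_i/E is bimodal.  A two-component ("binary") Gaussian
   mixture is fitted per class by EM; samples whose posterior for the
   high-mean component clears a dynamic threshold τ form the clean subset
   D̄_t.  The loop (refit → select → train the auxiliary net one epoch on
   the selection) stops when |D̄_t| reaches round((1−ρ̂)·N_t), with ρ̂
   supplied or estimated by cross-validated disagreement.
2. **Representative–diverse replay sampling.**  Each clean sample is scored
   by test-time-augmentation voting: S stochastic augmentations are
   classified, V_c counts argmax votes, and U = 1 − max_c V_c / S.  A
   fixed-capacity buffer M gives every seen class an equal quota
   N_M / |∪K_c| and fills it at evenly spaced ranks of the
   uncertainty-sorted candidates, so replay spans class-centre through
   class-boundary samples.  Random and reservoir baselines are included.
3. **Experience soft replay.**  Training batches are drawn uniformly from
   D̄_t ∪ M.  Mixup pairs (λ ~ Beta(α,α), λ′ = max(λ, 1−λ)) produce virtual
   samples x′ = λ′x_i + (1−λ′)x_j with soft labels y′, and the objective is
   L = L_ce + β·L_mix — hard-label cross-entropy on the composed batch plus
   soft-label cross-entropy on the mixed batch (β = 0 recovers plain
   experience replay).

Evaluation records the lower-triangular accuracy matrix (accuracy on task τ
after training task t, τ ≤ t); **Final Average Accuracy (FAA)** is the
unweighted mean of the last row.  Selection quality is measured by purity
(the percentage of the selection whose observed label is correct) and by
the noise reduction of the induced *equivalent noise ratio* 1 − purity.

The desk-scale reference backbone is a small 3-block CNN written in plain
numpy (im2col convolutions, Adam, explicit backprop), which keeps full runs
bit-reproducible on one CPU thread.

## Worked example

`examples/04_incremental_benchmark.py` runs the full pipeline and the
finetune baseline on the same synthetic stream — 8 separable classes,
200 images/class at 32×32, 30% symmetric label noise, four binary tasks:

```
dscnl: FAA = 98.75
  after task 1: 100.00
  after task 2: 100.00  100.00
  after task 3: 100.00  100.00  100.00
  after task 4: 100.00  100.00   95.00  100.00
  per-task selection purity (%): [97.9, 88.7, 97.2, 89.5]

finetune: FAA = 25.00
  after task 1: 100.00
  after task 2:   0.00  100.00
  after task 3:   0.00    0.00  100.00
  after task 4:   0.00    0.00    0.00  100.00
```

Each row is the test accuracy on tasks 1..t after finishing task t.  The
finetune baseline forgets every earlier task (zeros left of the diagonal;
its FAA of 25 is just the last task divided by four tasks), while the
dual-stage pipeline keeps earlier tasks near-perfect.  The filter's
selections are 89–98% pure even though 30% of the stream's labels are
wrong.  The other example scripts walk through stream generation, the
per-class mixture diagnostics, the uncertainty-sorted buffer and the
fixture-table arithmetic, each printing and explaining its numbers.

A thin CLI mirrors the stages
(`dscnl simulate|filter|run|evaluate`), e.g.:

```bash
dscnl simulate --classes 8 --per-class 200 --noise 0.3 --seed 7 --out stream.npz
dscnl run --stream stream.npz --mode dscnl --noise-rate 0.3 --seed 7 --out report.json
```

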