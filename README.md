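# pemnet

Pectoral-muscle segmentation for MLO-view mammograms, built around a
**global channel attention** encoder–decoder, packaged with the rule-based
breast-extraction chain that precedes it, a synthetic phantom generator
with exact ground truth, and a six-metric evaluation suite — so the whole
framework is trainable and testable at desk scale on one CPU, with no
image downloads.

## Why

In mammography CAD pipelines the pectoral muscle appears as a bright wedge
in the top corner of mediolateral-oblique (MLO) views and is routinely
removed before lesion analysis, because its intensity distribution mimics
fibroglandular tissue. This package is for people studying or teaching
such pipelines: it provides the full chain — orientation/flip,
breast-region extraction, MLO/CC view classification, semantic
segmentation of the muscle, and evaluation — as small, seeded,
inspectable components.

## The model

The segmentation network is a Deeplabv3+-style encoder–decoder (staged
encoder at output stride 16, atrous spatial pyramid pooling with dilated
separable convolutions, light decoder with a low-level skip). Its core is
the **global channel attention module (GCAM)**: at each tapped encoder
stage `x`, global max and average pooling give a channel descriptor

    M_cat^x = [GMP(M^x); GAP(M^x)] ∈ R^{2C_x},

a two-layer MLP with shrink rate `r` refines it to the next stage's width,

    M_RCAMs^x = σ(W1 · ReLU(W2 · M_cat^x)),   h = max(1, round(2C_x / r)),

the result multiplies elementwise into the next stage's descriptor, and
after the last transition the accumulated vector reweights the channels of
the final feature map directly. Early-stage channel statistics therefore
reach the deepest features at a parameter cost of only
`(C/r)(C + C')` per refined transition (`C = 2C_x`, `C' = 2C_{x+1}`) —
for the default 16→32→64→128 backbone with `r = 8`, 1 920 parameters on a
~340 k-parameter model. `budget_chain` computes this closed form and the
test suite asserts it equals the measured parameter difference against an
attention-free baseline, exactly.

Preprocessing follows fixed rules: orient (more non-zero pixels on the
left ⇒ pectoral wall on the left, otherwise mirror), binarise at gray
level 20, keep the largest connected component, open with a 5 px disk,
crop to the bounding box. Evaluation reports IoU (class-averaged), global
pixel accuracy, Dice, Jaccard (target class), sensitivity and specificity,
with mean ± sample-std aggregation over repeated seeded trainings.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import dataclasses
from pemnet.phantom import PhantomSpec, generate_dataset, DEFAULT_MLO_RANGES
from pemnet.model import PeMNetConfig, TrainConfig, build_model
from pemnet.train import train, evaluate_model
from pemnet.metrics import aggregate
from pemnet.gcam import budget_chain

base = PhantomSpec(width=128, height=128, margin=4)
train_set, _ = generate_dataset(200, DEFAULT_MLO_RANGES, seed=0, base_spec=base)
test_set, _ = generate_dataset(20, DEFAULT_MLO_RANGES, seed=1, base_spec=base)

cfg = PeMNetConfig()                      # tiny backbone, GCAM taps on all stages
model = build_model(cfg, seed=0)
baseline = build_model(dataclasses.replace(cfg, gcam=None), seed=0)
print(f"parameters: {model.parameter_count()} (GCAM adds "
      f"{model.parameter_count() - baseline.parameter_count()} "
      f"= budget {budget_chain(cfg.gcam)})")

history = train(model, train_set, TrainConfig(max_epochs=10, seed=0))
print(f"loss: {history[0]['loss']:.3f} -> {history[-1]['loss']:.3f}")

report = aggregate([ms for ms, _ in evaluate_model(model, test_set)])
for name in ("iou_mean_class", "gpa", "dsc", "jaccard"):
    print(f"{name:>15}: {100 * report.mean[name]:.2f}%")
```

prints (a few minutes on one CPU):

```
parameters: 339114 (GCAM adds 1920 = budget 1920)
loss: 0.597 -> 0.026
 iou_mean_class: 93.81%
            gpa: 99.08%
            dsc: 93.89%
        jaccard: 88.62%
```

The model trains from scratch in 10 epochs on 200 synthetic phantoms and
segments held-out phantoms with a class-averaged IoU of ~94% and a
pectoral-class Jaccard of ~89%; the attention module costs exactly its
closed-form parameter budget.

The same workflow is scriptable from the shell:

```bash
pemnet phantom --n 50 --out data --seed 0          # synthetic labelled data
pemnet prep --in data/phantom_0000.png --out prepped
pemnet budget --channels 16,32,64,128 --r 8        # GCAM parameter accounting
pemnet run-all --config experiment.yaml --out results
```

`run-all` executes phantom generation → preprocessing → training of the
attention model and its baseline → evaluation, and writes a manifest from
which a rerun reproduces every numeric output byte for byte.

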