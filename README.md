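# msssl

Multi-scale self-supervised pretraining for diabetic-retinopathy (DR)
grading, for researchers who want to study momentum-encoder pretraining on
fundus photographs without large labeled datasets — and without a GPU.

DR grading is a 5-stage ordinal problem (0 = no DR … 4 = proliferative) where
labels are expensive and ImageNet transfer is weakened by the domain gap.
`msssl` pretrains a **multi-scale encoder** directly on unlabeled fundus
images: a vision transformer (global feature extractor) fused with a
ResNet + feature-pyramid network (fine-grained extractor, levels P2/P3/P5),
refined by a **Deep Learner** — transposed-convolution upsampling stages
ending in a CBAM attention block. Training pairs two objectives:

* **self-distillation**: cross-entropy between a momentum teacher's centered,
  temperature-sharpened softmax and the student's softmax, symmetrized over
  two augmented views — no negative pairs;
* **saliency segmentation**: BCE + soft-Dice between a segmentation head on
  the Deep Learner output and an Otsu-binarized saliency mask of the green
  channel, steering features toward lesion-bearing regions.

Downstream, representations are scored by linear probing and fine-tuning with
the quadratic weighted kappa

    kappa = 1 - (sum_ij w_ij O_ij) / (sum_ij w_ij E_ij),  w_ij = (i-j)^2 / (K-1)^2,

the standard chance-corrected, distance-weighted agreement statistic for
ordinal grading.

Everything runs on a built-in NumPy automatic-differentiation engine
(`msssl.nn`) — no deep-learning framework required — and a bundled synthetic
fundus generator (green-dominant retina disc, optic-disc highlight, vessel
tree, grade-dependent Poisson lesion counts) makes the whole pipeline
runnable and testable with no data download. See `docs/methods.md` for the
model, parameter and design details.

## Worked example

Generate a small labeled synthetic dataset, pretrain at desk scale, and probe
the frozen representation:

```python
from msssl.config import RunConfig
from msssl.synthetic import SyntheticConfig, generate_dataset
from msssl.ssl_train import pretrain
from msssl.eval_protocols import SplitSpec, split_dataset, linear_eval

cfg = RunConfig(**{
    "data": {"image_size": 64, "n_per_grade": 24, "lesion_rates": (0, 4, 10, 18, 30)},
    "augment": {"crop_size": 64},
    "encoder": {"embed_dim": 64, "depth": 2, "num_heads": 4,
                "fpn_backbone": "resnet18", "fpn_channels": 64, "resnet_width": 16,
                "input_size": 64, "proj_hidden": 256, "proj_dim": 64},
    "ssl": {"batch_size": 8, "epochs": 3},
    "runtime": {"seed": 0},
})

syn = SyntheticConfig(image_size=64, lesion_rate_per_grade=cfg.data.lesion_rates,
                      seed=cfg.runtime.seed)
images, manifest = generate_dataset(syn, cfg.data.n_per_grade)

result = pretrain(images, cfg)
print(f"pretraining: {result['state'].step} steps, "
      f"loss {result['history'][0]['total']:.3f} -> {result['history'][-1]['total']:.3f}")

splits = split_dataset(manifest, SplitSpec(seed=0))
report = linear_eval(result["state"], images, splits, cfg, seed=0)
print(f"linear probe: kappa={report.kappa:.3f} accuracy={report.accuracy:.1f}% "
      f"f1_weighted={report.f1_weighted:.1f}%")
```

Output (a few minutes on one CPU):

```
pretraining: 45 steps, loss 4.860 -> 7.036
linear probe: kappa=0.747 accuracy=55.0% f1_weighted=53.1%
```

Reading it: the probe's kappa of 0.747 on the held-out test split means the
frozen self-supervised features order the five synthetic grades far above
chance (a label-shuffled probe scores kappa ≈ 0); accuracy of 55% against a
20% chance level says most test images land on or adjacent to their true
grade. The early *rise* of the total loss is normal for self-distillation —
the teacher's targets sharpen away from the student's before the student
catches up; on longer runs (5 epochs, 300 images) the loss falls to roughly a
quarter of its initial value.

## Command line

```bash
msssl synth        --config cfg.yaml --out data/            # synthetic dataset + manifest
msssl preprocess   --data data/ --out prep/ --saliency fine_grained
msssl pretrain     --config cfg.yaml --data data/ --out runs/
msssl linear-eval  --checkpoint runs/checkpoint_ep004.npz --data data/ --out metrics.json
msssl finetune     --checkpoint runs/checkpoint_ep004.npz --data data/
msssl evaluate     --true truth.csv --pred pred.csv
msssl visualize-attention --checkpoint runs/checkpoint_ep004.npz --image img.png --out attn.png
```

An empty YAML config loads the framework's best settings (fine-grained
saliency, ResNet50 FPN, ViT-S patch 16, addition fusion, transposed-conv
Deep Learner with CBAM last); any block can be overridden, and invalid keys
or enum values are rejected with the offending path.

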