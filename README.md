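# shapearena

A comparison arena for generative models of anatomical shape and
appearance. Building a model that captures the shape variability of a
population of anatomical structures — lung fields and clavicles in a chest
radiograph, subcortical structures in a brain MRI — is a classical problem
in computational anatomy, and today there are two competing families of
solutions: statistical models built by PCA on corresponded landmarks, and
convolutional autoencoder variants trained on label or intensity images.
`shapearena` puts six families behind a single generative contract and
evaluates them with one shared metric suite on synthetic multi-structure
populations whose ground-truth variation modes are known, so every claim
about a model can be checked against the generator that produced the data.

## Model families

All models expose `fit`, `encode` (f), `decode` (g), `reconstruct` and
`sample`, in scikit-learn style:

* **SSM** — PCA on landmark vectors x ∈ R^(dm): mean shape x_μ, orthonormal
  basis U, latent z with x = x_μ + U z; the latent dimension p is the
  smallest number of modes covering 95% of the variance.
* **LSSM** — locality-based SSM: the sample covariance is attenuated
  elementwise by a compactly supported kernel of inter-landmark distance at
  several radii (global → fine), and each level's leading eigenmodes are
  accumulated into one orthonormal basis. More modes than PCA alone, hence
  better generalization from few samples.
* **SAM** — SSM plus PCA of "shape-normalized" intensities: images warped
  to the mean shape, modeled, sampled, and warped back.
* **AE / VAE / AE-GAN** — a fixed conv encoder (3 stride-2 convolutions,
  channels [in, 20, 40, 80], then a fully connected layer to z) with a
  mirrored upsample+conv decoder; the VAE adds a KL pull toward N(0, 1),
  the AE-GAN an adversarial real/fake discriminator on reconstructions.
* **DAE / ADAE** — the decoder emits a displacement field φ that warps a
  fixed template t, so reconstructions are t ∘ φ (ADAE: (t + a) ∘ φ with a
  decoded per-image intensity offset a and a split latent [z_s, z_a]); φ is
  regularized by diffusion + L1 terms, each weighted by 10.

Label images train against a weighted generalized Dice loss, intensity
images against an SSIM loss. The networks run on a small numpy
reverse-mode autodiff engine included in `shapearena.nn` — no GPU or deep
learning framework is required.

## Metric suite

For held-out real images r and generated samples s, with dist = ASSD
(average symmetric surface distance) for label images or L1 for
intensities:

* **Generalization ability** GA = mean_i dist(r_i, g(f(r_i)))
* **Specificity** = mean_j min_i dist(r_i, s_j) against the training set
* **Likeness (DSI)** = (KS({d_R}, {d_RS}) + KS({d_S}, {d_RS})) / 2 over
  intra- and between-set distance distributions; in [0, 1], smaller better
* **Normality** = % of latent dimensions a Shapiro–Wilk test rejects
* **Compactness** = latent dimensionality (PCA modes or configured size)
* **LAS** (latent ambiguity score) = mean ‖f(r) − f(g(f(r)))‖ divided by the
  mean pairwise encoded distance; exactly 0 for any linear PCA model

## Worked example

Fit a plain and a locality-based shape model on 10 synthetic thorax-like
shapes drawn from 8 ground-truth deformation modes, and evaluate both:

```python
from functools import partial
from shapearena import synthetic as syn
from shapearena.harness import LandmarkModelAdapter
from shapearena.metrics import (generalization_ability, specificity,
                                likeness_dsi, latent_ambiguity_score,
                                compactness)
from shapearena.representation import assd
from shapearena.statistical import StatisticalShapeModel, LocalityShapeModel

template = syn.build_template("thorax-like", (64, 64), seed=0)
basis = syn.build_deformation_basis(template, k=8, seed=1)
population = syn.sample_population(template, basis, 60,
                                   offset_scale=0.05, seed=2)
train = [population.instances[i] for i in population.split["train"]][:10]
test = [population.instances[i] for i in population.split["test"]][:10]
dist = partial(assd, structures=template.structures)

for name, cls, kw in [("SSM ", StatisticalShapeModel, {}),
                      ("LSSM", LocalityShapeModel, {"ndim": 2})]:
    model = LandmarkModelAdapter(cls(variability_threshold=0.95, **kw),
                                 template.grid_shape, template.layout).fit(train)
    ga = generalization_ability(model, test, dist, lambda i: i.label)
    spec = specificity(model, [t.label for t in train], len(train), dist, seed=0)
    dsi = likeness_dsi([t.label for t in train],
                       model.sample(len(train), random_state=0), dist)
    las = latent_ambiguity_score(model, test)
    print(f"{name}  modes={compactness(model):3d}  GA={ga:.2f}px  "
          f"specificity={spec:.2f}px  DSI={dsi:.2f}  LAS={las:.1e}")
```

prints

```
SSM   modes=  3  GA=0.85px  specificity=1.36px  DSI=0.17  LAS=3.2e-16
LSSM  modes= 94  GA=0.09px  specificity=1.55px  DSI=0.12  LAS=1.7e-14
```

With only 10 training shapes the plain PCA model keeps 3 modes and leaves
a 0.85-pixel reconstruction error on unseen shapes, while the locality
model's extra local modes cut that to 0.09 px at the cost of a far less
compact latent space; both have a latent ambiguity score at numerical
zero, as any linear model must. Sampled shapes from either model sit about
1.4 px from their nearest real training shape and are statistically hard
to separate from real draws (DSI ≈ 0.1–0.2).

The same loop runs unchanged over the neural families
(`shapearena.neural.Autoencoder`, `VariationalAutoencoder`,
`AdversarialAutoencoder`, `DeformableAutoencoder`,
`AppearanceDeformableAutoencoder`) through
`shapearena.harness.ImageModelAdapter`.

## Command line

```bash
arena simulate --kind thorax-like --n 120 --modes 3 --seed 1 --out pop/
arena fit --model ssm --train pop/ --out model
arena evaluate --model model --data pop/ --metrics ga,spec,dsi,las,compact
arena sweep --config sweep.yaml --out results/
arena interpolate --model model --data pop/ --steps 20
arena report --metrics results/metrics.csv --out report/
```

`arena sweep` orchestrates the full experiment: a training-size sweep with
multi-fold training (four folds for N < 100, two for N ≥ 100), fold-averaged
metrics, incremental CSV output that survives interruption, and plots of
each metric against training size.

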