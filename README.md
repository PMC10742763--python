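# madseg

Edge-driven multi-agent reinforcement-learning segmentation of
ultrasound-like images.

Breast lesions in B-mode ultrasound are notoriously hard to delineate:
speckle, acoustic shadows and tissue interfaces leave the edge map of an
image with broken boundaries (edge leaks), false branches and an
irregular global shape. `madseg` implements a multi-agent deep
reinforcement-learning (MADRL) segmentation method for this setting:
point agents living on the binary edge map trace and link boundary
fragments, guided by a family of offset curves around a coarse attention
mask and rewarded by Gestalt grouping criteria. The package is aimed at
researchers in medical image analysis who want a fully inspectable,
dependency-light reference implementation that runs on synthetic
phantoms with known ground truth.

## Method

1. **Attention mask** — histogram equalization, superpixel
   decomposition, and a simplified neutrosophic membership scheme keep
   the superpixels that confidently belong to the dark (hypoechoic)
   class; the mask restricts the search space, since the true boundary
   is only ~1–5% of the edge map.
2. **Offsets** — the mask contour is displaced along its normals at
   signed distances (trim-and-join of self-intersection loops, periodic
   cubic-spline refit); agents spawn on the innermost offset at equal
   arc intervals, alternating clockwise (CW) and counterclockwise (CCW)
   traversal senses.
3. **Agents** — each step the agent observes its edge/free state, the
   unit tangent *v*<sub>is</sub> of the nearest offset point, the
   windowed mean absolute curvature
   *s*<sub>i,C</sub>(t) = (1/t₂) ∫ |κᵢ(s)| ds (t₂ = 21 steps), the time
   spent off the edge *t*<sub>free</sub>, the local edge density
   *d*ᵢ in its r×r receptive window (r = 24 px), an aggregate of its
   neighbors' observations (mean/max/min/std under logarithmic degree
   scalers), and the last three receptive-field crops (edge map,
   grayscale, agent occupancy). Agents that stay off the edge longer
   than *t*<sub>live</sub> steps die.
4. **Rewards** — a weighted sum of five indicators (Gestalt laws):
   continuity by curvature (*s*<sub>i,C</sub> ≤ s′), continuity by
   collision angle (θ<sub>min</sub> = 118° ≤ θ ≤ 180° when a CW and a
   CCW agent meet), proximity (*t*<sub>free</sub> ≤ t<sub>cont</sub>),
   closure (returning to the departure point), and edge density
   (*d*ᵢ > d′). Shipped weights are the trained values
   (0.31, 0.23, 0.15, 0.12, 0.19); the two continuity terms carry 54%
   of a fully rewarded step.
5. **Policy/value networks** — identical architectures with disjoint
   parameters: three 3×3 convolutions (32/64/128 filters) each followed
   by 2×2 max pooling over the stacked memory frames, a linear
   flattening stage to a 256-vector, concatenation with the observation
   and aggregated features and the previous reward, two dense layers of
   128 rectifier units, and a head of five sigmoid units (normalized to
   a categorical distribution over heading increments relative to the
   offset tangent) or one linear unit (state value). Implemented in
   pure numpy with explicit backpropagation.
6. **Training** — PPO with clipped surrogate
   L<sub>θ</sub> = Ê[min(r_t(θ)Â_t, clip(r_t, 1±ε)Â_t)] and generalized
   advantage estimation (γ = 0.99, λ = 0.95, ε = 0.2, 40 policy and 40
   value epochs per round, Adam with lr 2·10⁻⁴ / 10⁻³), with a
   curriculum over the eight-level edge-map complexity taxonomy.
7. **Assembly** — trajectories that close on themselves or take part in
   CW–CCW collisions become boundary candidates; collision events chain
   candidates into closed contours scored by accumulated reward per
   unit length, smoothed by a periodic cubic spline and rasterized.

The package also implements the **S|Cmax|C complexity taxonomy** (shape
score against the minimum enclosing circle, total and maximum boundary
gap fractions, each binarized against corpus mean + std) and the
evaluation metrics: Hausdorff distance H1, average Hausdorff H2,
relative Hausdorff H3 = H2/L<sub>X</sub>·100%, pixel-count metrics
(Recall, Precision, Accuracy, Jaccard, Dice) and the success ratio
SGratio (share of cases with H3 ≤ 2%).

A synthetic phantom generator supplies ultrasound-like images with
exactly known boundaries, controlled gap structure, shape irregularity,
speckle-like noise and false-edge distractors, so every stage is
testable without any data download.

## Worked example

```python
from madseg.phantoms import PhantomSpec, make_phantom
from madseg.policy import NetworkSpec, PolicyNetwork
from madseg.environment import EnvConfig
from madseg.pipeline import segment

phantom = make_phantom(PhantomSpec(image_size=128, gap_total_frac=0.30,
                                   gap_max_frac=0.10, noise_sigma=0.25,
                                   seed=7))
policy = PolicyNetwork(NetworkSpec(receptive_field=16), seed=0)
result, report = segment(phantom, policy,
                         env_config=EnvConfig(receptive_field=16),
                         n_agents=16, seed=0)
print(f"H3 = {report.distH3:.2f} % (success: {report.success})")
print(f"Dice = {report.Dice:.2f} %")
```

prints

```
H3 = 0.68 % (success: True)
Dice = 95.99 %
```

i.e. on a phantom whose edge map is missing 30% of the boundary (largest
single gap 10%), the assembled contour deviates from the truth by 0.68%
of the boundary length on average — well under the 2% success rule — and
overlaps the true mask with a Dice index of 96%. Here the policy runs
from its initialization (a straight-ahead motion prior along the offset
tangents); `madseg.training.train_on_corpus` or the `madseg train` CLI
refines it with PPO.

The same pipeline is available from the shell:

```bash
madseg fixtures --n-per-category 5 --out corpus/
madseg train --iterations 30 --out runs/ckpt
madseg segment image.png --checkpoint runs/ckpt --out out/
madseg evaluate corpus/manifest.csv --checkpoint runs/ckpt --out summary.json
madseg categorize corpus/manifest.csv --out labeled.csv
```

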