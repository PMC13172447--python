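# voroslice

Stereological reconstruction of 3D cellular microstructures from 2D
sections, using differentiable periodic Voronoi tessellations fitted by
adversarial learning.

## The problem

Many materials — polycrystalline metals, foams, biological tissues — are
cellular: space partitions into domains whose size, shape and arrangement
control the bulk properties. Measuring such structures in 3D (FIB-SEM,
tomography) is destructive or expensive, while 2D sections are cheap. The
stereological question: given only planar section images, generate a full
3D structure whose own planar sections are statistically indistinguishable
from the measured ones.

## The model

A periodic Voronoi tessellation in W = [0, L)³ represents the 3D structure
with just three parameters per cell — its seed point sᵢ. The hard cell
indicator is relaxed to a softmax over negative periodic distances,

    Cᵢ(x) = exp(−β d̃(x, sᵢ)) / Σⱼ exp(−β d̃(x, sⱼ)),
    d̃(x, y) = min_{v ∈ {−L,0,L}³} ‖x − (y + v)‖,

making cell membership differentiable in the seeds. Random per-cell RGB
coloring turns structures into images; a fully convolutional patch
discriminator D (truncated VGG19, 11 feature modules, LeakyReLU α = 0.2,
spectral normalization, sigmoid head, 24×24-pixel field of view) scores
local patches of sections. Alternating Adam updates minimize

    L_T = mean ‖D(rendered section of C^S)‖₁        in the seed points,
    L_D = ‖D(measured section)‖₁ − L_T              in the weights of D,

while the seed count adapts every 100 iterations from the deficit in cell
profiles per unit section area. The result is a low-parameter, physically
interpretable 3D reconstruction (≈ 500× fewer parameters than the voxel
grid it replaces), which can be re-voxelized at any resolution.

Everything — the differentiable tessellation, the discriminator with its
backward pass, spectral normalization, Adam — is implemented on NumPy
arrays; no deep-learning framework is required. See `docs/methods.md` for
the full model description and numerical choices.

## Worked example

Reconstruct a known 40-cell hardcore tessellation in a 32³ window from its
96 planar sections (the scaled-down validation experiment; ~6 minutes on
one CPU):

```python
import voroslice as vs

result = vs.recovery_experiment(rng_seed=1)
print("true cells:", result.true_cell_count)
print("final seeds:", result.final_seed_count,
      f"({result.seed_count_rel_error_pct:.1f}% off)")
for k, f in result.improvement_factor.items():
    print(f"Wasserstein({k}) shrinks by x{f:.1f} vs untrained baseline")
```

prints

```
true cells: 40
final seeds: 36 (10.0% off)
Wasserstein(d_V) shrinks by x23.2 vs untrained baseline
Wasserstein(E) shrinks by x5.0 vs untrained baseline
Wasserstein(gamma) shrinks by x12.1 vs untrained baseline
```

Starting from 10 random seeds, the adaptation drives the seed count to
within 20% of the 40-cell truth, and adversarial training shrinks the 1-D
Wasserstein distance between input and output 2D descriptor distributions
(area-equivalent diameter d_V, elongation E, neighbor count γ) severalfold
relative to the untrained random tessellation it started from.

The same pipeline is scriptable from the shell:

```sh
voroslice simulate-pattern --kind twinning --n-initial 222 --l 100 --seed 1 --out seeds.csv
voroslice voxelize --seeds seeds.csv --out volume.tif
voroslice slice --volume volume.tif --out slices/        # 300 sections
voroslice fit --images slices/ --l 100 --iters 10000 --seed 1 --out run/
voroslice descriptors --image volume.tif --periodic --out cells.csv
voroslice compare --a cells.csv --b other.csv --out table.csv
```

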