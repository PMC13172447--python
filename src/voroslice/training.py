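"""Adversarial optimization of seed-point patterns.

Alternating scheme: the seed coordinates of a periodic Voronoi tessellation
are moved to minimize the mean patch score L_T that a discriminator assigns
to rendered planar sections, while the discriminator minimizes
L_D = (mean score on measured sections) - L_T, sharpening the statistics it
has learned.  Random per-cell recoloring of both measured and generated
sections at every step acts as implicit data augmentation.

The number of seeds is not known a priori; it adapts every ``adapt_every``
iterations by comparing the mean number of cell profiles per unit area
between generated and measured sections, adding or removing half of the
estimated deficit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discriminator import Discriminator, DiscriminatorConfig, build_discriminator
from .slicing import PlanarGrid, planar_grid, render_slice_with_tape, slice_label_image
from .tessellation import SeedPointPattern

__all__ = [
    "TrainingConfig",
    "TrainingState",
    "loss_tessellation",
    "loss_discriminator",
    "tessellation_loss_and_grad",
    "cells_per_area",
    "adapt_seed_count",
    "fit",
    "Adam",
]


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with default moment parameters; only the learning rate varies."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] = []
        self.v: list[np.ndarray] = []

    def _ensure(self, arrays: list[np.ndarray]) -> None:
        if not self.m:
            self.m = [np.zeros_like(a, dtype=np.float64) for a in arrays]
            self.v = [np.zeros_like(a, dtype=np.float64) for a in arrays]

    def step(self, values: list[np.ndarray], grads: list[np.ndarray]) -> None:
        """In-place descent step on each value array."""
        self._ensure(values)
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for val, g, m, v in zip(values, grads, self.m, self.v):
            g = np.asarray(g, dtype=np.float64)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            val -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                val.dtype
            )

    def resize_rows(self, index: int, keep: np.ndarray | None, add: int) -> None:
        """Adjust the moment rows of one state tensor after seed adaptation."""
        if not self.m:
            return
        for buf in (self.m, self.v):
            a = buf[index]
            if keep is not None:
                a = a[keep]
            if add:
                a = np.concatenate([a, np.zeros((add,) + a.shape[1:])], axis=0)
            buf[index] = a


# ---------------------------------------------------------------------------
# losses


def _mean_scores(disc, batch: np.ndarray, padding: str, train: bool, norm: str):
    """Forward a batch; return (scalar mean |score|, gradient wrt scores)."""
    s = disc.forward(batch, padding=padding, train=train)
    if norm == "mean":
        w = 1.0 / s.size
    elif norm == "sum":
        w = 1.0 / s.shape[0]  # per-image raw L1, averaged over the batch
    else:
        raise ValueError(f"unknown norm {norm!r}")
    value = float(np.abs(s).sum() * w)
    dscore = np.sign(s) * w
    return value, dscore


def _render_batch(S, colors, beta, slice_set):
    tapes = []
    imgs = []
    for grid in slice_set:
        img, tape = render_slice_with_tape(S, colors, beta, grid)
        imgs.append(img.transpose(2, 0, 1))
        tapes.append(tape)
    return np.stack(imgs), tapes


def loss_tessellation(
    disc,
    S: SeedPointPattern,
    colors: np.ndarray,
    beta: float,
    slice_set: list[PlanarGrid],
    padding: str = "periodic",
    norm: str = "mean",
) -> float:
    """Mean normalized L1 patch score of the rendered sections (lower = fools D).

    With ``slice_set`` covering all 3L grids this is the full average score
    over every planar section; by default the patch-score L1 norm is
    mean-normalized so score maps of different sizes contribute comparably
    (``norm="sum"`` restores the raw matrix L1).
    """
    if not slice_set:
        raise ValueError("slice_set must not be empty")
    batch, _ = _render_batch(S, colors, beta, slice_set)
    value, _ = _mean_scores(disc, batch, padding, train=False, norm=norm)
    return value


def tessellation_loss_and_grad(
    disc,
    S: SeedPointPattern,
    colors: np.ndarray,
    beta: float,
    slice_set: list[PlanarGrid],
    padding: str = "periodic",
    norm: str = "mean",
    train: bool = False,
    need_param_grad: bool = False,
) -> tuple[float, np.ndarray]:
    """L_T together with its analytic gradient with respect to the seeds."""
    if not slice_set:
        raise ValueError("slice_set must not be empty")
    batch, tapes = _render_batch(S, colors, beta, slice_set)
    value, dscore = _mean_scores(disc, batch, padding, train=train, norm=norm)
    if need_param_grad:
        disc.zero_grad()
    dimg = disc.backward(dscore, need_param_grad=need_param_grad)
    grad = np.zeros_like(S.points)
    for i, tape in enumerate(tapes):
        grad += tape.seed_gradient(dimg[i].transpose(1, 2, 0).astype(np.float64))
    return value, grad


def loss_discriminator(
    disc,
    real_images: list[np.ndarray],
    S: SeedPointPattern,
    colors: np.ndarray,
    beta: float,
    slice_set: list[PlanarGrid],
    norm: str = "mean",
) -> float:
    """L_D = mean patch score on measured sections - L_T on generated ones.

    Minimized with respect to the discriminator weights only; measured
    sections are scored without padding, generated ones with cyclic padding.
    """
    if not real_images:
        raise ValueError("at least one real image is required")
    vals = []
    for img in real_images:
        x = np.asarray(img, dtype=float).transpose(2, 0, 1)[None]
        v, _ = _mean_scores(disc, x, "none", train=False, norm=norm)
        vals.append(v)
    return float(np.mean(vals)) - loss_tessellation(
        disc, S, colors, beta, slice_set, norm=norm
    )


# ---------------------------------------------------------------------------
# seed-count adaptation


def cells_per_area(image: np.ndarray) -> float:
    """Distinct labels per pixel of a 2D label image (unit spacing)."""
    img = np.asarray(image)
    return float(len(np.unique(img))) / img.size


def adapt_seed_count(
    S: SeedPointPattern,
    n2d_sim: float,
    n2d_input: float,
    rng: np.random.Generator,
    scale: float | None = None,
) -> SeedPointPattern:
    """Add or remove ``floor(scale * |n2d_input - n2d_sim| / 2)`` seeds.

    ``n2d_*`` are mean cell counts per unit area in generated and measured
    sections.  ``scale`` defaults to ``L^3``; removals pick existing seeds
    uniformly at random and never drop below one seed; additions are uniform
    in the window and the returned pattern's ``metadata["adapt"]`` records
    the kept indices / number added so optimizer state can follow.
    """
    if n2d_sim < 0 or n2d_input < 0:
        raise ValueError("cell densities must be nonnegative")
    L = S.window_size
    if scale is None:
        scale = L**3
    # epsilon guards the floor against binary representation error
    # (e.g. 1e6 * 2e-4 / 2 evaluating to 99.9999...)
    delta = int(np.floor(scale * abs(n2d_input - n2d_sim) / 2.0 + 1e-9))
    meta = dict(S.metadata)
    if n2d_sim < n2d_input and delta > 0:
        new = rng.random((delta, 3)) * L
        pts = np.concatenate([S.points, new], axis=0)
        meta["adapt"] = {"kept": None, "added": delta}
    elif n2d_sim > n2d_input and delta > 0:
        delta = min(delta, S.n - 1)
        drop = rng.choice(S.n, size=delta, replace=False)
        keep = np.setdiff1d(np.arange(S.n), drop)
        pts = S.points[keep]
        meta["adapt"] = {"kept": keep, "added": 0}
    else:
        meta["adapt"] = {"kept": None, "added": 0}
        pts = S.points
    return SeedPointPattern(pts, L, meta)


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainingConfig:
    """Study conditions of a fitting run.

    Defaults follow the reference procedure: Adam learning rates 1e-5
    (discriminator) and 3e-1 (seeds), temperature beta=10 (voxel units),
    10,000 iterations, 300 initial seeds, seed-count adaptation every 100
    iterations.  ``slices_per_direction`` generated sections are sampled per
    direction per iteration (unbiased subsample of the full 3L-slice loss;
    set to L for the exact mode).  ``adapt_scale`` chooses the prefactor of
    the adaptation rule: "area" (L^2: half the deficit in mean profiles per
    section, a contraction) or "volume" (the literal L^3 rule).
    """

    L: int = 100
    iterations: int = 10_000
    lr_discriminator: float = 1e-5
    lr_seeds: float = 3e-1
    beta: float = 10.0
    initial_n: int = 300
    slices_per_direction: int = 1
    real_batch: int = 2
    adapt_every: int = 100
    adapt_slices: int = 12
    adapt_scale: str = "area"
    norm: str = "mean"
    rng_seed: int = 0
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)

    def __post_init__(self):
        if min(self.lr_discriminator, self.lr_seeds, self.beta) <= 0:
            raise ValueError("learning rates and beta must be positive")
        if self.adapt_every < 1:
            raise ValueError("adapt_every must be >= 1")
        if self.adapt_scale not in ("area", "volume"):
            raise ValueError("adapt_scale must be 'area' or 'volume'")


@dataclass
class TrainingState:
    """Result of :func:`fit`: final pattern, discriminator and histories."""

    pattern: SeedPointPattern
    discriminator: Discriminator
    iteration: int
    loss_T: list[float] = field(default_factory=list)
    loss_D: list[float] = field(default_factory=list)
    seed_counts: list[int] = field(default_factory=list)


def _recolor(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random RGB embedding of a 2D label image (fresh colors per call)."""
    uniq, inv = np.unique(labels, return_inverse=True)
    colors = rng.random((len(uniq), 3))
    return colors[inv].reshape(labels.shape + (3,))


def fit(real_images: list[np.ndarray], config: TrainingConfig) -> TrainingState:
    """Adversarially fit a periodic Voronoi tessellation to 2D label images.

    ``real_images`` are integer label maps of measured (or synthetic)
    sections, each at least as large as the discriminator's field of view.
    Fully reproducible from ``config.rng_seed``.
    """
    if not real_images:
        raise ValueError("at least one real image is required")
    real_images = [np.asarray(im) for im in real_images]
    rng = np.random.default_rng(config.rng_seed)
    disc = build_discriminator(
        config.discriminator, rng_seed=int(rng.integers(2**31 - 1))
    )
    rf = disc.receptive_field
    for im in real_images:
        if im.ndim != 2:
            raise ValueError("real images must be 2D label maps")
        if min(im.shape) < rf:
            raise ValueError(
                f"image {im.shape} smaller than the {rf}x{rf} field of view"
            )
    L = int(config.L)
    pattern = SeedPointPattern(
        rng.random((config.initial_n, 3)) * L,
        L,
        {"kind": "fit-initial", "rng_seed": config.rng_seed},
    )
    n2d_input = float(np.mean([cells_per_area(im) for im in real_images]))

    seed_opt = Adam(config.lr_seeds)
    disc_opt = Adam(config.lr_discriminator)
    state = TrainingState(pattern, disc, 0)

    for it in range(config.iterations):
        # (1) fresh colors; (2) sample sections and a real batch
        colors = rng.random((pattern.n, 3))
        grids = [
            planar_grid(d, int(k), L)
            for d in (1, 2, 3)
            for k in rng.choice(L, size=config.slices_per_direction, replace=False)
        ]
        idx = rng.choice(
            len(real_images), size=min(config.real_batch, len(real_images)), replace=False
        )
        real_batch = [_recolor(real_images[i], rng) for i in idx]

        # (3) L_T and its seed gradient; the same backward pass also yields
        # the generated-term parameter gradient of L_D
        lt, seed_grad = tessellation_loss_and_grad(
            disc,
            pattern,
            colors,
            config.beta,
            grids,
            train=True,
            need_param_grad=True,
        )
        gen_pgrads = [p["grad"].copy() for p in disc.parameters()]
        new_pts = pattern.points.copy()
        seed_opt.step([new_pts], [seed_grad])
        pattern = pattern.wrapped(new_pts)

        # (4) discriminator step on L_D = real - generated
        disc.zero_grad()
        real_vals = []
        for img in real_batch:
            x = np.asarray(img).transpose(2, 0, 1)[None]
            v, ds = _mean_scores(disc, x, "none", train=True, norm=config.norm)
            disc.backward(ds / len(real_batch), need_param_grad=True)
            real_vals.append(v)
        ld = float(np.mean(real_vals)) - lt
        params = disc.parameters()
        grads = [p["grad"] - g_gen for p, g_gen in zip(params, gen_pgrads)]
        disc_opt.step([p["value"] for p in params], grads)

        # (5) periodic seed-count adaptation
        if (it + 1) % config.adapt_every == 0:
            ks = rng.choice(L, size=min(config.adapt_slices, L), replace=False)
            ds = rng.integers(1, 4, size=len(ks))
            n2d_sim = float(
                np.mean(
                    [
                        cells_per_area(slice_label_image(pattern, planar_grid(d, int(k), L)))
                        for d, k in zip(ds, ks)
                    ]
                )
            )
            scale = L**2 if config.adapt_scale == "area" else L**3
            pattern = adapt_seed_count(pattern, n2d_sim, n2d_input, rng, scale=scale)
            info = pattern.metadata.get("adapt", {})
            seed_opt.resize_rows(0, info.get("kept"), info.get("added", 0))

        state.loss_T.append(lt)
        state.loss_D.append(ld)
        state.seed_counts.append(pattern.n)
        state.iteration = it + 1

    state.pattern = pattern
    return state
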