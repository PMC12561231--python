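"""Synthetic heterogeneous graphs with planted herb-target structure.

Two generators:

* :func:`make_toy_graph` — a nine-edge worked example over 3 herbs, 2
  ingredients and 3 targets whose metapath instances are known by hand;
  it anchors the enumeration tests.
* :func:`generate` — a planted-latent-factor simulator. Herbs,
  ingredients and targets receive latent vectors; herb-ingredient and
  ingredient-target edges are Bernoulli draws with a logistic link on
  latent affinity (the intercept is calibrated by bisection to hit the
  configured density); herb-efficacy edges attach each herb to its most
  affine efficacy prototypes; and the true herb-target positives are the
  top-affinity pairs, corrupted by a noise rate and partially masked for
  held-out evaluation. Because the planted signal is exactly the
  shared-ingredient/shared-efficacy structure the model exploits, link
  recovery on these graphs is a meaningful end-to-end check.

Default densities emulate the shape of the reference data set (128 herbs,
139 efficacies, 419 H-E, 14,302 H-I and 7,902 H-T relations); the small
preset scales the node counts down to desk size at similar densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import HeteroGraph


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the small desk-scale preset."""

    n_herbs: int = 30
    n_efficacies: int = 20
    n_ingredients: int = 80
    n_targets: int = 60
    latent_dim: int = 4
    density_hi: float = 0.056  # herb-ingredient edge density
    density_it: float = 0.05  # ingredient-target edge density
    density_ht: float = 0.04  # herb-target positive density
    efficacies_per_herb: int = 3
    affinity_scale: float = 3.0  # logistic-link sharpness on latent dot products
    noise_rate: float = 0.05  # fraction of true positives replaced at random
    holdout_fraction: float = 0.2  # positives masked for evaluation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_herbs", "n_efficacies", "n_ingredients", "n_targets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")
        for name in ("density_hi", "density_it", "density_ht"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0.0 <= self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in [0, 1)")


def reference_shape_config(seed: int = 0) -> SynthConfig:
    """Preset matching the reference data set's node counts and densities."""
    return SynthConfig(
        n_herbs=128,
        n_efficacies=139,
        n_ingredients=2000,
        n_targets=2000,
        density_hi=14302 / (128 * 2000),
        density_it=0.05,
        density_ht=7902 / (128 * 2000),
        efficacies_per_herb=3,
        seed=seed,
    )


@dataclass
class SynthResult:
    """A generated graph plus its ground truth.

    ``positives`` is the full true herb-target pair set; ``held_out`` is
    the masked subset absent from the graph's H-T edges; ``latents`` holds
    the planted factor matrices (keys ``H``, ``I``, ``T``) so tests can
    evaluate the exact latent-affinity oracle.
    """

    graph: HeteroGraph
    positives: list[tuple[str, str]]
    held_out: set[tuple[str, str]]
    latents: dict[str, np.ndarray] = field(default_factory=dict)

    def latent_affinity(self) -> np.ndarray:
        """The planted herb-by-target affinity matrix (the oracle score)."""
        return self.latents["H"] @ self.latents["T"].T


def make_toy_graph() -> HeteroGraph:
    """The worked-example graph: 3 herbs, 2 ingredients, 3 targets, 9 edges.

    Its H-I-H instances from H1 are the six walks H1-I2-H1 ... H1-I3-H3,
    and its T-H-I-T instances from T1 are T1-H1-I3-T3 and T1-H1-I2-T4.
    """
    g = HeteroGraph()
    for h in ("H1", "H2", "H3"):
        g.add_node("H", h)
    for i in ("I2", "I3"):
        g.add_node("I", i)
    for t in ("T1", "T3", "T4"):
        g.add_node("T", t)
    for h in ("H1", "H2", "H3"):
        g.add_edge("H-I", h, "I2")
        g.add_edge("H-I", h, "I3")
    g.add_edge("H-T", "H1", "T1")
    g.add_edge("I-T", "I2", "T4")
    g.add_edge("I-T", "I3", "T3")
    g.validate()
    return g


def _calibrated_bernoulli(
    affinity: np.ndarray, density: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a binary matrix whose edge probability is a logistic link on
    the affinity, with the intercept bisected so mean(prob) == density."""

    def mean_prob(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(scale * affinity + c)))))

    lo, hi = -60.0, 60.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if mean_prob(mid) < density:
            lo = mid
        else:
            hi = mid
    probs = 1.0 / (1.0 + np.exp(-(scale * affinity + (lo + hi) / 2.0)))
    return rng.random(affinity.shape) < probs


def generate(config: SynthConfig | None = None) -> SynthResult:
    """Sample a planted-structure heterogeneous graph.

    The returned graph contains H-I, H-E, I-T and the unmasked H-T edges;
    H-H and T-T similarity edges are intentionally absent — they are
    derived downstream from the incidences, mirroring the data-processing
    pipeline.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)

    herbs = [f"H{i + 1}" for i in range(config.n_herbs)]
    effs = [f"E{i + 1}" for i in range(config.n_efficacies)]
    ings = [f"I{i + 1}" for i in range(config.n_ingredients)]
    targets = [f"T{i + 1}" for i in range(config.n_targets)]

    k = config.latent_dim
    U = rng.normal(size=(config.n_herbs, k)) / np.sqrt(k)
    V_i = rng.normal(size=(config.n_ingredients, k))
    V_t = rng.normal(size=(config.n_targets, k))
    P_e = rng.normal(size=(config.n_efficacies, k))

    g = HeteroGraph()
    for t, ids in (("H", herbs), ("E", effs), ("I", ings), ("T", targets)):
        for n in ids:
            g.add_node(t, n)

    # herb-ingredient and ingredient-target incidences: logistic link
    HI = _calibrated_bernoulli(U @ V_i.T, config.density_hi, config.affinity_scale, rng)
    IT = _calibrated_bernoulli(V_i @ V_t.T, config.density_it, config.affinity_scale, rng)
    for i, j in zip(*np.nonzero(HI)):
        g.add_edge("H-I", herbs[i], ings[j])
    for i, j in zip(*np.nonzero(IT)):
        g.add_edge("I-T", ings[i], targets[j])

    # herb-efficacy: each herb joins its most affine efficacy prototypes
    eff_aff = U @ P_e.T
    n_eff = min(config.efficacies_per_herb, config.n_efficacies)
    for i in range(config.n_herbs):
        for j in np.argsort(-eff_aff[i])[:n_eff]:
            g.add_edge("H-E", herbs[i], effs[j])

    # true herb-target positives: top-affinity pairs, plus noise flips
    A = U @ V_t.T
    n_pos = max(1, int(round(config.density_ht * config.n_herbs * config.n_targets)))
    order = np.argsort(-A.ravel(), kind="stable")
    pos_codes = list(order[:n_pos])
    n_flip = int(round(config.noise_rate * n_pos))
    if n_flip:
        drop = set(rng.choice(len(pos_codes), size=n_flip, replace=False).tolist())
        complement = np.setdiff1d(
            np.arange(config.n_herbs * config.n_targets), np.asarray(pos_codes)
        )
        added = rng.choice(complement, size=n_flip, replace=False)
        pos_codes = [c for idx, c in enumerate(pos_codes) if idx not in drop] + list(added)
    pos_codes = sorted(int(c) for c in pos_codes)
    positives = [
        (herbs[c // config.n_targets], targets[c % config.n_targets]) for c in pos_codes
    ]

    n_hidden = int(round(config.holdout_fraction * len(positives)))
    hidden_idx = set(
        rng.choice(len(positives), size=n_hidden, replace=False).tolist()
    ) if n_hidden else set()
    held_out = {positives[i] for i in sorted(hidden_idx)}
    for idx, (h, t) in enumerate(positives):
        if idx not in hidden_idx:
            g.add_edge("H-T", h, t)

    g.validate()
    return SynthResult(
        graph=g,
        positives=positives,
        held_out=held_out,
        latents={"H": U, "I": V_i, "T": V_t, "E": P_e},
    )
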