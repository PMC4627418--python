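"""Synthetic benchmark data: planted "active complex" networks and values.

The generator emulates the structure that makes neighbor scoring work:
essential genes cluster in dense protein complexes, and the members of an
active complex carry coherently elevated values. Concretely:

* the network has ``n_modules`` disjoint modules of ``module_size`` genes;
  within-module gene pairs get an edge with probability
  ``intra_module_edge_prob`` at a high confidence weight, all other pairs
  with the much smaller ``background_edge_prob`` at a low weight;
* a fixed fraction of modules is "active"; per sample, genes in active
  modules have mean ``effect_size`` and everyone else mean 0, with i.i.d.
  Gaussian noise of sd ``noise_sd`` on top. Values are generated already
  centered (background mean 0), so the scoring step is exercised in
  isolation from the centering step;
* the screen variant signs the effect: "protective" modules get
  ``+effect_size`` (positively selected knockouts) and "sensitizing"
  modules ``−effect_size``, mimicking the two tails of a toxin screen.

Module membership is independent of degree by construction, giving the
logistic confounder analysis a clean null for the degree covariate. All
generators are pure functions of the spec (same spec ⇒ same dataset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import WeightedGeneNetwork

BACKGROUND = -1  # module label for genes outside every planted module


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module benchmark.

    Defaults are the package's standard benchmark conditions: 500 genes,
    10 modules of 10 of which 3 are active, dense modules (p=0.6, weight
    0.9) over a sparse low-confidence background (p=0.01, weight 0.2),
    unit effect size against unit noise.
    """

    n_genes: int = 500
    background_edge_prob: float = 0.01
    n_modules: int = 10
    module_size: int = 10
    intra_module_edge_prob: float = 0.6
    intra_module_weight: float = 0.9
    background_weight: float = 0.2
    active_fraction: float = 0.3
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_samples: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_modules * self.module_size > self.n_genes:
            raise ValidationError("n_modules * module_size must not exceed n_genes")
        if not (0 < self.background_edge_prob < 1) and self.background_edge_prob != 0:
            raise ValidationError("background_edge_prob must be in [0, 1)")
        if self.n_modules > 0 and not (0 < self.intra_module_edge_prob <= 1):
            raise ValidationError("intra_module_edge_prob must be in (0, 1]")
        if self.n_modules > 0 and self.intra_module_edge_prob <= self.background_edge_prob:
            raise ValidationError("modules must be denser than background")
        for name in ("intra_module_weight", "background_weight"):
            w = getattr(self, name)
            if not (0 < w <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")
        if not (0 < self.active_fraction <= 1):
            raise ValidationError("active_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.n_samples < 1 or self.n_genes < 2:
            raise ValidationError("need n_samples >= 1 and n_genes >= 2")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def n_active_modules(self) -> int:
        if self.n_modules == 0:
            return 0
        return max(1, round(self.active_fraction * self.n_modules))


@dataclass
class SyntheticDataset:
    """Network + planted labels + values + ground truth, ready for the pipeline."""

    network: WeightedGeneNetwork
    module_labels: dict[str, int]  # BACKGROUND (-1) for unplanted genes
    active_modules: frozenset[int]
    values: pd.DataFrame
    truth_positives: frozenset[str]
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)

    @property
    def background_genes(self) -> frozenset[str]:
        return frozenset(g for g in self.network.nodes if g not in self.truth_positives)


def _active_gene_mask(labels: dict[str, int], active_modules, genes: list[str]) -> np.ndarray:
    active = set(active_modules)
    return np.array([labels[g] in active for g in genes], dtype=bool)


def generate_network(spec: SyntheticSpec) -> tuple[WeightedGeneNetwork, dict[str, int]]:
    """Sample the planted-module network.

    The first ``n_modules * module_size`` genes form consecutive modules;
    same-module pairs get an edge with ``intra_module_edge_prob`` at
    ``intra_module_weight``, all other pairs with ``background_edge_prob``
    at ``background_weight``. Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    n = spec.n_genes
    labels = {g: BACKGROUND for g in genes}
    for m in range(spec.n_modules):
        for g in genes[m * spec.module_size : (m + 1) * spec.module_size]:
            labels[g] = m

    iu, ju = np.triu_indices(n, k=1)
    lab = np.array([labels[g] for g in genes])
    same_module = (lab[iu] == lab[ju]) & (lab[iu] != BACKGROUND)
    prob = np.where(same_module, spec.intra_module_edge_prob, spec.background_edge_prob)
    present = rng.random(len(iu)) < prob
    weight = np.where(same_module, spec.intra_module_weight, spec.background_weight)
    edges = (
        (genes[a], genes[b], float(w))
        for a, b, w in zip(iu[present], ju[present], weight[present])
    )
    return WeightedGeneNetwork.from_edges(edges, nodes=genes), labels


def generate_values(
    labels: dict[str, int],
    active_modules,
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Per-sample values: effect_size for active-module genes plus Gaussian noise.

    Values represent already-centered quantities (background mean 0).
    Returns the gene × sample matrix and the ground-truth positive set.
    """
    rng = np.random.default_rng(spec.seed + 1)  # independent of the network draw
    genes = list(labels)
    active = _active_gene_mask(labels, active_modules, genes)
    signal = spec.effect_size * active.astype(float)
    data = signal[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(genes), spec.n_samples))
    values = pd.DataFrame(
        data, index=genes, columns=[f"s{j}" for j in range(spec.n_samples)]
    )
    return values, frozenset(np.array(genes)[active])


def generate_screen(
    labels: dict[str, int],
    active_modules,
    spec: SyntheticSpec,
) -> tuple[pd.Series, frozenset[str], frozenset[str]]:
    """Signed screen fold changes: protective modules +effect, sensitizing −effect.

    Active modules alternate direction in sorted order (even positions
    protective, odd sensitizing). Returns the per-gene fold-change vector
    and the two directional truth sets.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = list(labels)
    ordered = sorted(active_modules)
    protective = {m for i, m in enumerate(ordered) if i % 2 == 0}
    sensitizing = set(ordered) - protective
    sign = np.array(
        [
            1.0 if labels[g] in protective else (-1.0 if labels[g] in sensitizing else 0.0)
            for g in genes
        ]
    )
    fold_change = spec.effect_size * sign + rng.normal(0.0, spec.noise_sd, size=len(genes))
    values = pd.Series(fold_change, index=genes, name="fold_change")
    gene_arr = np.array(genes)
    return (
        values,
        frozenset(gene_arr[sign > 0]),
        frozenset(gene_arr[sign < 0]),
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full benchmark dataset: network, labels, values, truth positives.

    The active modules are the first ``round(active_fraction * n_modules)``
    module ids, keeping the choice a pure function of the spec.
    """
    network, labels = generate_network(spec)
    active = frozenset(range(spec.n_active_modules()))
    values, truth = generate_values(labels, active, spec)
    return SyntheticDataset(
        network=network,
        module_labels=labels,
        active_modules=active,
        values=values,
        truth_positives=truth,
        spec=spec,
    )


def spec_to_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> SyntheticSpec:
    return replace(SyntheticSpec(), **d)
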