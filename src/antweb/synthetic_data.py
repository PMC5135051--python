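"""Synthetic multilayer ant-plant communities with planted structure.

The generator emits long-format interaction-event tables with the same
shape and statistical texture as a year of field sampling in a multi-site
tropical grassland study: a few hundred events across ~7 sites, a plant
guild several times richer than the ant guild, strongly skewed ant
frequencies with a few dominant species, a dominant "visit" layer, and
sparse feeding layers of increasing specialization (EFN < flower <
trophobiont), plus a marginal fruit layer restricted to a handful of ant
species.

Structure is planted through a simple propensity model: every species gets
a log-normal abundance weight and a latent trait in [0, 1]; the propensity
of a (plant, ant) pair in a layer is the product of the two weights, a
Gaussian trait-matching kernel whose bandwidth shrinks as the layer's
specialization grows, an optional module bonus, and core-species boosts
(one shared set of boosted ants across all layers; disjoint per-layer sets
of boosted plants).  Events are a single multinomial draw over (site,
layer, plant, ant) cells, so total event count is conserved exactly and
identical seeds give identical tables.

Separate helpers plant clean modular and nested matrices for metric tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import ValidationError
from .network_model import InteractionEvent, LayerMatrix, RESOURCE_TYPES

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "planted_modular_matrix",
    "planted_nested_matrix",
]

#: Relative specialization of each layer (multiplies the global knob).
#: Visits are a diffuse background; trophobiont tending is the most
#: partitioned resource, flowers intermediate, EFNs the most open feeding
#: layer — mirroring the ordering of specialization seen in the field.
LAYER_SPECIALIZATION: Mapping[str, float] = {
    "visit": 1.0,
    "EFN": 2.5,
    "flower": 4.0,
    "trophobiont": 6.0,
    "fruit": 3.0,
}

SEASONS = ("Jan", "Apr", "Jul", "Oct")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs of the synthetic community.

    Defaults emulate the scale of the field study the pipeline targets:
    7 sites, 78 plant and 30 ant species, 795 events, with two thirds of
    events being bare visits and a ~1% fruit layer.
    """

    n_sites: int = 7
    n_plants: int = 78
    n_ants: int = 30
    total_events: int = 795
    layer_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "EFN": 0.20,
            "flower": 0.08,
            "fruit": 0.01,
            "trophobiont": 0.05,
            "visit": 0.66,
        }
    )
    abundance_shape: float = 1.5  # log-normal sigma of species weights
    specialization: float = 1.0  # global trait-matching strength, >= 0
    n_planted_modules: int = 0  # per-layer modules; 0 = none
    module_bonus: float = 3.0
    core_ants_shared: int = 4
    ant_core_boost: float = 10.0
    plant_core_size: int = 5
    plant_core_boost: float = 14.0
    plant_core_disjoint: bool = True
    fruit_ant_pool: int = 4
    site_presence_prob: float = 0.6  # chance a plant occurs at a given site
    site_trait_jitter: float = 0.2  # SD of per-site ant trait displacement
    seed: int = 0

    def validate(self) -> None:
        mix = dict(self.layer_mix)
        if set(mix) - set(RESOURCE_TYPES):
            raise ValidationError(f"unknown layers in mix: {set(mix) - set(RESOURCE_TYPES)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValidationError("layer_mix must sum to 1")
        if self.total_events <= 0:
            raise ValidationError("total_events must be positive")
        if self.specialization < 0:
            raise ValidationError("specialization must be >= 0")
        if self.n_planted_modules > min(self.n_plants, self.n_ants):
            raise ValidationError("more planted modules than species")
        core_layers = ("EFN", "flower", "trophobiont")
        if (
            self.plant_core_disjoint
            and self.plant_core_size * len(core_layers) > self.n_plants
        ):
            raise ValidationError("not enough plants for disjoint per-layer cores")
        if self.core_ants_shared > self.n_ants or self.fruit_ant_pool > self.n_ants:
            raise ValidationError("core/fruit ant pools exceed n_ants")


@dataclass(frozen=True)
class GroundTruth:
    """Everything that was planted, for parameter-recovery tests."""

    plant_weights: np.ndarray
    ant_weights: np.ndarray
    plant_traits: np.ndarray
    ant_traits: np.ndarray
    core_ants: tuple[str, ...]
    layer_plant_cores: Mapping[str, tuple[str, ...]]
    module_assignment: Mapping[str, Mapping[str, int]]
    site_presence: np.ndarray  # (n_sites, n_plants) boolean
    fruit_ants: tuple[str, ...]


def _species_labels(n_plants: int, n_ants: int) -> tuple[list[str], list[str]]:
    return (
        [f"P{i + 1:03d}" for i in range(n_plants)],
        [f"A{j + 1:02d}" for j in range(n_ants)],
    )


def generate(config: Optional[GeneratorConfig] = None) -> tuple[list[InteractionEvent], GroundTruth]:
    """Draw one synthetic event table plus its ground truth."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    plants, ants = _species_labels(cfg.n_plants, cfg.n_ants)
    layers = [r for r in RESOURCE_TYPES if cfg.layer_mix.get(r, 0.0) > 0]

    pw = rng.lognormal(0.0, cfg.abundance_shape, cfg.n_plants)
    aw = rng.lognormal(0.0, cfg.abundance_shape, cfg.n_ants)
    tp = rng.uniform(0.0, 1.0, cfg.n_plants)
    ta = rng.uniform(0.0, 1.0, cfg.n_ants)

    # shared ant core: the heaviest ants, boosted identically in every layer.
    # Dominant, massively recruiting ants are trait generalists: their latent
    # traits sit in the middle of the plant spectrum so they stay central in
    # every layer regardless of how narrow the layer's matching kernel is.
    core_ant_idx = np.argsort(-aw, kind="stable")[: cfg.core_ants_shared]
    if cfg.core_ants_shared > 0:
        ta[core_ant_idx] = np.linspace(0.35, 0.65, cfg.core_ants_shared)
    aw_boosted = aw.copy()
    aw_boosted[core_ant_idx] *= cfg.ant_core_boost

    # disjoint per-layer plant cores on the feeding layers; like the core
    # ants, the favoured resource plants of each layer are trait-typical so
    # that the dominant generalist ants attend them in every layer
    core_layers = [l for l in ("EFN", "flower", "trophobiont") if l in layers]
    plant_core_idx: dict[str, np.ndarray] = {}
    if cfg.plant_core_size > 0 and core_layers:
        pool = rng.permutation(cfg.n_plants)
        for k, layer in enumerate(core_layers):
            if cfg.plant_core_disjoint:
                idx = pool[k * cfg.plant_core_size : (k + 1) * cfg.plant_core_size]
            else:
                idx = pool[: cfg.plant_core_size]
            plant_core_idx[layer] = idx
            tp[idx] = np.linspace(0.4, 0.6, len(idx))

    # per-layer module assignment (optional)
    module_assignment: dict[str, dict[str, int]] = {}
    layer_modules: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if cfg.n_planted_modules > 0:
        for layer in layers:
            pm = rng.integers(0, cfg.n_planted_modules, cfg.n_plants)
            am = rng.integers(0, cfg.n_planted_modules, cfg.n_ants)
            layer_modules[layer] = (pm, am)
            module_assignment[layer] = {
                **{plants[i]: int(pm[i]) for i in range(cfg.n_plants)},
                **{ants[j]: int(am[j]) for j in range(cfg.n_ants)},
            }

    # site occupancy: each plant present at a random subset of sites; the
    # core resource plants of each layer are widespread (present everywhere)
    presence = rng.random((cfg.n_sites, cfg.n_plants)) < cfg.site_presence_prob
    for i in np.where(~presence.any(axis=0))[0]:
        presence[rng.integers(cfg.n_sites), i] = True
    for idx in plant_core_idx.values():
        presence[:, idx] = True

    fruit_ant_idx = np.argsort(-aw, kind="stable")[: cfg.fruit_ant_pool]

    # propensity tensor over (site, layer, plant, ant); ant traits get a
    # per-site displacement (local populations differ in activity), which
    # makes the identity of trait-matching ants turn over between sites
    prop = np.zeros((cfg.n_sites, len(layers), cfg.n_plants, cfg.n_ants))
    ta_site = ta[None, :] + rng.normal(0.0, cfg.site_trait_jitter, (cfg.n_sites, cfg.n_ants))
    d2 = (tp[None, :, None] - ta_site[:, None, :]) ** 2  # (site, plant, ant)
    for li, layer in enumerate(layers):
        s = cfg.specialization * LAYER_SPECIALIZATION[layer]
        match = np.exp(-((s) ** 2) * d2)
        pw_l = pw.copy()
        if layer in plant_core_idx:
            pw_l[plant_core_idx[layer]] *= cfg.plant_core_boost
        aw_l = aw_boosted.copy()
        if layer == "fruit":
            mask = np.zeros(cfg.n_ants, dtype=bool)
            mask[fruit_ant_idx] = True
            aw_l = np.where(mask, aw_l, 0.0)
        cell = np.outer(pw_l, aw_l)[None, :, :] * match  # (site, plant, ant)
        if layer in layer_modules:
            pm, am = layer_modules[layer]
            cell = cell * np.where(pm[:, None] == am[None, :], cfg.module_bonus, 1.0)
        block = cell * presence[:, :, None]
        # normalize each (site, layer) block so the expected share of events
        # per layer equals the configured mix exactly, with sites balanced,
        # regardless of how much mass the matching kernel removes
        sums = block.reshape(cfg.n_sites, -1).sum(axis=1)
        sums = np.where(sums > 0, sums, 1.0)
        prop[:, li] = cfg.layer_mix[layer] * block / (cfg.n_sites * sums[:, None, None])

    p = prop.ravel()
    p = p / p.sum()
    counts = rng.multinomial(cfg.total_events, p).reshape(prop.shape)

    # expand cell counts into one row per event
    flat = counts.ravel()
    occupied = np.nonzero(flat)[0]
    reps = flat[occupied]
    cells = np.repeat(occupied, reps)
    s_idx, l_idx, p_idx, a_idx = np.unravel_index(cells, counts.shape)
    n = cells.size
    seasons = rng.choice(SEASONS, size=n)
    plots = rng.integers(1, 6, size=n)
    is_core_ant = np.isin(a_idx, core_ant_idx)
    workers = np.where(
        is_core_ant, rng.geometric(0.25, size=n), rng.geometric(0.6, size=n)
    )
    events = [
        InteractionEvent(
            site_id=f"S{s_idx[k] + 1}",
            plot_id=f"p{plots[k]}",
            season=str(seasons[k]),
            plant_sp=plants[p_idx[k]],
            ant_sp=ants[a_idx[k]],
            resource=layers[l_idx[k]],
            workers=int(workers[k]),
        )
        for k in range(n)
    ]
    truth = GroundTruth(
        plant_weights=pw,
        ant_weights=aw,
        plant_traits=tp,
        ant_traits=ta,
        core_ants=tuple(ants[i] for i in sorted(core_ant_idx)),
        layer_plant_cores={
            l: tuple(plants[i] for i in sorted(idx)) for l, idx in plant_core_idx.items()
        },
        module_assignment=module_assignment,
        site_presence=presence,
        fruit_ants=tuple(ants[i] for i in sorted(fruit_ant_idx)),
    )
    return events, truth


# -- planted fixtures -------------------------------------------------------


def planted_modular_matrix(
    n_rows: int,
    n_cols: int,
    k: int,
    noise: float,
    total: int,
    seed: int = 0,
) -> tuple[LayerMatrix, dict[str, int]]:
    """Random matrix with k planted modules and known assignment.

    A within-module cell carries propensity ``1 - noise``; each
    between-module cell carries ``noise / (k - 1)``, so at
    ``noise = (k-1)/k`` the matrix is uniform and the planted partition
    carries no signal.  Species emptied by the multinomial draw are
    dropped from both the matrix and the returned assignment.
    """
    if not (0.0 <= noise < 1.0):
        raise ValidationError("noise must be in [0, 1)")
    if k < 1 or k > min(n_rows, n_cols):
        raise ValidationError("k must be between 1 and min(n_rows, n_cols)")
    rng = np.random.default_rng(seed)
    plants, ants = _species_labels(n_rows, n_cols)
    pm = np.arange(n_rows) % k
    am = np.arange(n_cols) % k
    between = noise / (k - 1) if k > 1 else 0.0
    W = np.where(pm[:, None] == am[None, :], 1.0 - noise, between)
    p = W.ravel() / W.sum()
    A = rng.multinomial(total, p).reshape(n_rows, n_cols)
    keep_r = A.sum(axis=1) > 0
    keep_c = A.sum(axis=0) > 0
    layer = LayerMatrix(
        "EFN",
        [p_ for p_, kk in zip(plants, keep_r) if kk],
        [a_ for a_, kk in zip(ants, keep_c) if kk],
        A[np.ix_(keep_r, keep_c)],
    )
    assignment = {
        **{plants[i]: int(pm[i]) for i in np.where(keep_r)[0]},
        **{ants[j]: int(am[j]) for j in np.where(keep_c)[0]},
    }
    return layer, assignment


def planted_nested_matrix(
    n_rows: int,
    n_cols: int,
    decay: float,
    total: int,
    seed: int = 0,
    triangular: bool = True,
) -> LayerMatrix:
    """Random matrix with geometrically decaying, optionally triangular fill.

    Cell propensity is ``decay**(i + j)``; with ``triangular=True`` cells
    below the anti-diagonal are zeroed, producing the decreasing-fill
    pattern that weighted nestedness rewards.  ``decay`` near 1 with full
    support approaches a uniform (non-nested) matrix.
    """
    if not (0.0 < decay < 1.0):
        raise ValidationError("decay must be in (0, 1)")
    rng = np.random.default_rng(seed)
    plants, ants = _species_labels(n_rows, n_cols)
    i = np.arange(n_rows)[:, None]
    j = np.arange(n_cols)[None, :]
    W = decay ** (i + j).astype(float)
    if triangular:
        W = np.where(i / n_rows + j / n_cols < 1.0 + 1e-9, W, 0.0)
    p = W.ravel() / W.sum()
    A = rng.multinomial(total, p).reshape(n_rows, n_cols)
    keep_r = A.sum(axis=1) > 0
    keep_c = A.sum(axis=0) > 0
    return LayerMatrix(
        "EFN",
        [p_ for p_, kk in zip(plants, keep_r) if kk],
        [a_ for a_, kk in zip(ants, keep_c) if kk],
        A[np.ix_(keep_r, keep_c)],
    )
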