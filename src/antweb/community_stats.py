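"""Site-level descriptors, core-species extraction, and multivariate tests.

Two questions drive this module.  First, do resource types differ in simple
descriptors of their site-level networks (size, richness, frequency of
interactions)?  That is answered by Poisson GLMs with resource type as the
predictor and site as the replicate.  Second, is the *composition* of the
core of central species (degree above the network average) shared across
resource layers?  That is answered by PERMANOVA on a Jaccard distance
matrix over per-site core membership, visualized by NMDS ordination.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDesignError, EmptyLayerError, ValidationError
from .metrics import degree_centrality
from .network_model import InteractionEvent, LayerMatrix, build_layer

logger = logging.getLogger(__name__)

__all__ = [
    "SiteDescriptor",
    "CoreSet",
    "PermanovaResult",
    "NmdsResult",
    "site_descriptors",
    "descriptor_table",
    "poisson_glm_test",
    "extract_core",
    "build_core_incidence",
    "core_distance_matrix",
    "permanova",
    "core_similarity_permanova",
    "nmds",
]


@dataclass(frozen=True)
class SiteDescriptor:
    """Coarse descriptors of one site-level resource network.

    ``size`` counts interacting species (plants + ants), ``richness`` counts
    distinct plant-ant pairs (links), ``frequency`` counts events.  An empty
    site-layer yields zeros with ``empty=True``.
    """

    site_id: str
    resource: str
    size: int
    richness: int
    frequency: int
    empty: bool = False


@dataclass(frozen=True)
class CoreSet:
    """Above-average-degree species of one (site, resource) network."""

    site_id: str
    resource: str
    core_ants: frozenset[str]
    core_plants: frozenset[str]
    threshold: float


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA (Anderson partitioning) on a distance matrix."""

    pseudo_F: float
    R2: float
    p_value: float
    n_perm: int
    distance: str
    n_obs: int
    n_groups: int


@dataclass(frozen=True)
class NmdsResult:
    """NMDS ordination: centered coordinates and Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    labels: tuple[str, ...] = ()


# -- descriptors ------------------------------------------------------------


def site_descriptors(
    events: Sequence[InteractionEvent], resource: str, site: str
) -> SiteDescriptor:
    """Size, richness, and frequency of one site-level resource network."""
    try:
        layer = build_layer(events, resource, sites=[site])
    except EmptyLayerError:
        return SiteDescriptor(site, resource, 0, 0, 0, empty=True)
    return SiteDescriptor(
        site_id=site,
        resource=resource,
        size=layer.shape[0] + layer.shape[1],
        richness=layer.n_links,
        frequency=layer.F,
    )


def descriptor_table(
    events: Sequence[InteractionEvent],
    resources: Iterable[str],
    sites: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Long table of descriptors over every (site, resource) combination."""
    if sites is None:
        sites = sorted({e.site_id for e in events})
    rows = [
        site_descriptors(events, r, s).__dict__
        for s in sites
        for r in resources
    ]
    return pd.DataFrame(rows)


def poisson_glm_test(
    descriptors: pd.DataFrame, response: str
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a resource effect on a count descriptor.

    Fits a log-link Poisson GLM ``response ~ resource`` (site rows as
    replicates) and compares its deviance against the intercept-only model;
    the deviance difference is referred to a chi-square distribution on
    (levels - 1) degrees of freedom.  Returns (deviance difference, df, p).
    """
    if response not in ("size", "richness", "frequency"):
        raise ValueError(f"unknown response {response!r}")
    df = descriptors.copy()
    y = df[response].to_numpy()
    if not np.allclose(y, np.round(y)) or np.any(y < 0):
        raise ValidationError(f"{response} must be non-negative integer counts")
    levels = df["resource"].nunique()
    if levels < 2 or df["site_id"].nunique() < 2:
        raise DegenerateDesignError("need >=2 resource levels and >=2 sites")
    fit = smf.glm(
        f"{response} ~ C(resource)", data=df, family=sm.families.Poisson()
    ).fit()
    null = smf.glm(
        f"{response} ~ 1", data=df, family=sm.families.Poisson()
    ).fit()
    dev = float(null.deviance - fit.deviance)
    ddf = levels - 1
    from scipy.stats import chi2

    return dev, ddf, float(chi2.sf(dev, ddf))


# -- core extraction --------------------------------------------------------


def extract_core(A: LayerMatrix, per_guild: bool = False) -> CoreSet:
    """Core of central species: degree strictly above the network average.

    By default the threshold is the mean degree over all nodes pooled
    across guilds (one network average); ``per_guild=True`` thresholds
    plants and ants against their own guild means instead.
    """
    degrees = degree_centrality(A)
    if per_guild:
        plant_thr = float(np.mean([degrees[p] for p in A.plants]))
        ant_thr = float(np.mean([degrees[a] for a in A.ants]))
        threshold = (plant_thr + ant_thr) / 2.0
        core_p = frozenset(p for p in A.plants if degrees[p] > plant_thr)
        core_a = frozenset(a for a in A.ants if degrees[a] > ant_thr)
    else:
        threshold = float(np.mean(list(degrees.values())))
        core_p = frozenset(p for p in A.plants if degrees[p] > threshold)
        core_a = frozenset(a for a in A.ants if degrees[a] > threshold)
    site = next(iter(A.provenance)) if len(A.provenance) == 1 else "pooled"
    return CoreSet(
        site_id=site,
        resource=A.resource,
        core_ants=core_a,
        core_plants=core_p,
        threshold=threshold,
    )


def build_core_incidence(cores: Sequence[CoreSet], guild: str = "ants") -> pd.DataFrame:
    """Site x species presence/absence table of core membership.

    One row per (site, resource) core; rows with an empty core for the
    chosen guild are dropped (they carry no composition) with a logged
    count.  The row index is "site|resource"; a ``resource`` column keeps
    the grouping factor.
    """
    attr = "core_ants" if guild == "ants" else "core_plants"
    kept = [c for c in cores if getattr(c, attr)]
    n_dropped = len(cores) - len(kept)
    if n_dropped:
        logger.info("dropped %d empty %s cores from incidence table", n_dropped, guild)
    if not kept:
        raise DegenerateDesignError(f"every {guild} core is empty")
    species = sorted(set().union(*(getattr(c, attr) for c in kept)))
    data = np.zeros((len(kept), len(species)), dtype=int)
    sp_idx = {s: j for j, s in enumerate(species)}
    for i, c in enumerate(kept):
        for s in getattr(c, attr):
            data[i, sp_idx[s]] = 1
    idx = [f"{c.site_id}|{c.resource}" for c in kept]
    df = pd.DataFrame(data, index=idx, columns=species)
    df.insert(0, "resource", [c.resource for c in kept])
    return df


def core_distance_matrix(incidence: pd.DataFrame, distance: str = "jaccard") -> np.ndarray:
    """Pairwise distances between core-composition rows (square matrix)."""
    X = incidence.drop(columns="resource").to_numpy()
    if distance == "jaccard":
        D = squareform(pdist(X.astype(bool), metric="jaccard"))
    elif distance == "braycurtis":
        D = squareform(pdist(X.astype(float), metric="braycurtis"))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return D


# -- PERMANOVA --------------------------------------------------------------


def _pseudo_f(D2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Anderson (2001) pseudo-F and R2 from squared distances and labels."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    labels, counts = np.unique(groups, return_counts=True)
    for g, ng in zip(labels, counts):
        idx = np.where(groups == g)[0]
        if ng > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    a = len(labels)
    df_between = a - 1
    df_within = n - a
    if df_within <= 0 or ss_within <= 0:
        return np.inf, 1.0 if ss_total > 0 else 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(
    D: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    distance: str = "jaccard",
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F of a grouping factor on a distance matrix.

    The p-value comes from free permutation of the observation labels; with
    ``exhaustive=True`` every permutation of the rows is enumerated and the
    p-value is the exact proportion of permutations (identity included)
    with pseudo-F at least the observed — feasible only for small designs.
    Monte-Carlo p-values use the add-one convention.
    """
    D = np.asarray(D, dtype=float)
    groups = np.asarray(groups)
    n = D.shape[0]
    if D.shape != (n, n) or len(groups) != n:
        raise ValidationError("distance matrix and group labels are inconsistent")
    if len(np.unique(groups)) < 2:
        raise DegenerateDesignError("PERMANOVA needs >=2 groups")
    if not np.any(D[np.triu_indices(n, 1)] > 0):
        raise DegenerateDesignError("all distances are zero")
    D2 = D**2
    f_obs, r2 = _pseudo_f(D2, groups)
    tol = 1e-12
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        count = sum(
            1
            for p in perms
            if _pseudo_f(D2, groups[list(p)])[0] >= f_obs - tol
        )
        p_value = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _pseudo_f(D2, groups[perm])[0] >= f_obs - tol:
                count += 1
        p_value = (1 + count) / (n_perm + 1)
        n_used = n_perm
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=float(p_value),
        n_perm=n_used,
        distance=distance,
        n_obs=n,
        n_groups=int(len(np.unique(groups))),
    )


def core_similarity_permanova(
    cores: Sequence[CoreSet],
    guild: str = "ants",
    distance: str = "jaccard",
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Is core composition similar across resource layers?

    Builds the per-(site, resource) presence/absence incidence of core
    membership for one guild, computes pairwise distances, and tests the
    resource grouping by PERMANOVA.  Sites with empty cores are dropped;
    at least two resources and two rows per analysis are required.
    """
    incidence = build_core_incidence(cores, guild=guild)
    if incidence["resource"].nunique() < 2 or len(incidence) < 3:
        raise DegenerateDesignError(
            "need >=2 resource groups and >=3 non-empty cores for PERMANOVA"
        )
    D = core_distance_matrix(incidence, distance=distance)
    return permanova(
        D, incidence["resource"].to_numpy(), n_perm=n_perm, seed=seed, distance=distance
    )


# -- NMDS -------------------------------------------------------------------


def nmds(
    D: np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    labels: Sequence[str] = (),
) -> NmdsResult:
    """Nonmetric multidimensional scaling with Kruskal stress-1.

    Runs SMACOF-based nonmetric MDS (scikit-learn) from ``n_starts`` random
    starts and keeps the lowest-stress solution; coordinates are centered.
    """
    from sklearn.manifold import MDS

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise DegenerateDesignError("NMDS needs at least 3 points")
    if not np.any(D[np.triu_indices(n, 1)] > 0):
        raise DegenerateDesignError("all distances are zero")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=500,
        random_state=int(seed) % (2**31 - 1),
        normalized_stress=True,
        eps=1e-9,
    )
    coords = model.fit_transform(D)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return NmdsResult(
        coordinates=coords, stress=float(model.stress_), labels=tuple(labels)
    )
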