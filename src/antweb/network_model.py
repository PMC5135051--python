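"""Data model and I/O for multilayer ant-plant interaction networks.

An observation campaign yields a long-format event table: one row per
observed interaction event between an ant species and a plant species,
classified by the plant-derived resource the ant was using (extrafloral
nectar, flower nectar/pollen, fruit pulp, honeydew from a tended
trophobiont) or recorded as a bare "visit" when no feeding was seen.
Each resource type defines one weighted bipartite layer (plants as rows,
ants as columns, cells = number of events); the multilayer network is the
element-wise sum of all layers on the union of species.

Interaction weight counts *events*, never workers: the worker tally of an
event is kept as recruitment metadata only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyLayerError, SchemaError, ValidationError

#: The closed vocabulary of resource types, one bipartite layer each.
RESOURCE_TYPES: tuple[str, ...] = ("EFN", "flower", "fruit", "trophobiont", "visit")

#: Label used for the pooled (all-resource) matrix.
MULTILAYER: str = "multilayer"

EVENT_COLUMNS: tuple[str, ...] = (
    "site_id",
    "plot_id",
    "season",
    "plant_sp",
    "ant_sp",
    "resource",
    "workers",
)


@dataclass(frozen=True)
class InteractionEvent:
    """One observed ant-plant interaction event (the atomic input record)."""

    site_id: str
    plot_id: str
    season: str
    plant_sp: str
    ant_sp: str
    resource: str
    workers: int

    def __post_init__(self) -> None:
        if self.resource not in RESOURCE_TYPES:
            raise SchemaError(
                f"unknown resource {self.resource!r}; must be one of {RESOURCE_TYPES}"
            )
        if self.workers < 0:
            raise ValidationError(
                f"workers must be >= 0, got {self.workers} "
                f"({self.plant_sp} x {self.ant_sp} at {self.site_id})"
            )


class LayerMatrix:
    """Weighted plant x ant matrix for one resource type (or the pooled network).

    Rows are plant species, columns ant species, both in lexicographic order;
    every row and column has at least one positive cell (species absent from
    the layer are dropped at construction). Cell ``a_ij`` is the number of
    interaction events between plant ``i`` and ant ``j``.
    """

    __slots__ = ("resource", "plants", "ants", "A", "provenance")

    def __init__(
        self,
        resource: str,
        plants: Sequence[str],
        ants: Sequence[str],
        A: np.ndarray,
        provenance: Iterable[str] = (),
    ) -> None:
        A = np.asarray(A)
        if A.ndim != 2 or A.shape != (len(plants), len(ants)):
            raise ValidationError(
                f"matrix shape {A.shape} inconsistent with {len(plants)} plants "
                f"x {len(ants)} ants"
            )
        if np.any(A < 0):
            raise ValidationError("interaction counts must be non-negative")
        if A.size == 0 or A.sum() <= 0:
            raise EmptyLayerError(f"layer {resource!r} has no interaction events")
        if np.any(A.sum(axis=1) == 0) or np.any(A.sum(axis=0) == 0):
            raise ValidationError(
                "all-zero rows/columns are not allowed; drop absent species first"
            )
        self.resource = resource
        self.plants = tuple(plants)
        self.ants = tuple(ants)
        self.A = A.astype(np.int64, copy=True)
        self.A.setflags(write=False)
        self.provenance = frozenset(provenance)

    # -- derived quantities -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    @property
    def F(self) -> int:
        """Total number of interaction events in the layer."""
        return int(self.A.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.A.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.A.sum(axis=0)

    @property
    def n_links(self) -> int:
        """Number of realized (positive) plant-ant links."""
        return int(np.count_nonzero(self.A))

    def with_values(self, A: np.ndarray, resource: Optional[str] = None) -> "LayerMatrix":
        """Same species labels, new cell values (dropping emptied species)."""
        A = np.asarray(A)
        keep_r = A.sum(axis=1) > 0
        keep_c = A.sum(axis=0) > 0
        return LayerMatrix(
            resource or self.resource,
            [p for p, k in zip(self.plants, keep_r) if k],
            [a for a, k in zip(self.ants, keep_c) if k],
            A[np.ix_(keep_r, keep_c)],
            self.provenance,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LayerMatrix):
            return NotImplemented
        return (
            self.plants == other.plants
            and self.ants == other.ants
            and np.array_equal(self.A, other.A)
        )

    def __repr__(self) -> str:
        return (
            f"LayerMatrix({self.resource!r}, {self.shape[0]} plants x "
            f"{self.shape[1]} ants, F={self.F})"
        )

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=list(self.plants), columns=list(self.ants))

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="plant_sp")

    @classmethod
    def from_tsv(cls, path: str | Path, resource: str = MULTILAYER) -> "LayerMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(resource, list(df.index), list(df.columns), df.to_numpy())


@dataclass(frozen=True)
class MultilayerNetwork:
    """All five resource layers plus their pooled sum.

    ``layers`` maps each resource type to its :class:`LayerMatrix` or to
    ``None`` when no events of that type were recorded. ``pooled`` sums all
    layers on the union of species, so its total equals the event count.
    """

    layers: Mapping[str, Optional[LayerMatrix]]
    pooled: LayerMatrix

    def __post_init__(self) -> None:
        layer_total = sum(m.F for m in self.layers.values() if m is not None)
        if layer_total != self.pooled.F:
            raise ValidationError(
                f"pooled total {self.pooled.F} != sum of layer totals {layer_total}"
            )


# -- construction -----------------------------------------------------------


def read_events(path: str | Path, format: str = "csv") -> list[InteractionEvent]:
    """Parse a long-format interaction-event table.

    The file must carry the seven canonical columns (``site_id, plot_id,
    season, plant_sp, ant_sp, resource, workers``); extra columns are
    ignored. Unknown resource labels and negative worker counts are
    rejected with the offending row named.
    """
    if format != "csv":
        raise SchemaError(f"unsupported format {format!r}")
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = set(EVENT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        events: list[InteractionEvent] = []
        for i, row in enumerate(reader, start=2):
            try:
                workers = int(row["workers"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}:{i}: non-integer workers {row['workers']!r}") from exc
            try:
                events.append(
                    InteractionEvent(
                        site_id=row["site_id"],
                        plot_id=row["plot_id"],
                        season=row["season"],
                        plant_sp=row["plant_sp"],
                        ant_sp=row["ant_sp"],
                        resource=row["resource"],
                        workers=workers,
                    )
                )
            except (SchemaError, ValidationError) as exc:
                raise type(exc)(f"{path}:{i}: {exc}") from exc
    return events


def events_to_dataframe(events: Iterable[InteractionEvent]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in events], columns=list(EVENT_COLUMNS))


def write_events(events: Iterable[InteractionEvent], path: str | Path) -> None:
    events_to_dataframe(events).to_csv(path, index=False)


def build_layer(
    events: Sequence[InteractionEvent],
    resource: str,
    sites: Optional[Iterable[str]] = None,
) -> LayerMatrix:
    """Tally events of one resource type into a weighted plant x ant matrix.

    ``resource`` may also be :data:`MULTILAYER` to pool every event. Events
    can optionally be restricted to a set of sites (per-site networks for
    the descriptor and core analyses). Raises :class:`EmptyLayerError` when
    nothing remains after filtering — never a 0x0 matrix.
    """
    if resource != MULTILAYER and resource not in RESOURCE_TYPES:
        raise SchemaError(f"unknown resource {resource!r}")
    site_set = None if sites is None else set(sites)
    selected = [
        e
        for e in events
        if (resource == MULTILAYER or e.resource == resource)
        and (site_set is None or e.site_id in site_set)
    ]
    if not selected:
        raise EmptyLayerError(
            f"no events for resource {resource!r}"
            + (f" at sites {sorted(site_set)}" if site_set is not None else "")
        )
    plants = sorted({e.plant_sp for e in selected})
    ants = sorted({e.ant_sp for e in selected})
    p_idx = {p: i for i, p in enumerate(plants)}
    a_idx = {a: j for j, a in enumerate(ants)}
    A = np.zeros((len(plants), len(ants)), dtype=np.int64)
    for e in selected:
        A[p_idx[e.plant_sp], a_idx[e.ant_sp]] += 1
    return LayerMatrix(resource, plants, ants, A, provenance={e.site_id for e in selected})


def build_multilayer(
    events: Sequence[InteractionEvent],
    sites: Optional[Iterable[str]] = None,
) -> MultilayerNetwork:
    """Build all five resource layers plus the pooled multilayer matrix."""
    if not events:
        raise EmptyLayerError("no events")
    layers: dict[str, Optional[LayerMatrix]] = {}
    for r in RESOURCE_TYPES:
        try:
            layers[r] = build_layer(events, r, sites=sites)
        except EmptyLayerError:
            layers[r] = None
    pooled = build_layer(events, MULTILAYER, sites=sites)
    return MultilayerNetwork(layers=layers, pooled=pooled)


# -- Pajek export -----------------------------------------------------------


def export_pajek(matrix: LayerMatrix, path: str | Path) -> None:
    """Write a two-mode Pajek ``.net`` file (plants first, then ants).

    Uses the two-mode vertex header ``*Vertices N N1`` so Pajek treats the
    first block as one partition; edges carry event counts as weights.
    """
    n_p, n_a = matrix.shape
    path = Path(path)
    lines = [f"*Vertices {n_p + n_a} {n_p}"]
    for i, p in enumerate(matrix.plants, start=1):
        lines.append(f'{i} "{p}"')
    for j, a in enumerate(matrix.ants, start=1):
        lines.append(f'{n_p + j} "{a}"')
    lines.append("*Edges")
    for i in range(n_p):
        for j in range(n_a):
            w = matrix.A[i, j]
            if w > 0:
                lines.append(f"{i + 1} {n_p + j + 1} {w}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"could not write Pajek file {path}: {exc}") from exc


def read_pajek(path: str | Path, resource: str = MULTILAYER) -> LayerMatrix:
    """Read back a two-mode Pajek file written by :func:`export_pajek`."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    if header[0].lower() != "*vertices" or len(header) < 3:
        raise SchemaError(f"{path}: not a two-mode Pajek file")
    n_total, n_p = int(header[1]), int(header[2])
    labels: dict[int, str] = {}
    k = 1
    while k < len(lines) and not lines[k].startswith("*"):
        vid, label = lines[k].split(maxsplit=1)
        labels[int(vid)] = label.strip().strip('"')
        k += 1
    if k >= len(lines) or lines[k].lower() not in ("*edges", "*arcs"):
        raise SchemaError(f"{path}: missing *Edges section")
    plants = [labels[i] for i in range(1, n_p + 1)]
    ants = [labels[i] for i in range(n_p + 1, n_total + 1)]
    A = np.zeros((len(plants), len(ants)), dtype=np.int64)
    for ln in lines[k + 1 :]:
        u, v, w = ln.split()[:3]
        A[int(u) - 1, int(v) - 1 - n_p] = int(float(w))
    return LayerMatrix(resource, plants, ants, A)
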