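"""Event design and binary hypothesis (model) matrices.

The experimental design crosses a small set of central persons with a set of
contexts, where contexts are partitioned into context *types* (e.g., two
distinct cafes and two distinct grocery stores form the "cafe" and "store"
types). Each (person, context) pair is one event. Representational
hypotheses about which event pairs should evoke correlated multivoxel
patterns are expressed as binary event-by-event model matrices:

- ``person``:   1 where the two events feature the same person
- ``context``:  1 where the two events occur in the same context
- ``schema``:   1 where the contexts are of the same type
- ``episodic``: 1 only where the two events are the same event

The default design is 2 persons x 4 contexts (2 types x 2 exemplars) = 8
events, but the constructors are generic over any full person-x-context
crossing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODEL_KINDS",
    "Event",
    "EventDesign",
    "ModelMatrix",
    "build_default_design",
    "build_design",
    "build_model_matrix",
    "build_all_model_matrices",
    "lower_half_vector",
]

MODEL_KINDS = ("person", "context", "schema", "episodic")


@dataclass(frozen=True)
class Event:
    """A single person-in-context event."""

    event_id: int
    person: str
    context: str
    context_type: str

    @property
    def label(self) -> str:
        return f"{self.person}@{self.context}"


@dataclass(frozen=True)
class EventDesign:
    """An ordered collection of events forming a person x context crossing."""

    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        if ids != list(range(len(ids))):
            raise ValueError("event_ids must be consecutive integers from 0")
        type_of: dict[str, str] = {}
        for e in self.events:
            if type_of.setdefault(e.context, e.context_type) != e.context_type:
                raise ValueError(
                    f"context {e.context!r} maps to more than one context type"
                )
        pairs = {(e.person, e.context) for e in self.events}
        if len(pairs) != len(self.events):
            raise ValueError("duplicate (person, context) event")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def persons(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(e.person for e in self.events))

    @property
    def contexts(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(e.context for e in self.events))

    @property
    def context_types(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(e.context_type for e in self.events))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": [e.event_id for e in self.events],
                "person": [e.person for e in self.events],
                "context": [e.context for e in self.events],
                "context_type": [e.context_type for e in self.events],
            }
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_frame().to_dict(orient="records"), indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EventDesign":
        records = json.loads(Path(path).read_text())
        return cls(
            tuple(
                Event(r["event_id"], r["person"], r["context"], r["context_type"])
                for r in sorted(records, key=lambda r: r["event_id"])
            )
        )


def build_design(
    persons: Sequence[str], contexts_by_type: Mapping[str, Sequence[str]]
) -> EventDesign:
    """Fully cross `persons` with every context, preserving input order."""
    events = []
    eid = 0
    for person in persons:
        for ctype, contexts in contexts_by_type.items():
            for context in contexts:
                events.append(Event(eid, person, context, ctype))
                eid += 1
    return EventDesign(tuple(events))


def build_default_design() -> EventDesign:
    """The 8-event default: {Tommy, Lisa} x {Cafe1, Cafe2, Store1, Store2}."""
    return build_design(
        persons=("Tommy", "Lisa"),
        contexts_by_type={"cafe": ("Cafe1", "Cafe2"), "store": ("Store1", "Store2")},
    )


@dataclass(frozen=True)
class ModelMatrix:
    """Binary event-by-event hypothesis matrix.

    Cells hypothesized to show high pattern correlation are 1, all others 0.
    The diagonal (an event compared with itself across runs) is 1 for every
    kind when ``include_diagonal_ones`` is set, since cross-run same-event
    cells carry meaningful data.
    """

    kind: str
    values: np.ndarray
    include_diagonal_ones: bool = True
    schema_includes_same_context: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("model matrix must be square")
        if not np.array_equal(v, v.T):
            raise ValueError("model matrix must be symmetric")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("model matrix entries must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def lower_half(self, include_diagonal: bool = True) -> np.ndarray:
        return lower_half_vector(self.values, include_diagonal=include_diagonal)

    def to_frame(self, design: EventDesign | None = None) -> pd.DataFrame:
        labels = (
            list(design.labels) if design is not None else list(range(self.n_events))
        )
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_csv(self, path: str | Path, design: EventDesign | None = None) -> None:
        self.to_frame(design).to_csv(path)


def build_model_matrix(
    design: EventDesign,
    kind: str,
    *,
    include_diagonal_ones: bool = True,
    schema_includes_same_context: bool = True,
) -> ModelMatrix:
    """Construct one of the four binary hypothesis matrices for a design.

    Parameters
    ----------
    kind
        One of ``person``, ``context``, ``schema``, ``episodic``.
    include_diagonal_ones
        Set the diagonal to 1 regardless of kind (default). An event trivially
        shares its own person/context/type with itself.
    schema_includes_same_context
        If True (default), the schema matrix is the full context-type block,
        including same-context cells. If False, same-context cells are zeroed
        so the matrix isolates *similar-but-not-identical* contexts.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    E = design.n_events
    ev = design.events
    m = np.zeros((E, E), dtype=np.int8)
    for i in range(E):
        for j in range(E):
            if kind == "person":
                m[i, j] = ev[i].person == ev[j].person
            elif kind == "context":
                m[i, j] = ev[i].context == ev[j].context
            elif kind == "schema":
                same_type = ev[i].context_type == ev[j].context_type
                if schema_includes_same_context:
                    m[i, j] = same_type
                else:
                    m[i, j] = same_type and ev[i].context != ev[j].context
            else:  # episodic
                m[i, j] = i == j
    if include_diagonal_ones:
        np.fill_diagonal(m, 1)
    return ModelMatrix(
        kind=kind,
        values=m,
        include_diagonal_ones=include_diagonal_ones,
        schema_includes_same_context=schema_includes_same_context,
    )


def build_all_model_matrices(
    design: EventDesign, **kwargs
) -> dict[str, ModelMatrix]:
    return {kind: build_model_matrix(design, kind, **kwargs) for kind in MODEL_KINDS}


def lower_half_vector(matrix: np.ndarray, include_diagonal: bool = True) -> np.ndarray:
    """Vectorize the lower triangle of a square matrix.

    Ordering is row-major over cells with i >= j (or i > j without the
    diagonal), i.e. (0,0), (1,0), (1,1), (2,0), ... — deterministic so that
    model and similarity matrices vectorize identically.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    k = 0 if include_diagonal else -1
    rows, cols = np.tril_indices(m.shape[0], k=k)
    return m[rows, cols]
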