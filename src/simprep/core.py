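"""Data model and I/O for labelled abstract simplicial complexes.

Vertices are nested frozensets of positive integers: an original model
component is the singleton ``frozenset({i})`` where ``i`` is the integer
assigned to the component by the ordering bijection of a
:class:`ComponentUniverse`; a vertex produced by merging carries the
identifiers it absorbed (e.g. ``{{1},{2}}`` or ``{1,2}``).  Simplices are
frozensets of vertices, and a complex stores its *full* face-closed simplex
family, not just the maximal faces.

The void complex (no simplices, no vertices) is representable and has
dimension ``NEG_INFINITY``; the empty simplex is not representable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import IO, Iterable, Mapping

__all__ = [
    "NEG_INFINITY",
    "DomainError",
    "UnknownVertexError",
    "PreconditionError",
    "Vertex",
    "Simplex",
    "singleton",
    "flatten",
    "vertex_key",
    "simplex_key",
    "ComponentUniverse",
    "SimplicialRepresentation",
    "ValidationReport",
    "close_under_faces",
    "validate",
    "dimension",
    "skeleton",
    "full_subcomplex",
    "clique_completion",
    "adjacent_vertices",
    "load_json",
    "loads_json",
    "dump_json",
    "dumps_json",
]

#: Dimension assigned to the void complex.
NEG_INFINITY = float("-inf")

Vertex = frozenset
Simplex = frozenset


class DomainError(ValueError):
    """A request that violates the mathematical preconditions of an operation."""


class UnknownVertexError(DomainError):
    """A vertex outside ``Vert(K)`` was supplied."""


class PreconditionError(DomainError):
    """A partial operation was applied outside its domain of definition.

    ``clause`` names the violated condition.
    """

    def __init__(self, clause: str, message: str):
        super().__init__(f"{clause}: {message}")
        self.clause = clause


def singleton(i: int) -> Vertex:
    """The vertex identifier of the original model component ``i``."""
    if not isinstance(i, int) or i < 1:
        raise DomainError(f"component identifiers are positive integers, got {i!r}")
    return frozenset({i})


def flatten(v) -> frozenset:
    """Union of all component integers contained in a (nested) identifier."""
    if isinstance(v, int):
        return frozenset({v})
    out: set = set()
    for x in v:
        out |= flatten(x)
    return frozenset(out)


def _nested_key(x):
    if isinstance(x, int):
        return (0, (x,))
    return (1, tuple(sorted(_nested_key(y) for y in x)))


def vertex_key(v: Vertex):
    """Deterministic total order on vertex identifiers.

    Primary key is the sorted flattened component set, so merged vertices sort
    where their contents suggest; the fully nested structure breaks ties.
    """
    return (tuple(sorted(flatten(v))), _nested_key(v))


def simplex_key(s: Simplex):
    """Canonical sort key for simplices: cardinality, then member order."""
    return (len(s), tuple(sorted(vertex_key(v) for v in s)))


class ComponentUniverse:
    """The set of model components with its ordering bijection.

    Maps each positive integer to a distinct component name; invertible.
    """

    def __init__(self, components: Mapping[int, str]):
        comps = dict(components)
        for k, name in comps.items():
            if not isinstance(k, int) or k < 1:
                raise DomainError(f"component keys must be positive integers, got {k!r}")
            if not isinstance(name, str) or not name:
                raise DomainError(f"component names must be nonempty strings, got {name!r}")
        if len(set(comps.values())) != len(comps):
            raise DomainError("component names must be distinct")
        self._by_int = dict(sorted(comps.items()))
        self._by_name = {v: k for k, v in self._by_int.items()}

    def name(self, i: int) -> str:
        return self._by_int[i]

    def index(self, name: str) -> int:
        return self._by_name[name]

    def __contains__(self, i: int) -> bool:
        return i in self._by_int

    def __iter__(self):
        return iter(self._by_int.items())

    def __len__(self):
        return len(self._by_int)

    def __eq__(self, other):
        return isinstance(other, ComponentUniverse) and self._by_int == other._by_int

    def __repr__(self):
        return f"ComponentUniverse({self._by_int!r})"

    def as_dict(self) -> dict:
        return dict(self._by_int)


class SimplicialRepresentation:
    """A labelled abstract simplicial complex.

    ``simplices`` is the full face-closed family; ``vertices`` is derived from
    the 0-simplices.  The label of a vertex is the flattened set of component
    integers its identifier carries.  Construction does not enforce face
    closure (see :func:`validate`); use :func:`close_under_faces` to build
    guaranteed-valid complexes.
    """

    __slots__ = ("simplices", "vertices", "components")

    def __init__(
        self,
        simplices: Iterable[Simplex],
        components: ComponentUniverse | None = None,
    ):
        self.simplices = frozenset(frozenset(s) for s in simplices)
        for s in self.simplices:
            if not s:
                raise DomainError("the empty simplex is not representable")
        self.vertices = frozenset(v for s in self.simplices for v in s)
        self.components = components

    # -- basic protocol -------------------------------------------------

    def __contains__(self, s) -> bool:
        return frozenset(s) in self.simplices

    def __len__(self) -> int:
        return len(self.simplices)

    def __iter__(self):
        return iter(self.simplices)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimplicialRepresentation)
            and self.simplices == other.simplices
        )

    def __hash__(self) -> int:
        return hash(self.simplices)

    def __repr__(self) -> str:
        return f"<SimplicialRepresentation |V|={len(self.vertices)} |K|={len(self.simplices)}>"

    # -- labels ---------------------------------------------------------

    @property
    def labels(self) -> dict:
        """Vertex identifier -> flattened set of component integers."""
        return {v: flatten(v) for v in self.vertices}

    def label(self, v: Vertex) -> frozenset:
        if v not in self.vertices:
            raise UnknownVertexError(f"unknown vertex {set(v)!r}")
        return flatten(v)

    @property
    def is_void(self) -> bool:
        return not self.simplices

    def sorted_simplices(self) -> list:
        return sorted(self.simplices, key=simplex_key)

    def sorted_vertices(self) -> list:
        return sorted(self.vertices, key=vertex_key)

    def replace(self, simplices) -> "SimplicialRepresentation":
        return SimplicialRepresentation(simplices, components=self.components)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`; ``ok`` iff ``violations`` is empty."""

    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _freeze(x):
    if isinstance(x, int):
        return x
    return frozenset(_freeze(y) for y in x)


def _nonempty_subsets(s: Simplex):
    items = list(s)
    for r in range(1, len(items) + 1):
        for c in combinations(items, r):
            yield frozenset(c)


def close_under_faces(
    maximal: Iterable[Iterable],
    components: ComponentUniverse | None = None,
) -> SimplicialRepresentation:
    """Build the complex containing the listed simplices and all their faces.

    Members of ``maximal`` may list vertices either as bare positive integers
    (shorthand for singleton identifiers) or as explicit identifier sets.
    """
    simplices: set = set()
    for raw in maximal:
        s = frozenset(
            singleton(x) if isinstance(x, int) else _freeze(x) for x in raw
        )
        if not s:
            raise DomainError("empty member set: the empty simplex is excluded")
        simplices.update(_nonempty_subsets(s))
    return SimplicialRepresentation(simplices, components=components)


def validate(K: SimplicialRepresentation) -> ValidationReport:
    """Report every face-closure violation and every unlabelled vertex."""
    report = ValidationReport()
    for s in K.simplices:
        if len(s) > 1:
            for v in s:
                face = s - {v}
                if face not in K.simplices:
                    report.violations.append(("face-closure", (s, face)))
    for v in K.vertices:
        if frozenset({v}) not in K.simplices:
            report.violations.append(("missing-0-simplex", v))
        if not flatten(v):
            report.violations.append(("unlabelled-vertex", v))
    return report


def dimension(K: SimplicialRepresentation):
    """Max simplex cardinality minus one; ``NEG_INFINITY`` for the void complex."""
    if K.is_void:
        return NEG_INFINITY
    return max(len(s) for s in K.simplices) - 1


def skeleton(K: SimplicialRepresentation, k: int) -> SimplicialRepresentation:
    """The subcomplex of simplices with dimension at most ``k``."""
    if k < 0:
        raise DomainError(f"skeleton order must be >= 0, got {k}")
    return K.replace(s for s in K.simplices if len(s) <= k + 1)


def full_subcomplex(K: SimplicialRepresentation, W: Iterable[Vertex]) -> SimplicialRepresentation:
    """All simplices of ``K`` whose vertices all lie in ``W``."""
    W = frozenset(W)
    unknown = W - K.vertices
    if unknown:
        raise UnknownVertexError(f"unknown vertex: {sorted(map(set, unknown), key=str)!r}")
    return K.replace(s for s in K.simplices if s <= W)


def clique_completion(K1: SimplicialRepresentation) -> SimplicialRepresentation:
    """The flag complex of a 1-dimensional complex.

    Every vertex set whose pairs are all edges of ``K1`` becomes a simplex.
    Built incrementally by dimension: a candidate k-simplex is admitted when
    all its (k-1)-faces are already present, which for a graph input yields
    exactly the cliques.
    """
    if dimension(K1) > 1:
        raise DomainError("clique completion expects a 1-skeleton (dimension <= 1)")
    simplices = set(K1.simplices)
    current = {s for s in simplices if len(s) == 2}
    k = 3
    while current:
        nxt = set()
        for s in current:
            for v in K1.vertices - s:
                cand = s | {v}
                if len(cand) == k and all(
                    cand - {w} in simplices for w in cand
                ):
                    nxt.add(cand)
        simplices |= nxt
        current = nxt
        k += 1
    return K1.replace(simplices)


def adjacent_vertices(K: SimplicialRepresentation, u: Vertex) -> frozenset:
    """All vertices sharing a simplex with ``u``, excluding ``u`` itself."""
    if u not in K.vertices:
        raise UnknownVertexError(f"unknown vertex {set(u)!r}")
    out: set = set()
    for s in K.simplices:
        if u in s:
            out |= s
    out.discard(u)
    return frozenset(out)


# ---------------------------------------------------------------------------
# JSON dialect
#
#   {"components": {"<int>": "<name>", ...},     -- optional
#    "vertices":   [<vertex>, ...],              -- optional, inferred
#    "simplices":  [[<vertex>, ...], ...],
#    "maximal_only": bool,                       -- close under faces on read
#    "clique_complete": bool}                    -- flag-complete on read
#
# A <vertex> is a bare positive integer (singleton identifier) or a nested
# list of integers/lists mirroring a merged identifier.
# ---------------------------------------------------------------------------


def _encode_vertex(v: Vertex):
    if len(v) == 1:
        (x,) = v
        if isinstance(x, int):
            return x
    return sorted((_encode_item(x) for x in v), key=_json_key)


def _encode_item(x):
    if isinstance(x, int):
        return x
    return sorted((_encode_item(y) for y in x), key=_json_key)


def _json_key(x):
    if isinstance(x, int):
        return (0, (x,))
    return (1, tuple(_json_key(y) for y in x))


def _decode_vertex(obj) -> Vertex:
    if isinstance(obj, int):
        return singleton(obj)
    return frozenset(_decode_item(x) for x in obj)


def _decode_item(x):
    if isinstance(x, int):
        return x
    return frozenset(_decode_item(y) for y in x)


def dumps_json(K: SimplicialRepresentation) -> str:
    """Serialize canonically: identical complexes produce identical bytes."""
    doc: dict = {}
    if K.components is not None:
        doc["components"] = {str(k): v for k, v in K.components}
    doc["vertices"] = [_encode_vertex(v) for v in K.sorted_vertices()]
    doc["simplices"] = [
        [_encode_vertex(v) for v in sorted(s, key=vertex_key)]
        for s in K.sorted_simplices()
    ]
    doc["maximal_only"] = False
    doc["clique_complete"] = False
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def dump_json(K: SimplicialRepresentation, fp: IO[str]) -> None:
    fp.write(dumps_json(K))


def loads_json(text: str) -> SimplicialRepresentation:
    doc = json.loads(text)
    components = None
    if doc.get("components"):
        components = ComponentUniverse(
            {int(k): v for k, v in doc["components"].items()}
        )
    raw = [
        frozenset(_decode_vertex(v) for v in s) for s in doc.get("simplices", [])
    ]
    for v in doc.get("vertices", []):
        raw.append(frozenset({_decode_vertex(v)}))
    if doc.get("maximal_only") or doc.get("clique_complete"):
        K = close_under_faces(raw, components=components)
    else:
        K = SimplicialRepresentation(raw, components=components)
    if doc.get("clique_complete"):
        K = clique_completion(K)
    return K


def load_json(fp: IO[str]) -> SimplicialRepresentation:
    return loads_json(fp.read())
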