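"""Fissure feature-line extraction by minimum-cost heuristic search.

The pit-and-fissure network of an occlusal surface is traced as a closed
sequence of mesh vertices.  Each candidate step from the current vertex to an
adjacent one is scored by a weighted sum of four terms

    cost = la * f_dir1 + lb * f_dir2 + lc * f_D + ld * f_C

where f_dir1 is the turning angle against the previous step (smoothness),
f_dir2 the angle between the step and the direction toward the leg's goal
(pulls the line closed), f_D the distance of the candidate from the leg's
start, and f_C the curvature change across the step (keeps the line in the
high-curvature groove).  The minimum-accumulated-cost vertex path between two
seeds is found by Dijkstra search over (vertex, predecessor) states, since
the turning term makes the step cost depend on the incoming direction.

Term scales: the angles are in radians in [0, pi]; f_D is normalized by the
mesh bounding-box diagonal; f_C by the 95th percentile of |curvature change|
over all mesh edges, making the four terms commensurate so the default
weights are meaningful.
"""

from __future__ import annotations

import heapq
import json
import os
from dataclasses import dataclass

import numpy as np
import trimesh

from .mesh_core import bounding_box

__all__ = [
    "HeuristicWeights",
    "SearchState",
    "FeatureCurve",
    "NoPathError",
    "TermScales",
    "term_scales",
    "step_cost",
    "min_cost_path",
    "extract_fissure_loop",
]


class NoPathError(RuntimeError):
    """Start and goal are not connected on the mesh edge graph."""


@dataclass(frozen=True)
class HeuristicWeights:
    """Non-negative weights of the four step-cost terms."""

    la: float = 0.75
    lb: float = 0.85
    lc: float = 0.85
    ld: float = 0.55

    def __post_init__(self) -> None:
        if min(self.la, self.lb, self.lc, self.ld) < 0:
            raise ValueError("heuristic weights must be non-negative")


@dataclass
class SearchState:
    """Position of a search front: current vertex, where it came from, cost so far."""

    current: int
    previous: int | None
    start: int
    goal: int
    cost: float = 0.0


@dataclass
class FeatureCurve:
    """An ordered vertex path on a mesh; closed curves repeat the first index last."""

    vertex_indices: list[int]
    closed: bool
    total_cost: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "vertex_indices": [int(i) for i in self.vertex_indices],
                "closed": bool(self.closed),
                "total_cost": float(self.total_cost),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureCurve":
        d = json.loads(text)
        return cls(list(d["vertex_indices"]), bool(d["closed"]), float(d["total_cost"]))

    def save(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write(self.to_json())


@dataclass(frozen=True)
class TermScales:
    """Normalizers making the four cost terms dimensionless and commensurate."""

    bbox_diagonal: float
    curvature_p95: float


def term_scales(mesh: trimesh.Trimesh, curvature: np.ndarray) -> TermScales:
    lo, hi = bounding_box(mesh)
    diag = float(np.linalg.norm(hi - lo))
    edges = mesh.edges_unique
    dk = np.abs(curvature[edges[:, 0]] - curvature[edges[:, 1]])
    p95 = float(np.percentile(dk, 95)) if len(dk) else 0.0
    return TermScales(bbox_diagonal=max(diag, 1e-300), curvature_p95=p95)


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    """Included angle of two vectors in radians; 0 if either is degenerate."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-300 or nv < 1e-300:
        return 0.0
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _step_cost_raw(
    vertices: np.ndarray,
    curvature: np.ndarray,
    weights: HeuristicWeights,
    scales: TermScales,
    current: int,
    previous: int,
    candidate: int,
    start: int,
    goal: int,
) -> float:
    """Cost kernel on raw arrays; ``previous`` < 0 encodes the first step."""
    step = vertices[candidate] - vertices[current]

    if previous < 0:
        f_dir1 = 0.0
    else:
        f_dir1 = _angle(vertices[current] - vertices[previous], step)

    if candidate == goal:
        f_dir2 = 0.0
    else:
        f_dir2 = _angle(step, vertices[goal] - vertices[candidate])

    f_d = float(np.linalg.norm(vertices[candidate] - vertices[start]))
    f_d /= scales.bbox_diagonal

    dk = abs(float(curvature[candidate]) - float(curvature[current]))
    f_c = dk / scales.curvature_p95 if scales.curvature_p95 > 0 else 0.0

    cost = weights.la * f_dir1 + weights.lb * f_dir2 + weights.lc * f_d + weights.ld * f_c
    if not np.isfinite(cost) or cost < 0:
        raise AssertionError(f"step cost not finite/non-negative: {cost}")
    return float(cost)


def step_cost(
    state: SearchState,
    candidate: int,
    mesh: trimesh.Trimesh,
    curvature: np.ndarray,
    weights: HeuristicWeights = HeuristicWeights(),
    scales: TermScales | None = None,
) -> float:
    """Cost of extending the search from ``state.current`` to ``candidate``.

    ``candidate`` must be edge-adjacent to the current vertex.  Returns a
    non-negative, finite value.
    """
    if candidate not in mesh.vertex_neighbors[state.current]:
        raise ValueError(
            f"candidate vertex {candidate} is not adjacent to {state.current}"
        )
    if scales is None:
        scales = term_scales(mesh, curvature)
    return _step_cost_raw(
        np.asarray(mesh.vertices, dtype=float),
        np.asarray(curvature, dtype=float),
        weights,
        scales,
        state.current,
        -1 if state.previous is None else state.previous,
        candidate,
        state.start,
        state.goal,
    )


def min_cost_path(
    mesh: trimesh.Trimesh,
    start: int,
    goal: int,
    weights: HeuristicWeights = HeuristicWeights(),
    curvature: np.ndarray | None = None,
) -> FeatureCurve:
    """Edge path from ``start`` to ``goal`` minimizing the accumulated step cost.

    Dijkstra over (vertex, predecessor) states.  Ties are broken toward the
    lowest vertex index so identical inputs always return the same path.
    """
    nv = len(mesh.vertices)
    if not (0 <= start < nv and 0 <= goal < nv):
        raise ValueError("start/goal vertex index out of range")
    if start == goal:
        raise ValueError("start and goal must differ")
    if curvature is None:
        from .mesh_core import vertex_curvature

        curvature = vertex_curvature(mesh)
    scales = term_scales(mesh, curvature)
    vertices = np.asarray(mesh.vertices, dtype=float)
    curvature = np.asarray(curvature, dtype=float)
    neighbors = [sorted(n) for n in mesh.vertex_neighbors]

    # heap entries: (cost, current, previous); previous = -1 encodes "none"
    best: dict[tuple[int, int], float] = {}
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    heap: list[tuple[float, int, int]] = [(0.0, start, -1)]
    best[(start, -1)] = 0.0
    parent[(start, -1)] = None

    goal_state: tuple[int, int] | None = None
    while heap:
        cost, cur, prev = heapq.heappop(heap)
        key = (cur, prev)
        if cost > best.get(key, np.inf):
            continue
        if cur == goal:
            goal_state = key
            break
        for cand in neighbors[cur]:
            c = cost + _step_cost_raw(
                vertices, curvature, weights, scales, cur, prev, cand, start, goal
            )
            nkey = (cand, cur)
            if c < best.get(nkey, np.inf):
                best[nkey] = c
                parent[nkey] = key
                heapq.heappush(heap, (c, cand, cur))

    if goal_state is None:
        raise NoPathError(f"no path between vertices {start} and {goal}")

    path: list[int] = []
    node: tuple[int, int] | None = goal_state
    while node is not None:
        path.append(node[0])
        node = parent[node]
    path.reverse()
    return FeatureCurve(path, closed=False, total_cost=best[goal_state])


def extract_fissure_loop(
    mesh: trimesh.Trimesh,
    seed_vertices: list[int],
    weights: HeuristicWeights = HeuristicWeights(),
    curvature: np.ndarray | None = None,
) -> FeatureCurve:
    """Closed fissure curve through the given seeds (>= 3, distinct).

    Concatenates the minimum-cost path between consecutive seeds and joins
    the last seed back to the first; duplicated junction vertices are removed
    and the first vertex is repeated at the end to mark closure.
    """
    seeds = [int(s) for s in seed_vertices]
    if len(seeds) < 3:
        raise ValueError("need at least 3 seed vertices for a closed loop")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seed vertices must be distinct")
    if curvature is None:
        from .mesh_core import vertex_curvature

        curvature = vertex_curvature(mesh)

    loop: list[int] = []
    total = 0.0
    for a, b in zip(seeds, seeds[1:] + seeds[:1]):
        try:
            leg = min_cost_path(mesh, a, b, weights, curvature)
        except NoPathError as exc:
            raise NoPathError(f"leg {a} -> {b} of the fissure loop: {exc}") from exc
        total += leg.total_cost
        loop.extend(leg.vertex_indices[:-1])  # drop the junction duplicate
    loop.append(seeds[0])
    return FeatureCurve(loop, closed=True, total_cost=total)
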