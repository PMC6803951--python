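"""Ring (face) census of tube-embedded molecular graphs.

The bond graph of a nanotube is embedded in the cylinder surface, so its
rings are exactly the faces of that embedding.  The census therefore uses
face tracing with the rotation system induced by the geometry: at every
atom the incident bonds are ordered by angle in the local tangent plane
(counterclockwise about the outward radial normal), and faces are traversed
with the standard next-edge rule.  This is exact — it finds every pentagon,
hexagon and heptagon, including the 5-7-7-5 Stone–Wales pattern whose
heptagons are *not* shortest cycles through their edges (which is why a
naive shortest-path ring search misses them).

Periodic cells are handled natively: bonds crossing the axial boundary keep
their image offsets, and a face that wraps the boundary is still traced as
one face.  For finite tubes the two open rims appear as large boundary
faces; ``max_size`` filters them out.

Works on structures in the canonical frame (tube axis = z).
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .structure import AtomicStructure


def ring_census(structure: AtomicStructure, max_size: int = 10) -> Counter:
    """Counter mapping ring size -> number of rings (faces) of that size."""
    faces = trace_faces(structure)
    return Counter(len(f) for f in faces if len(f) <= max_size)


def trace_faces(structure: AtomicStructure) -> list[list[int]]:
    """All faces of the surface embedding, as lists of atom indices.

    Face length equals the number of edge steps; a face wrapping a short
    periodic cell may visit an atom more than once and is still one face.
    """
    pos = structure.positions
    period = structure.period
    # incident directed edges per atom: (neighbour, relative image)
    incident: list[list[tuple[int, int]]] = [[] for _ in range(structure.n_atoms)]
    for i, j, im in zip(structure.bond_i, structure.bond_j, structure.bond_image):
        incident[int(i)].append((int(j), int(im)))
        incident[int(j)].append((int(i), -int(im)))

    order: list[dict[tuple[int, int], int]] = []
    sorted_incident: list[list[tuple[int, int]]] = []
    for v, nbrs in enumerate(incident):
        p = pos[v]
        normal = np.array([p[0], p[1], 0.0])
        nn = np.linalg.norm(normal)
        if nn < 1e-9:
            raise ValueError("atom on the tube axis; structure is not a tube")
        normal /= nn
        t1 = np.array([0.0, 0.0, 1.0])
        t1 = t1 - normal * (t1 @ normal)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(normal, t1)
        angles = []
        for (u, im) in nbrs:
            vec = pos[u].copy()
            if period is not None:
                vec = vec + np.array([0.0, 0.0, im * period])
            vec = vec - p
            angles.append(np.arctan2(vec @ t2, vec @ t1))
        idx = np.argsort(angles, kind="stable")
        snbrs = [nbrs[k] for k in idx]
        sorted_incident.append(snbrs)
        order.append({key: k for k, key in enumerate(snbrs)})

    used: set[tuple[int, int, int]] = set()
    faces: list[list[int]] = []
    for v0 in range(structure.n_atoms):
        for (u0, im0) in sorted_incident[v0]:
            start = (v0, u0, im0)
            if start in used:
                continue
            face: list[int] = []
            edge = start
            while True:
                used.add(edge)
                a, b, im = edge
                face.append(a)
                # at b, the reverse edge is (a, -im); take the next incident
                # edge clockwise (previous in CCW order) -> consistent faces
                k = order[b][(a, -im)]
                nxt = sorted_incident[b][(k - 1) % len(sorted_incident[b])]
                edge = (b, nxt[0], nxt[1])
                if edge == start:
                    break
                if len(face) > 4 * structure.n_atoms:  # pragma: no cover
                    raise RuntimeError("face tracing did not close")
            faces.append(face)
    return faces
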