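"""Conformal tetrahedral meshing of structured cell complexes.

The shell models are assembled as complexes of hexahedral and wedge cells
whose shared faces carry identical global node ids (conformity by
construction).  Each cell is tetrahedralised by triangulating every face with
the diagonal through its smallest global node id -- a rule that two cells
sharing a face apply identically -- and fanning tetrahedra from the cell's
smallest node.  Cells too distorted for the fan (non-star-shaped from that
node) fall back to a centroid split, which adds one node but is
unconditionally valid.

Quadratic (10-node) tetrahedra are produced by inserting midside nodes on
every unique edge; midsides whose end nodes lie on the same cylindrical or
spherical model surface are projected onto that surface, which restores
second-order geometric accuracy of the pressure-loaded boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeshQualityError

__all__ = ["CellComplex", "FEMesh", "tetrahedralize"]

_VOL_EPS = 1e-10


@dataclass
class CellComplex:
    """Nodes plus polyhedral cells (faces as vertex-id polygons)."""

    nodes: list = field(default_factory=list)  # list of 3-vectors
    _ids: dict = field(default_factory=dict)  # key -> node id
    cells: list = field(default_factory=list)  # (region, (faces...))
    node_tags: dict = field(default_factory=dict)  # tag -> set of node ids
    surfaces: dict = field(default_factory=dict)  # tag -> ("cyl", r) | ("sph", c, r)
    meta: dict = field(default_factory=dict)

    def node(self, key, pos=None, tags=()) -> int:
        nid = self._ids.get(key)
        if nid is None:
            if pos is None:
                raise KeyError(f"unknown node key {key!r}")
            nid = len(self.nodes)
            self._ids[key] = nid
            self.nodes.append(np.asarray(pos, float))
        for t in tags:
            self.node_tags.setdefault(t, set()).add(nid)
        return nid

    def has_node(self, key) -> bool:
        return key in self._ids

    def add_cell(self, region: str, faces):
        self.cells.append((region, tuple(tuple(f) for f in faces)))

    def node_array(self) -> np.ndarray:
        return np.asarray(self.nodes, float)

    # ---- watertightness of the complex boundary --------------------------
    def boundary_triangles(self) -> np.ndarray:
        """Triangulated boundary (faces used by exactly one cell)."""
        count: dict = {}
        rep: dict = {}
        for _, faces in self.cells:
            for f in faces:
                key = tuple(sorted(f))
                count[key] = count.get(key, 0) + 1
                rep[key] = f
        tris = []
        for key, c in count.items():
            if c == 1:
                tris.extend(_triangulate_face(rep[key]))
        return np.asarray(tris, int)

    def is_watertight(self) -> bool:
        tris = self.boundary_triangles()
        edges: dict = {}
        for t in tris:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                key = (min(a, b), max(a, b))
                edges[key] = edges.get(key, 0) + 1
        return all(c == 2 for c in edges.values())


def _triangulate_face(face):
    """Split a polygon face into triangles via its smallest node id."""
    if len(face) == 3:
        return [tuple(face)]
    if len(face) == 4:
        a, b, c, d = face
        # diagonal through the smallest id
        if min(a, c) <= min(b, d):
            return [(a, b, c), (a, c, d)]
        return [(b, c, d), (b, d, a)]
    # generic fan from the smallest id (convex faces only)
    k = face.index(min(face))
    f = face[k:] + face[:k]
    return [(f[0], f[i], f[i + 1]) for i in range(1, len(f) - 1)]


def _tet_vol(nodes, a, b, c, d):
    return np.linalg.det(
        np.array([nodes[b] - nodes[a], nodes[c] - nodes[a], nodes[d] - nodes[a]])
    ) / 6.0


@dataclass
class FEMesh:
    """Tetrahedral mesh with region labels and tagged node sets."""

    nodes: np.ndarray  # (N, 3)
    tets: np.ndarray  # (E, 4) corner connectivity
    region: np.ndarray  # (E,) codes into region_names
    region_names: list
    order: int = 1
    conn10: np.ndarray | None = None  # (E, 10) for quadratic elements
    node_sets: dict = field(default_factory=dict)  # tag -> sorted id array
    external_facets: np.ndarray | None = None  # (F, 3|6), outward corner order
    meta: dict = field(default_factory=dict)
    quality: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    @property
    def conn(self) -> np.ndarray:
        return self.conn10 if self.order == 2 else self.tets

    def volumes(self) -> np.ndarray:
        n = self.nodes
        t = self.tets
        return (
            np.linalg.det(
                np.stack(
                    [
                        n[t[:, 1]] - n[t[:, 0]],
                        n[t[:, 2]] - n[t[:, 0]],
                        n[t[:, 3]] - n[t[:, 0]],
                    ],
                    axis=1,
                )
            )
            / 6.0
        )

    def region_ids(self, name: str) -> np.ndarray:
        code = self.region_names.index(name)
        return np.where(self.region == code)[0]

    def nodes_of_region(self, name: str) -> np.ndarray:
        els = self.region_ids(name)
        return np.unique(self.conn[els].ravel())

    def set(self, tag: str) -> np.ndarray:
        return self.node_sets.get(tag, np.empty(0, int))


def _boundary_faces(tets, nodes):
    """Boundary faces with outward orientation and owner element ids."""
    # local faces of tet (a,b,c,d) with outward normals for a positive tet
    local = [(0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)]
    E = tets.shape[0]
    faces = np.concatenate([tets[:, f] for f in local], axis=0)  # (4E, 3)
    owners = np.tile(np.arange(E), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_s = key[order]
    uniq_mask = np.ones(key_s.shape[0], bool)
    dup = (key_s[1:] == key_s[:-1]).all(axis=1)
    uniq_mask[1:][dup] = False
    uniq_mask[:-1][dup] = False
    sel = order[uniq_mask]
    return faces[sel], owners[sel]


def tetrahedralize(complex_: CellComplex, order: int = 2) -> FEMesh:
    """Convert a cell complex to a (linear or quadratic) tetrahedral mesh."""
    nodes = [np.asarray(p, float) for p in complex_.nodes]
    tets = []
    regions = []
    region_names: list = []
    region_code: dict = {}
    fallback_cells = 0

    for region, faces in complex_.cells:
        code = region_code.get(region)
        if code is None:
            code = len(region_names)
            region_code[region] = code
            region_names.append(region)
        cell_nodes = sorted({v for f in faces for v in f})
        tris = [t for f in faces for t in _triangulate_face(f)]
        fan = cell_nodes[0]
        centroid = np.mean([nodes[v] for v in cell_nodes], axis=0)
        vol_centroid = sum(
            abs(
                np.linalg.det(
                    np.array(
                        [
                            nodes[t[0]] - centroid,
                            nodes[t[1]] - centroid,
                            nodes[t[2]] - centroid,
                        ]
                    )
                )
                / 6.0
            )
            for t in tris
        )
        cell_tets = []
        vol_fan = 0.0
        for t in tris:
            if fan in t:
                continue
            v = _tet_vol(nodes, fan, *t)
            vol_fan += abs(v)
            if v < 0:
                t = (t[0], t[2], t[1])
                v = -v
            cell_tets.append((fan, *t, v))
        min_v = min(ct[4] for ct in cell_tets)
        # the fan must exactly tile the cell (star-shaped from the fan node);
        # an |volume| sum exceeding the centroid-split volume means overlap
        ok = (
            min_v > _VOL_EPS
            and abs(vol_fan - vol_centroid) <= 1e-8 * max(vol_centroid, 1e-30)
        )
        if ok:
            for a, b, c, d, _ in cell_tets:
                tets.append((a, b, c, d))
                regions.append(code)
        else:
            fallback_cells += 1
            centroid = np.mean([nodes[v] for v in cell_nodes], axis=0)
            cid = len(nodes)
            nodes.append(centroid)
            for t in tris:
                v = _tet_vol(nodes, cid, *t)
                if v < 0:
                    t = (t[0], t[2], t[1])
                    v = -v
                if v <= _VOL_EPS:
                    raise MeshQualityError(
                        f"degenerate cell in region {region!r} "
                        f"(tet volume {v:.3e})"
                    )
                tets.append((cid, *t))
                regions.append(code)

    node_arr = np.asarray(nodes, float)
    tet_arr = np.asarray(tets, dtype=np.int64)
    region_arr = np.asarray(regions, dtype=np.int32)

    vols = (
        np.linalg.det(
            np.stack(
                [
                    node_arr[tet_arr[:, 1]] - node_arr[tet_arr[:, 0]],
                    node_arr[tet_arr[:, 2]] - node_arr[tet_arr[:, 0]],
                    node_arr[tet_arr[:, 3]] - node_arr[tet_arr[:, 0]],
                ],
                axis=1,
            )
        )
        / 6.0
    )
    if vols.min() <= 0:
        raise MeshQualityError(f"inverted element (min volume {vols.min():.3e})")

    # ---- node tags as boolean masks --------------------------------------
    n_corner = node_arr.shape[0]
    masks = {}
    for tag, ids in complex_.node_tags.items():
        m = np.zeros(n_corner, bool)
        m[list(ids)] = True
        masks[tag] = m

    conn10 = None
    if order == 2:
        edge_pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        edge_ids: dict = {}
        extra_pos = []
        E = tet_arr.shape[0]
        conn10 = np.empty((E, 10), dtype=np.int64)
        conn10[:, :4] = tet_arr
        for col, (i, j) in enumerate(edge_pairs, start=4):
            a = tet_arr[:, i]
            b = tet_arr[:, j]
            for e in range(E):
                key = (a[e], b[e]) if a[e] < b[e] else (b[e], a[e])
                nid = edge_ids.get(key)
                if nid is None:
                    nid = n_corner + len(extra_pos)
                    edge_ids[key] = nid
                    extra_pos.append(0.5 * (node_arr[key[0]] + node_arr[key[1]]))
                conn10[e, col] = nid
        mid_arr = np.asarray(extra_pos, float).reshape(-1, 3)

        # project midside nodes onto tagged model surfaces
        keys = np.asarray(list(edge_ids.keys()), dtype=np.int64).reshape(-1, 2)
        ids_m = np.asarray(list(edge_ids.values()), dtype=np.int64) - n_corner
        for tag, surf in complex_.surfaces.items():
            m = masks.get(tag)
            if m is None:
                continue
            both = m[keys[:, 0]] & m[keys[:, 1]]
            sel = ids_m[both]
            if sel.size == 0:
                continue
            p = mid_arr[sel]
            if surf[0] == "cyl":
                r = surf[1]
                rad = np.hypot(p[:, 0], p[:, 1])
                scale = np.where(rad > 1e-12, r / np.where(rad > 1e-12, rad, 1.0), 1.0)
                p[:, 0] *= scale
                p[:, 1] *= scale
            elif surf[0] == "sph":
                c = np.asarray(surf[1], float)
                r = surf[2]
                d = p - c
                dist = np.linalg.norm(d, axis=1)
                good = dist > 1e-12
                p[good] = c + d[good] * (r / dist[good])[:, None]
            mid_arr[sel] = p

        node_arr = np.vstack([node_arr, mid_arr])
        # propagate tags to midside nodes
        for tag, m in list(masks.items()):
            both = m[keys[:, 0]] & m[keys[:, 1]]
            full = np.zeros(node_arr.shape[0], bool)
            full[: n_corner] = m
            full[n_corner + ids_m[both]] = True
            masks[tag] = full

    node_sets = {tag: np.where(m)[0] for tag, m in masks.items()}

    # ---- boundary / external facets --------------------------------------
    bfaces, _ = _boundary_faces(tet_arr, node_arr)
    ext_mask_nodes = np.zeros(node_arr.shape[0], bool)
    for tag in complex_.meta.get("external_tags", []):
        if tag in node_sets:
            ext_mask_nodes[node_sets[tag]] = True
    on_ext = ext_mask_nodes[bfaces].all(axis=1)
    ext = bfaces[on_ext]
    if order == 2 and ext.shape[0] > 0:
        mids = np.empty((ext.shape[0], 3), dtype=np.int64)
        for k, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
            for f in range(ext.shape[0]):
                a, b = ext[f, i], ext[f, j]
                key = (a, b) if a < b else (b, a)
                mids[f, k] = edge_ids[key]
        ext = np.hstack([ext, mids])

    mesh = FEMesh(
        nodes=node_arr,
        tets=tet_arr,
        region=region_arr,
        region_names=region_names,
        order=order,
        conn10=conn10,
        node_sets=node_sets,
        external_facets=ext,
        meta=dict(complex_.meta),
        quality={
            "n_cells": len(complex_.cells),
            "fallback_cells": fallback_cells,
            "min_volume": float(vols.min()),
            "total_volume": float(vols.sum()),
        },
    )
    return mesh
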