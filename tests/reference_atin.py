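"""Naive per-point reference implementation of the adaptive-TIN classifier.

Used as an independent oracle for the vectorized implementation: plain
Python loops, per-point plane fitting via explicit linear algebra, same
seeding and acceptance rules (distance to the facet below, angle between
the facet plane and the segment to the facet's nearest vertex).
"""

import numpy as np
from scipy.spatial import Delaunay


def classify_reference(xyz, cell_size, max_distance, max_angle_deg, max_iterations=100):
    xyz = np.asarray(xyz, float)
    # seed: lowest point per occupied cell, ties by input order
    seeds = {}
    for idx, (x, y, z) in enumerate(xyz):
        key = (int(np.floor(x / cell_size)), int(np.floor(y / cell_size)))
        if key not in seeds or z < xyz[seeds[key], 2]:
            seeds[key] = idx
    ground = set(seeds.values())

    for _ in range(max_iterations):
        gidx = sorted(ground)
        tri = Delaunay(xyz[gidx][:, :2])
        added = False
        for j in range(len(xyz)):
            if j in ground:
                continue
            s = int(tri.find_simplex(xyz[j, :2]))
            if s < 0:
                # outside the hull: use a facet incident to the nearest vertex
                d = np.linalg.norm(tri.points - xyz[j, :2], axis=1)
                s = int(tri.vertex_to_simplex[int(np.argmin(d))])
                if s < 0:
                    continue
            vids = [gidx[k] for k in tri.simplices[s]]
            p0, p1, p2 = xyz[vids[0]], xyz[vids[1]], xyz[vids[2]]
            n = np.cross(p1 - p0, p2 - p0)
            if abs(n[2]) < 1e-15:
                continue
            z_plane = p0[2] - (n[0] * (xyz[j, 0] - p0[0]) + n[1] * (xyz[j, 1] - p0[1])) / n[2]
            dist = abs(xyz[j, 2] - z_plane)
            d2 = [np.hypot(*(xyz[v, :2] - xyz[j, :2])) for v in vids]
            v_near = vids[int(np.argmin(d2))]
            seg = xyz[v_near] - xyz[j]
            seg_len = np.linalg.norm(seg)
            if seg_len == 0:
                angle = 0.0
            else:
                n_unit = n / np.linalg.norm(n)
                angle = np.degrees(np.arcsin(min(1.0, abs(np.dot(seg, n_unit)) / seg_len)))
            if dist <= max_distance and angle <= max_angle_deg:
                ground.add(j)
                added = True
        if not added:
            break
    return ground
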