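# osteoplan

Automatic positioning of coincident cutting planes for bone tumor resection
surgery.

Given watertight surface meshes of a bone and an embedded tumor, a surgical
access direction, a plane count `n` and a safety margin, `osteoplan` searches
for the open polygonal chain of `n+1` xy-points whose extrusion along the
access direction forms a cutting surface of `n` planar facets (one saw cut
each).  Particle swarm optimization minimizes

```
f = vol_B_cut / vol_B_tot + K * vol_T_left / vol_T_tot
```

the normalized resected-healthy-bone volume plus a heavily weighted residual
tumor term, under penalties for invalid configurations (facets that miss the
bone, self-intersections crossing the anatomy).  A warm-start path derived
from the tumor projection's 2D convex hull (trimmed to bone-intersecting
vertices, Ramer-Douglas-Peucker-simplified to `n+1` points and offset
outward) replaces one random particle and substantially stabilizes the
search.

No clinical meshes ship with the package; a phantom generator provides three
synthetic bone/tumor families, including a corner-column case whose optimal
two-plane resection (f = 0.0625) is known in closed form.

## Layout

| module | role |
| --- | --- |
| `osteoplan.mesh_core` | STL/PLY I/O, watertightness, volumes, case canonicalization, tumor margin expansion |
| `osteoplan.cutting_surface` | polar ordering, chain extrusion, facet normal orientation, mesh splitting |
| `osteoplan.validity` | facet-misses-bone and self-intersection detection |
| `osteoplan.objective` | penalized fitness evaluation |
| `osteoplan.ach_init` | approximated-convex-hull warm start |
| `osteoplan.pso` | particle swarm optimizer and coefficient-schedule experiments |
| `osteoplan.phantoms` | synthetic bone/tumor mesh generator |
| `osteoplan.workbench` | CLI and report generation |

All cutting facets are parallel to the access direction (canonical +z), so
mesh splitting reduces to 2D: the chain slits the scene's xy-silhouette, the
resected part is the component containing the tumor centroid, and volumes
over the resulting vertical prism are computed exactly from the mesh
triangles (no voxelization in the production path; voxel-column oracles live
in the test suite).

## CLI

```sh
# generate a synthetic case
osteoplan make-phantom corner_column ph/

# plan: canonicalize -> ACH warm start -> PSO -> export report/path/STL
osteoplan plan ph/case.yaml --out-dir plan/ --particles 150 --iterations 100 \
    --schedule variable --seed 1

# evaluate an externally provided path (CSV of x,y per row)
osteoplan evaluate ph/case.yaml plan/path.csv

# coefficient grid study (variable schedule + nine constant c1+c2=4 configs)
osteoplan experiment ph/case.yaml --repeats 10 --out summary.csv
```

`plan` writes `report.json` (case summary, warm start, optimization history,
validity report), `path.csv`, `facet_planes.json` (point + normal per facet,
for downstream guide CAD), `iterations.csv` and the resected-bone STL.

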