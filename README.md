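# cardiotet

Monodomain cardiac electrophysiology simulation on tetrahedral meshes.

Cardiac tissue propagates action potentials as a reaction–diffusion
process: each myocyte's membrane voltage obeys a stiff system of ionic
ODEs, and voltage spreads to neighboring tissue by diffusion.  cardiotet
solves the monodomain formulation

    ∂V/∂t = ∇·(D ∇V) − (I_ion + I_stim)/C_m

on unstructured tetrahedral meshes, with the Luo–Rudy 1991 ventricular
cell model (six ionic currents, Hodgkin–Huxley gating
`du/dt = α(V)(1−u) − β(V)u`) as the reaction term.  It is written for
people studying the *numerics and data layout* of such simulators as much
as the physiology: it implements and tests

- an **enhanced adjacency list** — per-node fixed-width neighbor arrays
  built in one pass over the tetrahedra, giving O(degree) neighbor access;
- **BFS node renumbering** that places topological neighbors at nearby
  indices (bandwidth reduction / memory locality);
- operator-splitting time integration (forward Euler or RK4 reaction,
  Euler diffusion) in two variants: the classic **coupled** scheme, and a
  **decoupled delayed-PDE** scheme in which the diffusion term reads the
  *previous* step's committed neighbor voltages, making node updates
  order-independent at the cost of an O(Δt) consistency error;
- **structure-of-arrays** cell state with constant-parameter extraction
  (60 model quantities per node → 40 varying + 20 shared constants;
  480 → 320 bytes/node, 33% saved);
- interchangeable **scalar / vectorized backends** required to agree to
  1e−9 mV, and a **double-buffered snapshot pipeline** (`t & 1` parity)
  whose output is byte-identical to synchronous writing;
- error analysis (MSE/RMSE/MAE) between schemes and activation-time maps.

A synthetic slab-mesh generator (structured grids split into 6 tetrahedra
per cell, optional seeded shuffling) makes everything testable without
external data; TetGen-style `.node`/`.ele` and Gmsh MSH v2 ASCII meshes
are read and written, and legacy VTK output supports visualization.

See `docs/methods.md` for the model details, numerical choices and
calibrated defaults.

## Mesh formats

TetGen-style pairs (`mesh.node` + `mesh.ele`, 0- or 1-based) — a single
tetrahedron looks like:

```
# mesh.node                      # mesh.ele
4 3 0 0                          1 4 0
1 0.0 0.0 0.0                    1 1 2 3 4
2 1.0 0.0 0.0
3 0.0 1.0 0.0
4 0.0 0.0 1.0
```

and Gmsh MSH v2 ASCII (`$Nodes`/`$Elements`, element type 4 = tetrahedron):

```
$MeshFormat
2.2 0 8
$EndMeshFormat
$Nodes
4
1 0.0 0.0 0.0
2 1.0 0.0 0.0
3 0.0 1.0 0.0
4 0.0 0.0 1.0
$EndNodes
$Elements
1
1 4 0 1 2 3 4
$EndElements
```

Read with `read_mesh(path, dialect="node_ele" | "msh")`; write with
`write_mesh`, or `write_vtk` for a legacy VTK unstructured grid (with
optional per-node scalars such as voltage snapshots or activation maps).

## Worked example

How large is the error introduced by decoupling the PDE by one time step?
Run both schemes on a 6×6×6 synthetic slab (corner stimulus, 20 ms,
forward Euler) over a grid of time steps:

```sh
$ cardiotet error-study --synthetic 6,6,6 --dts 0.01,0.005,0.002,0.001 --t-total 20
   dt  t_total      mse     rmse      mae
0.010     20.0 0.602792 0.776397 0.517215
0.005     20.0 0.147949 0.384642 0.250666
0.002     20.0 0.023746 0.154096 0.098784
0.001     20.0 0.005956 0.077176 0.049074
```

Each row compares the decoupled against the coupled trace over all nodes
and samples.  The mean absolute difference falls from 0.52 mV at
Δt = 0.01 ms to 0.049 mV at Δt = 0.001 ms — the delayed-PDE error vanishes
with the step size, and even the coarse-step error is well under 1% of the
~140 mV action-potential range.

The same machinery is available as a library:

```python
import cardiotet as ct

mesh = ct.generate_synthetic_mesh(16, 16, 17, spacing=0.25)   # 4352 nodes
adj  = ct.build_adjacency(mesh)
perm, mesh, adj = ct.bfs_renumber(mesh, adj, start=0)

stim = ct.StimulusProtocol.from_box(mesh, (1.2, 2.6, 1.2, 2.6, 3.7, 4.0),
                                    amplitude=-80.0, duration=2.0)
cfg  = ct.SimConfig(scheme="decoupled", integrator="rk4", dt=0.005,
                    t_total=150.0, D=0.1, stimulus=stim)
res  = ct.run_simulation(cfg, mesh, adj=adj,
                         consts=ct.CellConstants.short_apd())
act  = ct.activation_map(res.trace, threshold=-40.0)
```

`cardiotet validate` packages that scenario (stimulate the upper-central
patch of the slab, 150 ms at Δt = 0.005 ms) and reports that 100% of nodes
activate within ~8 ms and every node returns to within ~0.1 mV of rest —
the qualitative signature of a healthy propagating beat.

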