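# neuromosaic

Quantitative 3D analysis of neuronal mosaics in tomographic volumes.

X-ray phase-contrast tomography resolves individual neuron somata in
intact nervous tissue — grey level tracks electron density, with the
nucleus as the brightest core of each cell. Given such a volume (or
directly a table of cell coordinates), `neuromosaic` answers three
questions a neuroanatomist asks of a cell mosaic:

1. **Where are the cells?** Intensity-threshold detection: voxels above
   ⟨I⟩ + 2ΔI are segmented into connected components, components smaller
   than 7×7×7 μm³ are discarded, and each survivor becomes a cell with an
   intensity-weighted centroid, physical volume, equivalent diameter and
   a size class (motor neuron 30–50 μm, interneuron 10–20 μm, glia-like
   < 7 μm).
2. **Do they aggregate or disperse?** The 3D Ripley K-function with
   translation edge correction,

       K̂(x) = V/(n(n−1)) · Σ_{i≠j} w_ij · 1[d_ij ≤ x],
       w_ij = V / Π_a (s_a − |Δ_a|),

   compared to the CSR null K_CSR(x) = (4/3)πx³, summarised by the
   clustering degree ρ(Δx) = [K̂ − K_CSR]/K_CSR (> 0 aggregation,
   < 0 dispersion) and the clustering length L_c (the distance range over
   which K̂ > K_CSR), with pointwise Monte-Carlo CSR envelopes.
3. **How regular is the arrangement?** Bounded 3D Voronoi tessellation
   (Qhull), cell density in mm⁻³, mean cell volume V_v and the
   fluctuation dV_v = ΔV_v / V_v — 0 for a lattice, ≈ 0.44 for a random
   (Poisson) mosaic, larger for clustered ones.

A synthetic-data module generates point patterns with known structure
(CSR, Thomas cluster, hard-core) and renders them into tomography-like
volumes with ground truth, so every stage is validated without access to
original tomograms. Scenario presets keyed by spinal-cord level carry the
reported ventral-horn motor-neuron densities for healthy cord and for the
EAE (experimental autoimmune encephalomyelitis) degeneration model, and a
group comparison flags the qualitative degeneration signature — cells
become rarer but more aggregated (density↓, L_c↓, ρ↑).

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Analyse a synthetic thoracic-level ROI with known ground truth:

```python
import numpy as np
from neuromosaic import RipleyK, VoronoiTessellation
from neuromosaic.synthetic import simulate_scenario

pattern = simulate_scenario("thoracic", seed=7)   # 136 cells in a 400³ μm box
res = RipleyK(pattern, radii=np.linspace(30.0, 400.0, 100)).fit(
    envelope=True, n_sims=99, alpha=0.01, seed=7)
print(res.summary())
print(VoronoiTessellation(pattern).fit().summary())
```

```
3D Ripley K analysis
============================================
points                      136
density (mm^-3)             2.12e+03
edge correction             translation
radius grid (μm)            30.00 .. 400.00 (100 steps)
clustering length L_c       385.1 μm
clustering degree ρ(Δx)     +0.002  at Δx = 385.1 μm
K̂ outside CSR envelope     33% of radii

3D Voronoi tessellation
============================================
points                      136
interior points             41
boundary policy             clip_to_box
density (mm^-3)             2.12e+03
mean volume V_v (μm³)       4.706e+05
volume std ΔV_v (μm³)       3.616e+05
fluctuation dV_v            0.768
```

Reading the output: the density matches the generator's 2.0×10³ mm⁻³ to
sampling error; K̂ exceeds the CSR K over the whole admissible range (so
L_c runs to the end of the grid) and escapes the 99% CSR envelope at a
third of the radii — the pattern is significantly clustered; and
dV_v = 0.77 well above the ≈ 0.44 Poisson reference says the Voronoi
mosaic is much less regular than random, as expected for clustered cells.

The same analyses run from the shell:

```sh
neuromosaic simulate --scenario lumbar_eae --seed 1 --out eae/ --render
neuromosaic detect eae/volume.tif --voxel-size 2.0 --out eae/cells.csv
neuromosaic ripley eae/pattern.csv --box 300,300,300 --envelope-sims 99
neuromosaic run --scenario lumbar --seed 1 --out ctrl/
neuromosaic run --scenario lumbar_eae --seed 2 --out eae/
neuromosaic compare ctrl/summary.json eae/summary.json
```

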