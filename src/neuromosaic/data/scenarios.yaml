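# Scenario presets keyed by spinal-cord level.
#
# Motor-neuron densities are the values reported for ventral-horn ROIs of
# healthy cervical/thoracic/lumbar cord and lumbar cord in the EAE
# (experimental autoimmune encephalomyelitis) model. Cluster geometries
# (Thomas process sigma and mean offspring) were calibrated by simulation
# so the empirical clustering length reproduces the scale observed per
# level; the ROI side is chosen so the admissible distance range (radii may
# not exceed the smallest box side) covers that scale. Radius grids start
# at 30 um, the motor-neuron soma scale, below which pair counts carry no
# information. The detection_validation scenario uses a hard-core pattern
# so rendered somata never merge and detector counts can be checked
# exactly.

cervical:
  description: healthy cervical ventral horn, weak tight clustering
  density_mm3: 3000.0
  process: cluster
  cluster_sigma_um: 10.0
  mean_offspring: 3.0
  box: {lo: [0.0, 0.0, 0.0], hi: [300.0, 300.0, 300.0]}
  voxel_size_um: 2.0
  noise_sigma: 10.0
  radii_start_um: 30.0

thoracic:
  description: healthy thoracic ventral horn, intermediate clustering
  density_mm3: 2000.0
  process: cluster
  cluster_sigma_um: 40.0
  mean_offspring: 5.0
  box: {lo: [0.0, 0.0, 0.0], hi: [400.0, 400.0, 400.0]}
  voxel_size_um: 2.0
  noise_sigma: 10.0
  radii_start_um: 30.0

lumbar:
  description: healthy lumbar ventral horn (control group), long-range clustering
  density_mm3: 5000.0
  process: cluster
  cluster_sigma_um: 40.0
  mean_offspring: 10.0
  box: {lo: [0.0, 0.0, 0.0], hi: [600.0, 600.0, 600.0]}
  voxel_size_um: 2.0
  noise_sigma: 10.0
  radii_start_um: 30.0

lumbar_eae:
  description: lumbar ventral horn in EAE, rarefied but locally aggregated
  density_mm3: 1000.0
  process: cluster
  cluster_sigma_um: 20.0
  mean_offspring: 2.0
  box: {lo: [0.0, 0.0, 0.0], hi: [300.0, 300.0, 300.0]}
  voxel_size_um: 2.0
  noise_sigma: 10.0
  radii_start_um: 30.0

detection_validation:
  description: hard-core motor-neuron pattern for detector ground-truth checks
  density_mm3: 1111.11
  process: hardcore
  min_dist_um: 55.0
  box: {lo: [0.0, 0.0, 0.0], hi: [300.0, 300.0, 300.0]}
  voxel_size_um: 2.0
  noise_sigma: 10.0
  radii_start_um: 30.0
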