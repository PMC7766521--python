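# Demo pipeline configuration: a solvated histamine-like monocation with
# solution-phase conformer populations (73% trans), a 92%-occupied
# ammonium-water contact, the toy 16-residue binding pocket, and the
# published-table inputs for the cycle and decomposition stages.
seed: 1

ligand:
  tautomer: Ntau
  protonated: true
  side_torsion: 158.8

solvation:
  n_water: 16
  geometry: sphere
  radius: 7.0
  contacts:
    - [N2, 2.8]
    - [N1, 2.9]
    - [N3, 2.9]

trajectory:
  n_frames: 800
  populations: {trans: 0.73, gauche: 0.27}
  jitter_sigma: 0.02

occupancy:
  - [N2, "HOH@N2", 0.92]

conformer:
  gauche_max: 90.0
  trans_min: 120.0
  k_clusters: 2

hbond:
  max_distance: 3.5
  min_angle: 135.0

rdf:
  r_max: 6.0
  dr: 0.1
  r_cut: 3.5

deuteration:
  fraction: 0.023

cluster_ranges: [[98, 103], [186, 190], [250, 254]]

# the random droplet packs sparser than liquid water, so the demo shell
# uses a wider cutoff to fill the 36-molecule layer
shell:
  n_waters: 36
  cutoff: 5.0
  droplet_n_water: 70
  droplet_radius: 7.5

cycle_components: null     # null -> bundled component table
decomposition_table: null  # null -> bundled decomposition table

affinity:
  temperature: 298.15
  pki: 4.3
  pic50_control: 7.25
  pic50_treated: 7.80
  ph: 7.4
  pka_ring: 6.0
  pka_amine: 9.7
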