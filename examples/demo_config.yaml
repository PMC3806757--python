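# Demo pipeline: two generated toy complexes sharing a residue universe.
# Residues 1000–1002 contact both ligands; 1005–1006 contact only the
# inhibitor (the designed resistance hotspots); 1003–1004 anchor the ions.
seed: 7
outdir: runs/demo
systems:
  atp:
    n_replicates: 2
    toy:
      n_frames: 120
      contact_residues: [0, 1, 2]
      acidic_residues: [3, 4]
      n_ions: 2
      n_key_waters: 3
      n_bulk_waters: 20
  inhibitor:
    n_replicates: 2
    toy:
      n_frames: 120
      contact_residues: [0, 5, 6]
      acidic_residues: []
      n_ions: 0
      n_key_waters: 1
      n_bulk_waters: 20
segmentation:
  penalty: auto
  min_len: 20
  merge_gap: 2.0
scan:
  stride_ps: 10
  keep_key_waters: true
energy:
  sasa_points: 128
hotspots:
  tau_inhibitor: 0.25
  tau_atp: 0.10
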