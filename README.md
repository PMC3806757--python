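# bindmode

Binding-mode decomposition of per-frame MM-GBSA binding-energy series and
alanine-scanning prediction of drug-resistance hotspots in kinase–ligand
complexes.

## The problem

End-point binding free energies (MM-GBSA) computed along molecular-dynamics
trajectories of a kinase bound to its natural substrate (ATP, with its Mg²⁺
ions and conserved catalytic waters) or to an ATP-competitive inhibitor
fluctuate between distinct levels: the complex visits several co-existing
**binding modes** (subpopulations, macrostates) rather than a single bound
state. Averaging over the whole trajectory hides the tighter, sometimes
short-lived modes that matter for inhibitor design.

`bindmode` takes the analysis from the per-frame energy series onward:

1. **Segmentation** — the total-energy series of each replicate is split by
   exact penalized change-point detection (Gaussian mean-shift cost,
   `Σ_seg SSE + β·#changes`, minimized by dynamic programming), segments are
   clustered into macrostates across replicates (length-weighted density-valley
   clustering of segment means, followed by a penalized step-fit refinement of
   the frame assignment), and each macrostate is reported with its occupancy
   and per-component mean ± SD — van der Waals, electrostatics, generalized-Born
   polar solvation, nonpolar surface term.
2. **Energetics** — a desk-scale single-point engine for toy complexes:
   cross-partition Coulomb (k_e = 332.0636 kcal·Å/mol·e²) and 12-6
   Lennard-Jones terms, pairwise generalized Born
   (f_GB = √(r² + RᵢRⱼ e^(−r²/4RᵢRⱼ)), ε_in = 1, ε_out = 80, fixed per-element
   Born radii) and γ·SASA nonpolar with a Shrake–Rupley sphere-point SASA.
3. **Alanine scanning** — per macrostate, every protein residue is truncated
   beyond Cβ and the snapshots rescored; ΔΔG = ΔG_mut − ΔG_wt estimates that
   residue's contribution to binding.
4. **Interactions** — hydrogen-bond detection (3.5 Å / 135°), Mg²⁺
   coordination spheres, signed dihedrals, gauche−/trans/gauche+ rotamer
   classification, and axis-aligned 2-D kernel density maps.
5. **Hotspots** — the ATP-system and inhibitor-system contribution profiles
   are normalized to [0, 1] and contrasted: residues with
   norm_inhibitor ≥ τ_inh and norm_atp ≤ τ_atp are putative resistance sites
   (their mutation can evict the drug while sparing catalysis), benchmarked
   against a literature mutation list with a hypergeometric overlap test.

A synthetic-data module generates every input with known ground truth —
Markov-switching Gaussian energy series matching published per-subpopulation
statistics (bundled in `bindmode/data/reference_macrostates.csv`), toy 3-D
pocket/ligand/ion/water complexes, and von Mises rotamer-cluster dihedral
series — so the full pipeline is testable without any MD engine.

## Worked example

Recover the four binding modes of the EGFR–ATP system from a synthetic
three-replicate series generated at the published state parameters:

```python
from bindmode import BindingModeModel, GeneratorConfig, StateSpec
from bindmode.reference import system_states

states = [StateSpec.from_reference_row(r)
          for _, r in system_states("EGFRa-ATP").iterrows()]
cfg = GeneratorConfig.from_states(states, n_replicates=3, n_frames=5000,
                                  mean_dwell=50.0, seed=42)
model, truth = BindingModeModel.simulate(cfg)
res = model.fit()
print(res.summary())
```

```
Binding-mode decomposition
==========================
replicates: 3   frames/replicate: 5000   macrostates: 4

state  %occ      vdw            ele          gb_polar       nonpolar        total
S1      35.2     -30.8±8.2     -394.6±15.6     370.2±14.7      -7.3±0.2      -62.5±7.6
S2      41.3     -28.2±7.5     -392.8±16.5     372.2±15.5      -7.3±0.3      -56.2±7.6
S3      14.1     -28.0±7.4     -375.2±15.5     359.2±14.5      -7.1±0.3      -51.1±6.6
S4       9.5     -23.3±6.0     -357.9±14.7     344.4±13.8      -7.1±0.1      -43.9±8.4
```

The dominant looser mode S2 (41.3 %, −56.2 kcal/mol) and the tighter mode S1
(35.2 %, −62.5 kcal/mol) recover the generating occupancies (41.5 % / 36.4 %)
and state means (−56.3 / −62.3 kcal/mol) of the reference system; binding is
driven by the large electrostatic term, mostly cancelled by the polar
desolvation penalty, exactly the signature of the phosphate/Mg²⁺-dominated
ATP association.

The full pipeline — toy complexes, per-frame energies, segmentation, per-mode
alanine scan, interaction tables, hotspot report — runs from one config:

```bash
bindmode run --config examples/demo_config.yaml
```

and finishes by listing the designed inhibitor-only contact residues as the
resistance-hotspot candidates (`hotspots_summary.json`:
`"candidates": [1005, 1006]`).

## Layout

```
src/bindmode/
  simulate.py       synthetic generators (energy series, toy complexes, dihedrals)
  segmentation.py   change-point DP, macrostate clustering + refinement
  model.py          BindingModeModel / BindingModeResults (fit/summary API)
  energetics.py     Coulomb, LJ, generalized Born, SASA, B-factors, key waters
  alascan.py        alanine truncation and ΔΔG profiles
  interactions.py   H-bonds, ion coordination, dihedrals, rotamers, 2-D KDE
  hotspots.py       profile normalization, differential candidates, benchmark
  io.py             PQR-dialect structures, text trajectories, CSV tables
  pipeline.py       end-to-end orchestration;  cli.py  the `bindmode` command
  data/             reference macrostate table, literature mutation list
```

See `docs/methods.md` for the models, parameter choices and limitations.
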