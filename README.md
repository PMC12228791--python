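# kinemt

Analysis toolkit for kinesin/microtubule structural studies, in three parts:

1. **Filament-metadata consensus** (`kinemt.filament`, `kinemt.lattice`,
   `kinemt.star`) — per-microtubule bookkeeping applied to Relion-style
   particle tables: modal class voting, smoothing of in-plane angles and
   shifts along each filament, circular-median phi assignment, adjacent-
   segment signal averaging, enumeration of the 2N seam/register hypotheses
   of an N-protofilament B-lattice, modal seam-register assignment,
   symmetry expansion into per-protofilament asymmetric units, focused
   sub-particle re-centering, and occupancy statistics.
2. **Structure comparison** (`kinemt.structmodel`, `kinemt.compare`,
   `kinemt.hbonds`) — selection-restricted Kabsch superposition with
   global/per-residue RMSD and rotation angle/axis decomposition, CA
   displacement after frame alignment, distal-head rotation between
   two-headed complexes, and hydrogen-bond network extraction/diffing.
3. **MD observables** (`kinemt.mdobs`) — monitored pair distances, ligand
   RMSD after rigid alignment on a CA subset, fluctuation statistics, 2D
   densities, the adaptive Level 1→2→3 restart-frame selector, sustained-
   release detection, ion-coordination counting, and the protocol time
   ledger.

`kinemt.synthetic` generates every fixture with known ground truth
(filament tables with a register-confusion vote model, structure pairs
with constructed rigid transforms and displacement fields, and
ligand-in-well escape trajectories), so the whole pipeline is testable
without any downloads. `kinemt.pipeline` orchestrates stages from a YAML
config and writes a checksummed manifest.

## CLI

```sh
kinemt --version
kinemt consensus references --n-pf 13          # 26 seam/register hypotheses
kinemt --seed 7 synth filaments --n-filaments 5 --confusion-p-true 0.7 --out f.star
kinemt consensus vote f.star --out voted.star
kinemt consensus seam f.star --out seamed.star
kinemt consensus expand f.star --out expanded.star
kinemt md ledger                               # adaptive protocol: 9.75 us
kinemt --seed 2 synth escape --n-frames 5000 --escape-bias 4 --out traj.csv
kinemt md release traj.csv
kinemt structure superpose mobile.pdb reference.cif --selection P_LOOP+HELIX_A2A
kinemt run --config pipeline.yaml
```

Pipeline configs are YAML with a `stages` list; see
`kinemt.pipeline.STAGES` for stage names and `tests/test_pipeline_cli.py`
for working examples.

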