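# fibrilmod

Quantitative analysis of how a polyvalent ligand — spermine in the
motivating application — reshapes the monomeric conformational ensemble of
an intrinsically disordered protein (IDP) relative to disease-relevant
amyloid fibril architectures.

Aggregation-prone IDPs such as Tau (and its K18 fragment, residues
244–372), α-synuclein and Aβ40 form structurally distinct fibril
polymorphs in patients. Whether a small polyvalent ligand promotes or
suppresses aggregation can be read out at residue-pair resolution from
molecular-dynamics ensembles of the *monomer*: if a residue pair that is
in contact inside a fibril core becomes more probable in solution as the
ligand concentration rises, the ligand biases the monomer toward that
fibril fold.

## What the package computes

- **Fibril-native contacts and polymorph clustering.** Each deposited
  fibril structure (PDB/mmCIF) is reduced to one monomer and to the set of
  intrachain residue pairs whose heavy atoms come within 0.45 nm at
  sequence separation |i−j| ≥ 4. Structures are clustered by shared
  contacts (graph connected components): polymorphs sharing no contact
  with any other remain singletons.
- **Contact maps and modulation coefficients.** For each ensemble, the
  contact probability P<sub>ij</sub> is the fraction of frames with any
  heavy atom of residue *i* within 0.45 nm of any heavy atom of residue
  *j*. Across a ligand:protein ratio series, the modulation coefficient
  k<sub>ij</sub> is the ordinary-least-squares slope of P<sub>ij</sub>
  versus ratio, evaluated on fibril-native pairs: k<sub>ij</sub> > 0 means
  the ligand promotes that fibril contact, k<sub>ij</sub> < 0 that it
  suppresses it.
- **Contact dynamics.** Twin-cutoff (0.45/0.6 nm hysteresis) binary
  contact trajectories, their autocorrelation C(t), and relaxation times
  from a single-exponential fit — the sampling-adequacy check for contact
  formation/breaking.
- **Ligand association.** Per-residue mean ligand counts
  (N<sub>ligand</sub>, 0.45 nm cutoff), ligand-mediated contact maps
  P<sub>i,s,j</sub> (both residues within 0.6 nm of the *same* ligand
  molecule), and binding-event kinetics: residue residence time
  τ<sub>residue</sub> (enter below 0.45 nm, leave beyond 0.6 nm),
  protein-level τ<sub>protein</sub>, and per-residue exchange rates, with
  explicit censoring of events still bound at trajectory end.
- **Chain metrics.** Radius of gyration with 4-block SEM, Cα–ligand radial
  distribution functions g(r) under the minimum-image convention, the
  Flory scaling exponent ν from R(s) = b·s<sup>ν</sup> with the prefactor
  fixed at b = 0.55 nm, and 3-state secondary-structure fraction
  aggregation from per-frame assignment codes.
- **ThT aggregation kinetics.** Plate-reader fluorescence fitted to the
  logistic model F(t) = F₀ + (F<sub>max</sub> − F₀)/(1 + exp[−k(t −
  t<sub>1/2</sub>)]), lag time t<sub>1/2</sub> − 2/k, and seeded
  residual-resampling bootstrap confidence intervals.
- **Synthetic data with known ground truth** for every stage: bead-chain
  ensembles with programmed P<sub>ij</sub>(ratio) = a + b·ratio, telegraph
  ligand-binding processes with known on/off rates, fibril-like structure
  sets with designed cluster layouts, and noisy logistic ThT curves.

A periodic-image QC filter (flagging frames whose protein approaches its
own image within 0.3 nm) runs before all analyses.

## Worked example

Generate a three-ratio synthetic series in which the contact (3, 10) is
programmed to gain 0.04 probability per unit ligand ratio, then recover
that slope:

```python
import pandas as pd
from fibrilmod import RunConfig, run_pipeline
from fibrilmod.fibrils import NativeContactSet, write_contacts_tsv
from fibrilmod.synthetic import GeneratorSpec, ProgrammedContact, generate_ensemble
from fibrilmod.trajectory import write_ensemble_pdb, write_topology_json

rows = []
for ratio in (0.0, 5.0, 10.0):
    spec = GeneratorSpec(seed=13, chain_length=14, n_frames=400,
                         programmed_contacts=[ProgrammedContact(3, 10, 0.2, 0.04)])
    ens = generate_ensemble(spec, ratio)
    write_ensemble_pdb(ens, f"r{ratio:g}.pdb")
    write_topology_json(ens.topology, f"r{ratio:g}.json")
    rows.append((f"r{ratio:g}", ratio, f"r{ratio:g}.json", f"r{ratio:g}.pdb", 0))
pd.DataFrame(rows, columns=["condition_label", "ratio", "topology",
                            "trajectory", "skip_frames"]).to_csv(
    "manifest.tsv", sep="\t", index=False)
write_contacts_tsv(NativeContactSet("design", frozenset({(3, 10)})), "native.tsv")

out = run_pipeline(RunConfig(out_dir="out", seed=1), "manifest.tsv",
                   native_contacts="native.tsv")
print(pd.read_csv(out / "modulation.tsv", sep="\t", comment="#"))
```

This prints the modulation table for the single native pair:

```
   i_full  j_full      k  intercept        r2  n     class
0       3      10  0.039   0.205833  0.958815  3  promoted
```

`k = 0.039` recovers the programmed slope 0.04 within binomial sampling
error of 400 frames per condition, `intercept ≈ 0.21` the programmed
baseline occupancy, and the pair is classified as promoted by the ligand.

The same stages are exposed on the command line
(`fibrilmod simulate | qc | contacts | fibril | cluster | modulate |
binding | metrics | tht-fit | pipeline`).

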