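# ankylotherm

Is the ankyrin (ANK) domain of the Notch-1 receptor a cellular
thermometer?  The active Notch transcription complex (NICD·RBPJ·MAML-1)
is held together in part by the ankyrin domain — a stack of ~seven
33-residue repeats, each two antiparallel α-helices (α1, α2) followed by a
β-hairpin.  Relative to other ankyrin domains, Notch-1's has accumulated
destabilizing features: alanine-enriched helices, clusters of acidic
residues on the solvent-exposed hairpin/α2 surface, and a markedly higher
mean intrinsic-disorder score.  `ankylotherm` implements the computational
chain behind that argument as a tested, reusable Python package for
structural bioinformaticians:

* **repeat anatomy** — profile-based segmentation into 33-residue repeats,
  element labelling (positional template or Cα geometry), per-element
  composition and log2 enrichment, global-alignment percent similarity;
* **disorder energetics** — the Boltzmann-inverted pair potential
  `E_ij = −ln(ρ_ij/ρ*_ij)`, windowed per-residue disorder scores in
  [0, 1], and the charge/hydrophobicity plane with the natively-unfolded
  boundary `⟨R⟩ = 2.785⟨H⟩ − 1.151`;
* **sensor thermodynamics** — the destabilization coefficient
  `R·(S_notch/S_ref)·N/1000` (kcal·mol⁻¹·K⁻¹), the dissociation
  temperature `|ΔG⁰|/coefficient`, its partition over degrees of freedom,
  and the cellular heat spike `P·t/(c_p·m)`;
* **surface electrostatics** — formal side-chain charges, a Shrake–Rupley
  dot surface, the screened-Coulomb (Debye–Hückel) potential
  `φ(r) = Σᵢ C qᵢ e^{−|r−rᵢ|/λ_D}/(ε|r−rᵢ|)`, connected charged-zone
  detection, carboxyl distance matrices and charge anisotropy;
* **interface hydrogen bonds** — geometric detection (donor–acceptor
  ≤ 3.5 Å, donor-antecedent angle ≥ 120°, both configurable) and
  per-molecule-pair inventories for multi-chain complexes;
* **a charged coupled-oscillator model** — Langevin dynamics of the repeat
  stack with charge-softened on-site springs and screened inter-repeat
  repulsion, reproducing the qualitative RMSF response to temperature and
  to charge-removal mutation;
* **assay arithmetic** — the Pfaffl ratio, amplification-efficiency
  regression over the window of linearity, and a unimolecular
  nearest-neighbour melting temperature for beacon hairpins;
* **synthetic generators** — idealized repeat structures, complexes with
  planted hydrogen bonds, charge-cluster fixtures with known patch
  membership, and qPCR curves of known efficiency, so every stage is
  testable offline with exact planted truth.

## Worked example

```python
from ankylotherm.thermo import ThermoParams, HeatBudget, sensor_report

report = sensor_report(
    ThermoParams(score_target=0.37, score_ref=0.21, n_residues=230,
                 deltaG0=-8.0, ndof=3),
    HeatBudget(power=20.0, mass=1.0, duration=1.0),
)
for key, value in report.items():
    print(f"{key}: {value:.3f}")
```

prints

```
per_residue_coefficient_cal_mol_K: 3.501
destabilization_coefficient_kcal_mol_K: 0.805
dissociation_delta_t_K: 9.935
dof_threshold_K: 3.312
heat_spike_K: 4.780
spike_exceeds_dof_threshold: 1.000
```

Read: with the Notch-1 mean disorder score (0.37) against the yeast
reference (0.21), each of the domain's 230 residues contributes
3.5 cal·mol⁻¹·K⁻¹ of relative destabilization — 0.8 kcal·mol⁻¹ per kelvin
for the domain.  Dissociating the complex (ΔG⁰ ≈ −8 kcal·mol⁻¹) then
needs ≈10 K, or only ≈3 K if the energy channels into the domain's one
soft axis (3 degrees of freedom).  A 1 ng cell producing 20 nW for one
second warms by ≈4.8 K — above that threshold, so a metabolic burst can
plausibly switch Notch signalling off.

The same chain is available from the shell (`ankylotherm thermo`,
`ankylotherm heat`), alongside `segment`, `compose`, `similarity`,
`disorder`, `patches`, `distances`, `hbonds`, `simulate`, `assay`,
`synth` and `report` subcommands; `ankylotherm report` chains every stage
into a deterministic TSV/JSON bundle with a hashed manifest.

The numbered scripts under `analysis/` walk the full study — repeat
anatomy, disorder, thermodynamics, electrostatic zones, the hydrogen-bond
inventory (with a criteria sensitivity sweep), the oscillator temperature
response, and the assay arithmetic — writing their tables under
`results/analysis/`.

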