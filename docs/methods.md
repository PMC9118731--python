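# Methods

This note records the models, parameter choices and numerical decisions
behind `ankylotherm`, and what the synthetic fixtures do and do not
establish about real data.

## Repeat segmentation and elements

A 33-residue ankyrin repeat is scored against a position-weight profile
(log2-odds vs a uniform background, pseudocount 0.5) estimated from a
small curated alignment of canonical repeats built around the invariant
TPLH and GH/GADVNA motifs (`repeats.CANONICAL_REPEATS`); any 33-column
alignment can be substituted.  Segmentation is a weighted-interval dynamic
program over all window offsets: it maximizes first the number of
non-overlapping above-threshold windows (threshold 0 log2-odds), then the
total score, taking windows greedily leftward on exact ties.  With
`n_expected` set, the threshold is relaxed and the best-scoring n windows
kept.

Element labels come from a fixed positional template in sequence-only
mode — positions 5–12 α1, 15–24 α2, 25–31 βhp, the rest loop, matching
the canonical ordering of the fold — or geometrically when Cα
coordinates exist: residues i..i+3 are helical when |Cα(i)−Cα(i+3)| lies
in 4.0–6.5 Å (an ideal α-helix with 1.5 Å rise and ~100° turn gives
≈5.1 Å; extended strands ≈10 Å); the first two ≥4-residue helical runs in
a repeat become α1/α2 and the trailing non-helical stretch the hairpin.

Percent similarity is a global affine-gap alignment (BLOSUM62, open 10,
extend 1 by default, via Biopython's `PairwiseAligner`); "similar" means
a positive substitution score, the denominator is alignment columns with
terminal gaps excluded (domain extracts have ragged ends).  The aligner
is cross-checked in the tests against exhaustive alignment enumeration at
linear gap penalties on short sequences.

## Disorder scoring

The pair potential is Boltzmann-inverted from pairing statistics:
ordered residue pairs within a contact window (default 4) are counted in
both orders, ρ* is the outer product of marginal frequencies, and
E = −ln(ρ/ρ*).  Cells never observed are flagged NaN, and imputed as the
observed maximum + 1 only at scoring time — an unseen pairing carries no
evidence of attraction, and NaNs must not propagate.

Because no structural contact corpus ships with the package, the default
potential is inverted from a packaged *synthetic quasi-globular corpus*:
runs of 4–8 hydrophobic residues separated by 1–3 scattered polar ones,
mimicking the way folded chains cluster a buried core while isolating
surface polars.  Under it, hydrophobic–hydrophobic pairings come out
favourable and specific polar–polar pairings unfavourable, which is the
qualitative structure the published disorder predictors rely on.

A residue's score is the mean interaction energy of its window (default
21, within the published 2–100 range; truncated at termini) mapped by a
logistic to [0, 1].  The logistic midpoint/slope are anchored so that a
packaged ordered/disordered benchmark pair (a hydrophobic-core-like and a
polar low-complexity sequence, both synthetic) straddles 0.5.  The scorer
is therefore validated on *orderings and ranges only*; the published
per-domain score averages (0.37 Notch-1, 0.22 other human ankyrins, 0.21
yeast, 0.16 A. thaliana) depend on the original tool's parameter fit and
are accepted verbatim as inputs downstream (`read_scores_tsv` ingests
externally computed profiles).

The charge/hydrophobicity classifier uses side-chain charges D,E = −1,
K,R = +1, H = +0.1 (pH 7 approximation, configurable), Kyte–Doolittle
hydrophobicity min-max normalised to [0, 1] and smoothed over 5-residue
windows, and the standard boundary line ⟨R⟩ = 2.785⟨H⟩ − 1.151.

## Sensor thermodynamics

The chain is deliberately back-of-envelope and is implemented exactly:

* destabilization coefficient = R·(S_target/S_ref)·N/1000 kcal·mol⁻¹·K⁻¹
  with R = 1.987 cal·mol⁻¹·K⁻¹ (= N_A·k_B) and N = 230 residues.  With
  S_ref = 0.21 the per-residue value is 3.50 cal·mol⁻¹·K⁻¹ and with 0.22
  it is 3.34; both round the domain coefficient to 0.8, so both
  references are supported and the default is 0.21 (the value consistent
  with the printed 3.5).
* dissociation ΔT = |ΔG⁰|/coefficient, with ΔG⁰ = −8 kcal·mol⁻¹ for
  NICD–RBPJ binding: ≈10 K.
* dof threshold = ΔT/ndof with ndof = 3 by default.  The "3 degrees of
  freedom" stands for the domain's flexibility being channelled along one
  major axis; it is qualitative, so ndof is a free parameter.
* heat spike = P·t/(c_p·m) with c_p = 4.184 J·g⁻¹·K⁻¹; nW·s ≡ nJ and
  J·g⁻¹·K⁻¹ ≡ nJ·ng⁻¹·K⁻¹, so the nano prefixes cancel: 20 nW into 1 ng
  for 1 s gives 4.78 K.

All values are carried at full precision; rounding (one decimal, integer
kelvin) happens only in reporting.

## Surface electrostatics

A single-dielectric Debye–Hückel screening stands in for the
two-dielectric Poisson–Boltzmann solve: point formal charges (D/E −1 at
the carboxyl-oxygen midpoint, K +1 at NZ, R +1 at CZ, H neutral by
default), a Shrake–Rupley dot surface (probe 1.4 Å, 256 dots/atom by
default — a Fibonacci sphere per atom, dots kept when outside every
neighbour's expanded sphere), and

    φ(r) = Σᵢ C qᵢ exp(−|r−rᵢ|/λ_D) / (ε |r−rᵢ|)

with C = N_A e²/(4πε₀) = 1389.35 kJ·Å·mol⁻¹·e⁻² and λ_D from the ionic
strength (7.83 Å at 0.15 M, 298.15 K, ε = 78); zero ionic strength
recovers the bare Coulomb potential exactly.  The solvent dielectric 78
is used throughout; the protein dielectric (2 in the original two-zone
setup) has no role in a single-dielectric model and is kept only as
recorded provenance.  Patches are connected components (link distance
2× the mean dot spacing by default) of points beyond ±5 kJ·mol⁻¹·e⁻¹ —
the colour-scale extreme of the original maps.  **Consequence:** patch
*areas* are comparative only; the testable claim is zone identity (which
residues belong to which connected zone), and that is what the tests and
the planted fixtures assert.  Charge anisotropy is the dipole
|Σ qᵢ(rᵢ−c)| about a supplied centroid (defaulting to the mean charge
site); pass the molecular centroid to compare across molecules.

## Hydrogen bonds

Donors are N/O/S heavy atoms with an in-residue antecedent (backbone N
except proline; side-chain donors per residue type), acceptors are
carbonyl/carboxyl/hydroxyl O, His N and Met S.  A bond requires
donor–acceptor distance ≤ d_max (3.5 Å default) and, when no explicit
hydrogen is present, antecedent–donor–acceptor angle ≥ angle_min (120°
default); with hydrogens, the D–H⋯A geometry is used.  Bifurcated bonds
count once per atom pair; same-residue pairs are excluded.  The criteria
are config-exposed because published interface counts always depend on
them; `analysis/05` sweeps d_max 3.2–3.6 Å and angle 90–135° and reports
the count stability instead of tuning silently.  Chain-to-molecule
grouping is always supplied explicitly, never guessed.

## The coupled-oscillator model

Each repeat is one particle displacing in 1-D along the domain's long
axis (the fold's soft direction).  Model units: mass 1, lattice spacing
1, k_B T ≈ 1 at 300 K (kb = 1/300 per kelvin).  Forces:

* on-site spring k_intra = 100, *softened* by the repeat's surface
  charge: k_i = k_intra − 20·qᵢ² — the like-charge self-repulsion of a
  clustered acidic surface destabilizes the repeat's own fold.  This is
  the term that carries the charge→fluctuation coupling: a purely convex
  pair repulsion between collinear charges would *stiffen* the chain
  (along the line of centres, like-charge repulsion is stabilizing), so
  the destabilization must act on the local fold, which is also where the
  natively-unfolded argument locates it.
* soft neighbour springs k_link = 5 (the hairpin connectors).
* screened inter-repeat repulsion C·qᵢqⱼ·e^{−r/λ}/r with C = 5, λ = 1,
  which shifts the equilibrium outward and couples neighbours
  anharmonically.
* Langevin thermostat, friction 1, BAOAB splitting, Gaussian kicks from a
  counter-based Philox stream keyed by the seed — trajectories are
  bit-reproducible and ensemble integration is exactly equivalent to the
  per-seed runs.  The step bound dt ≤ 0.1/ω_max is enforced
  (default dt 0.005); runs start from the static equilibrium (scipy root
  solve) so a T = 0 run stays put.

The Notch preset places charge −1 on repeats 3–6 (the acidic clusters).
Defaults were chosen once to satisfy the qualitative orderings the model
exists for — RMSF grows with temperature, charged repeats out-fluctuate
neutral ones, discharging a repeat dampens it — and absolute RMSF values
are *not* comparable to all-atom simulation.  Because the 310.15 → 312.15
K contrast is only ~0.6% in k_BT, ordering tests use common random
numbers (the same seed list at both temperatures), which makes the paired
comparison essentially deterministic at 8–10 seeds; independent-seed
comparisons at this effect size would need orders of magnitude more
sampling.  Test problem sizes (40k–100k steps, 8–10 seeds; one 10⁶-step
equipartition check against ⟨x²⟩ = k_BT/k within 5%) were chosen as the
smallest that make those contracts statistically comfortable.

## Assay arithmetic

* Pfaffl ratio Eff_tar^Δct_tar / Eff_ref^Δct_ref, with Δct fixed as
  control − test; swapping test and control negates both Δct and inverts
  the ratio exactly.
* Amplification efficiency: best 5-point window of log10 F vs cycle by
  coefficient of determination among positive-slope, positive-signal
  windows (ties to the earliest cycles), efficiency = 10^slope.  The
  estimate is scale-invariant; on noiseless exponentials it is exact, and
  under 1% relative Gaussian noise the mean over replicates recovers the
  truth within ±0.02.
* Hairpin Tm: unimolecular two-state, Tm = ΔH/ΔS (no concentration
  term), ΔH/ΔS summed over the stem's nearest-neighbour stacks
  (SantaLucia unified DNA parameters from Biopython), plus a loop-closure
  entropy −14.0 cal·mol⁻¹·K⁻¹ at the reference loop of 15 nt — calibrated
  once against the two beacon anchors (36 °C for the 4-bp stem, 50 °C for
  the 5-bp stem; the model reproduces them at 34.0/52.6 °C, within the
  documented ±3 °C band) — extrapolated to other loop sizes by
  Jacobson–Stockmayer 1.75·R·ln(n/15), and the salt term
  0.368·n_stacks·ln[Na⁺] with [Na⁺] = 0.135 M by default (the
  electroporation buffer's KCl concentration).  Only the MB-5 > MB-4
  ordering is asserted as a hard contract; the measurement buffer and
  half-dissociation criterion behind the printed values are unknown.

## Synthetic fixtures: what they do and do not show

The generators plant exact ground truth: ideal-geometry repeats (1.5 Å
helical rise, 100° turn, extended hairpins), complexes whose every
hydrogen bond is placed at a chosen distance/angle in an isolated 40 Å
cell (so no unplanted polar contact can qualify), charge clusters whose
zone membership is known, and qPCR curves of known efficiency.  In the
noiseless case recovery must be exact, so the fixtures double as oracles
for the analysis modules.  The bundled ternary-complex model
(`notch_ternary_complex`) is a *synthetic stand-in*, not the crystal
structure: it reproduces the reported interface topology (8 ANK↔MAML-1
bonds, 5 via GLU-2008/ASP-1972, 2 GLN-347↔ASP-1994 bonds, in Notch-1
author numbering) and exercises the identical inventory code path.
Likewise the orthologue-pair generator emulates a conserved domain pair
at a chosen divergence rather than the real human/fly sequences.  Passing
these tests establishes that the machinery is correct and exactly
recovers planted truth; it does not re-measure the crystal-structure
counts or the real cross-species similarity, which require the actual
PDB entries and orthologue sequences as inputs (`read_structure`,
`read_fasta` accept them directly when available).

## Known limitations

* Debye–Hückel screening with point charges cannot reproduce
  Poisson–Boltzmann isopotential areas; only zone identity is meaningful.
* The oscillator model is 1-D and harmonic-plus-corrections; it encodes
  the charge-softening hypothesis rather than testing it.
* The disorder scorer's absolute scale is anchored on synthetic
  benchmarks; cross-tool score comparisons require external profiles.
* Insertion codes are carried for identity but ordering within a residue
  number is not resolved beyond file order.
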