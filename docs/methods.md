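# Methods

## Model

Each atom is a Hansen–Coppens pseudoatom: a continuous electron density

ρ(**r**) = P_core ρ_core(r) + P_val κ³ ρ_val(κr) + Σ_{l=0}^{4} κ′³ R_l(κ′r) Σ_m P_lm d_lm(θ, φ)

evaluated in an atom-local frame. The three terms are the frozen core,
the κ-scaled spherical valence shell, and the aspherical deformation
density. A molecule is simply the superposition of its pseudoatoms; the
model is rigid (no polarization, no geometry response) and purely
electrostatic — exchange-repulsion, dispersion and induction are out of
scope by construction.

Conventions fixed in this implementation:

- **Units.** Internal lengths in Bohr, energies in Hartree; all I/O in
  Angstrom and kcal/mol. 1 Bohr = 0.529177210903 Å, 1 Hartree =
  627.509474 kcal/mol (CODATA 2018), giving the Coulomb constant
  332.0637 kcal Å mol⁻¹ e⁻² used for point charges.
- **Core/valence densities** are per-electron-normalized sums of
  squared single-ζ Slater orbitals read from a packaged plain-text
  shell table (`data/wavefunctions.txt`, Clementi–Raimondi effective
  exponents, noble-gas core split). Alternative tables in the same
  format can be swapped in.
- **Deformation radial functions** R_l(r) = ζⁿ⁺³/(n+2)! rⁿ e^(−ζr) are
  density-normalized; n(l) is stored per databank entry. Defaults follow
  the usual second-row choice n(l) = 2,2,3,4 for l = 1..4, with
  phosphorus at 2,4,6,8 and sulfur at 6,6,6,6. Deformation ζ values are
  density-scale, i.e. about twice the orbital exponent — a deformation
  cloud must decay like the squared orbital it redistributes, and an
  orbital-scale exponent produces unphysically long-ranged deformation
  density (and penetration energies of the wrong sign at hydrogen-bond
  distances).
- **d_lm** are density-normalized real spherical harmonics:
  ∫|d_lm| dΩ = 2 for l ≥ 1 (a population P_lm shifts |P_lm| electrons
  between lobes), d_00 = 1/4π. The normalization constants are computed
  once at import by piecewise adaptive quadrature between the zeros of
  the Legendre factors rather than transcribed from literature tables.
- **Local frames**: z toward the heaviest bonded neighbor (ties broken
  by distance, then name), x toward the next neighbor, Gram–Schmidt
  orthogonalized; terminal atoms fall back to the global axis least
  parallel to z; isolated atoms carry no frame and may only be
  spherical. Frames are deterministic and independent of atom input
  order.
- **Net atomic charge** q = Z − P_core − P_val − P_00 (the packaged
  parameter sets use P_00 = 0).

## Parameter transfer

Atom types are keyed by element plus the sorted multiset of bonded
neighbor elements, with a documented fallback order (full key →
element + neighbor count → element). This is deliberately simpler than
the full topological keys of production pseudoatom databanks; the
packaged fixture databank is physically sane but makes no claim of
numerical agreement with any published parameter set, which also means
full-size literature energy values are reproduced in character, not in
number.

The transfer protocol is two-pass, as used for metal-containing
macromolecules: bonds are first detected with the Mg covalent radius
overridden to 0.01 Å so that Mg–O coordination contacts never count as
covalent bonds while X–H bonds are extended to standard neutron
distances (C–H 1.092, N–H 1.009, O–H 0.983, S–H 1.338 Å; a YAML config);
typing then runs with the default Mg radius of 1.36 Å so the metal's
coordination environment is visible to the matcher. Bond criterion:
d ≤ r_i + r_j + 0.4 Å.

After transfer, each fragment (usually one residue; optionally a grouped
unit such as metal + waters + triphosphate + a coordinating carboxylate)
is rescaled so its modeled charge equals its formal charge *exactly*
(to 1e−8 e). The shift is distributed proportionally to each atom's
current P_val — preserving relative valence populations — with an
additive-uniform mode available; P_lm, κ, κ′ are never touched.

## Energies

**Multipole (MM).** Atomic moments of the total charge density
(nucleus + electrons) in the spherical-tensor (Racah) convention, up to
l = 4 per atom. For each pair, moments are rotated into the frame whose
z axis is the internuclear vector and contracted with the closed-form
interaction coefficients (−1)^{l₂} √(C(L, l₂+m) C(L, l₂−m)) / R^{L+1},
L = l₁+l₂ — exact for non-overlapping densities, and including all
terms with l₁, l₂ ≤ 4 (hence L ≤ 8). Real-spherical-harmonic rotation
matrices are obtained by sampling on a fixed spherical point set and
solving the exactly determined linear system, avoiding recursion-formula
bookkeeping; they are validated by rotation-equivariance property tests.

**Exact potential (EP).** The pair Coulomb integral is decomposed:
nucleus–nucleus and both nucleus–electron terms are analytic (the
electron potential of every density term has a closed form via lower and
upper incomplete gamma functions, including the aspherical l ≥ 1 terms),
so only the smooth electron–electron integral is done numerically. It is
integrated on atom-centered grids — Gauss–Chebyshev (second kind) radial
nodes with a Becke-style r_m(1+x)/(1−x) mapping, times Gauss–Legendre ×
uniform-φ product grids on the sphere — and averaged over the two atoms'
grids, which makes E(a,b) = E(b,a) exact by construction. Grid
orientation is tied to the pair axis and the atoms' local frames, so
rigidly moving the whole system leaves energies unchanged to machine
precision. Requested angular sizes snap to the 2k² product-grid ladder
(590 → 648, 974 → 1058 points; exact for spherical harmonics to degree
2k−1).

**Hybrid (EPMM).** Pairs with separation ≤ rcrit get EP, the rest MM;
`e_mm` is the multipole energy over *all* pairs, so the penetration
energy E_pen = E_EPMM − E_MM holds identically and is exactly zero when
no pair enters the EP zone. Defaults follow the production run settings
Nrad = 99, Nang = 590, rcrit = 5 Å (a 4.5 Å zone radius also appears in
method descriptions of this family; both are accepted — the default is
the run setting). At these settings, refining to Nrad = 199 /
Nang = 974 moves pair energies by ~1e−4 kcal/mol, and the exact
integral agrees with an independent brute-force oracle to ~4e−5
kcal/mol on Slater dimers.

**Point charges.** Plain Coulomb sums over partial charges, provided
for force-field-style comparisons; with all higher moments dropped the
multipole energy reduces to exactly this.

## Pipeline

`partition_fragments` finds the RNA chain (first residue carrying ≥ 2
phosphorus atoms), takes its first three residues as fragments, and
assigns the metal plus the waters whose O sits within 2.6 Å of it to
fragment 1 (more than three such waters is an error; a missing metal is
a logged warning). `residue_energy_table` computes the residue ×
fragment E_MM/E_EPMM/E_pen table and applies three filters:

1. distance — any atom (hydrogens included) within 5 Å of any RNA
   fragment atom, closed interval;
2. significance — |E_EPMM| strictly greater than 5 kcal/mol against any
   fragment ("over ±5");
3. penetration — |E_pen| ≥ 2 kcal/mol, restricted to the
   distance-selected site. The 2 kcal/mol default is a choice of this
   package (the filter idea does not come with a published threshold);
   raw E_pen values are always kept in the report so the threshold is
   post-hoc adjustable.

The pipeline refuses to run on models whose fragments do not sit at
integral formal charges (a sign that charge scaling was skipped).
Reports are deterministic to the byte: there is no randomness anywhere
downstream of structure generation.

`compare_sequences` aggregates per-fragment totals across complexes and
reports the maximum pairwise spread of the grand totals as a percentage
of their mean magnitude.

## ESP maps

Potential maps on cubic grids sum, per atom, the exact analytic
potential within rcrit and the l ≤ 4 multipolar far field beyond it;
voxels on a nucleus are clipped at ±1e4 a.u. and counted. Values are in
atomic units (e/Bohr); output is Gaussian cube (Bohr header). Iso-density
masks threshold the electron density (conventional surface level
0.002 e/Bohr³) with 6-neighborhood surface extraction. The default
desk-scale grid is a 250 Å³-class box at 0.5 Å voxels; finer settings
are accepted with a memory warning.

## Synthetic data and oracles

The generators exist so every stage runs and is checkable offline:

- a fixture databank (H, C, N, O, P, S, Mg, water types) with sane
  κ ∈ (0.5, 2), near-neutral valence populations, and deformation terms
  calibrated only so far as to reproduce known qualitative physics —
  penetration negative and monotonically decaying at hydrogen-bond
  contacts (−2.2 kcal/mol at 1.8 Å for an ammonium/formate pair);
- single-atom 1s-Slater dimers with closed-form electrostatics (the
  two-exponential Coulomb integral is re-derived symbolically with
  sympy inside the test that uses it);
- toy protein–RNA complexes: a triphosphate-bearing first nucleotide
  (−4 e), Mg²⁺ with three waters at 2.1 Å, −1 e nucleotides, and +1/−1/0
  residue mimics placed on a 3–12 Å shell with seed-deterministic
  integer-grid direction draws and a 2 Å clash guard. A `base_variant`
  switch tilts the nucleobase mimic while keeping the rest of the
  geometry fixed, emulating the same binding site presented with a
  different RNA sequence. Toy residues are coarse mimics — correct
  formal charges, bonding topology and coordination geometry, not full
  residue atom graphs — sufficient because every quantity tested depends
  only on densities, charges and geometry. Passing tests therefore
  validate the machinery and its invariants, not agreement with any
  particular crystal structure.
- `brute_force_coulomb_oracle`: for spherical models, dense-log-grid
  cumulative-trapezoid shell integration with spherical averaging —
  sharing no code with the incomplete-gamma/quadrature production path;
  for aspherical models, direct double-grid point-pair summation
  (looser, used for sign and stability checks). Models are capped at 10
  atoms each.

## Problem sizes

The shipped test suite and the acceptance script run the full pipeline
on 80-atom toy complexes (8 protein residues × 3 RNA fragments) at the
Nrad = 99 / Nang = 590 production quadrature, with the three-variant
sequence comparison at a reduced 40/128 grid; these sizes exercise every
code path, including several hundred exact-integral pairs, in seconds
to a couple of minutes on one CPU. Full crystal structures (~500
residues) run through the identical code path; cost grows linearly in
the number of EP pairs (~50 ms per pair at default settings).

## Known limitations

- Atom typing is element + neighbor multiset, not full topological
  keys; transferability across subtle chemical environments (ring
  systems, hybridization) is correspondingly coarse.
- Single-ζ shell densities are a minimal basis; absolute penetration
  magnitudes are sensitive to the radial tails and should be read as
  qualitative with the fixture databank.
- No polarization, exchange-repulsion, dispersion, periodic boundary
  conditions, or forces.
- Protonation states and side-chain flips are taken from the input
  structure as-is; only X–H distances are adjusted.
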