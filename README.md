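# epmm

Aspherical pseudoatom electron densities and hybrid exact-potential /
multipole-moment (EPMM) electrostatics for macromolecular complexes,
with a per-residue binding-site analysis pipeline for protein–RNA
recognition sites.

## The problem

Electrostatics dominates how proteins recognize RNA: the triphosphate
(ppp) moiety at an uncapped RNA 5′ end carries −4 e, innate-immunity
receptors that sequester such pppRNA line their binding sites with
lysines and arginines, and a Mg²⁺ cation with its coordinating waters
mediates the contact. Point-charge force fields miss two things that
matter at these short ranges: the asphericity of atomic charge clouds
(lone pairs, bond density) and the *charge penetration* that appears
once the clouds of two molecules interlock. Full quantum-chemical
calculations are out of reach for a 400-residue complex.

`epmm` implements the middle road used in quantum crystallography:
each atom is a **Hansen–Coppens pseudoatom**,

```
ρ(r) = P_core ρ_core(r) + P_val κ³ ρ_val(κr) + Σ_l κ′³ R_l(κ′r) Σ_m P_lm d_lm(θ,φ)
```

with per-electron core/valence spherical densities from Slater-shell
wavefunction tables, density-normalized real spherical harmonics `d_lm`
(l ≤ 4), Slater radial functions `R_l`, and expansion–contraction
parameters κ, κ′. Parameters are *transferred* from a databank keyed by
chemical environment, fragment charges are rescaled to formal values,
and the intermolecular electrostatic energy is computed per atom pair:

- **EP** (exact potential): the full Coulomb integral of the two
  continuous charge distributions — analytic potentials via incomplete
  gamma functions integrated on atom-centered quadrature grids — for
  pairs closer than a critical radius (default 5 Å, Nrad = 99,
  Nang = 590);
- **MM**: a Buckingham-type spherical-tensor multipole expansion for
  everything else (and, as `E_MM`, for *all* pairs);
- **E_pen = E_EPMM − E_MM**: the penetration energy, the short-range
  stabilization that point multipoles cannot see.

On top of the engine sits the analysis pipeline: partition the first
three RNA residues into interaction fragments (fragment 1 = triphosphate
nucleotide + metal + its ≤ 3 coordinating waters), compute residue ×
fragment energy tables, and apply three binding-site filters (5 Å
distance, ±5 kcal/mol significance, penetration).

## Worked example

Everything below runs offline from packaged fixtures (a small databank
covering H, C, N, O, P, S, Mg and a seeded toy protein–RNA complex
generator — coarse chemical mimics with correct formal charges and
coordination geometry):

```bash
epmm make-fixtures work --seed 3
epmm transfer work/toy_complex.pdb work/databank.txt \
     --charges work/charges.yaml -o work/model.json
epmm binding-site work/model.json work/model.extended.pdb -o work/out
```

which prints (numbers from this exact run):

```
transferred 80 atoms (total charge -3.0000 e); model -> work/model.json, ...
within 5.0 A: 2 residues; significant (|Ees| > 5.0): 5; strong penetration (|Epen| >= 2.0): 0
binding-site E_EPMM totals (kcal/mol): fragment1=-268.0, fragment2=-85.2, fragment3=-47.7
```

Reading this: the transferred model hits the summed formal charge of the
fragment plan exactly (−3 e); two residues have atoms within 5 Å of the
RNA fragments; five interact with |E| above 5 kcal/mol with at least one
fragment (long-range Coulomb interactions reach well past the distance
filter); the ammonium-bearing residue closest to the triphosphate
dominates the fragment-1 total. `work/out/energies.csv` holds the
residue × fragment `e_mm`/`e_epmm`/`e_pen` table and
`work/out/manifest.json` the quadrature settings and constants used.

The same works in Python:

```python
from epmm import (QuadratureSpec, make_fixture_databank, make_toy_complex,
                  partition_fragments, residue_energy_table,
                  scale_fragment_charges, transfer_parameters)

structure, plan = make_toy_complex()
model, extended = transfer_parameters(structure, make_fixture_databank())
scaled = scale_fragment_charges(model, extended, plan)
report = residue_energy_table(scaled, extended, partition_fragments(extended),
                              QuadratureSpec(n_radial=99, n_angular=590, rcrit=5.0))
print(report.binding_site_totals())
```

For real structures, pass any protonated PDB file (the transfer step
extends X–H bonds to neutron distances and handles the Mg covalent-radius
override for coordination chemistry) together with a YAML fragment
charge plan in the `charges.yaml` format that `make-fixtures` writes.
Electrostatic-potential maps on cubic grids (Gaussian cube output, with
iso-density masking) are available via `epmm map`.

## Layout

| module | contents |
| --- | --- |
| `epmm.density` | pseudoatom parameters, density evaluation, multipole moments |
| `epmm.harmonics` | real spherical harmonics, density normalization, rotations |
| `epmm.wavefunctions` | Slater-shell core/valence density tables |
| `epmm.databank` / `epmm.transfer` | databank format, atom typing, H extension, charge scaling |
| `epmm.energy` / `epmm.grids` | EP, MM, EPMM, penetration, point-charge energies; quadrature |
| `epmm.pipeline` | fragment partition, binding-site filters, reports, comparisons |
| `epmm.maps` | ESP/density cubic grids, iso-density masks, cube files |
| `epmm.synthetic` | fixture databank, analytic dimers, toy complexes, oracles |
| `epmm.cli` | `epmm` command-line interface |

See `docs/methods.md` for the model, conventions, numerical choices and
limitations.
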