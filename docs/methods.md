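# Methods

## Model

The protocol treats binding as an ensemble property. For a two-partner
complex, three conformational ensembles are defined — the bound complex and
each unbound partner — over the same coordinates: mutable residues are
flexible (discrete side-chain rotamers), everything else is rigid. Each
ensemble's partition function `Z = Σ_c exp(−E_c/RT)` is combined into

    Log10 K* = log10 Z_complex − log10 Z_A − log10 Z_B,

an ensemble approximation to binding affinity. A mutation's effect is the
difference ΔK* between mutant and wildtype scores *from the same run*, so
systematic offsets (template energies, rigid-body terms) cancel. Only the
classification — does the mutation disrupt binding, and how likely is it to
arise — is meant to be accurate; absolute affinities are not.

Assumptions worth stating plainly: rigid backbone; discrete rotamers as a
stand-in for continuous side-chain flexibility (optional ±10° sub-sampling
per chi, off by default, narrows that gap); heavy atoms only, with no
explicit protonation beyond the three histidine variants; no unfolded-state
stability filter of any kind (matching the protocol setting this package
reproduces); DNA partners are always rigid and never mutated.

## Bounded partition functions

`partition_function_bounded` enumerates conformations best-first on
f = g + h, where g is the energy of the assigned positions (template +
singles + pairs) and h is an admissible completion bound: for every
unassigned position the minimum over its rotamers of (single + pairs to all
assigned rotamers), plus the minimum pair energy for every unassigned
position pair. Completed conformations accumulate the lower bound in
natural-log space (log-sum-exp); the upper bound adds
`remaining_count · exp(−f_min/RT)` with f_min the smallest f on the
frontier, which under-estimates every remaining conformation's energy
because h is admissible. Termination when `(upper − lower)/upper ≤ ε`
(checked as `log L − log U ≥ log(1 − ε)`). Consequences:

- the exact Z always lies in [lower, upper] (checked against exhaustive
  enumeration on hundreds of random toy spaces in the tests);
- the relative gap at termination is ≤ ε by construction;
- ties in f break on lexicographic rotamer indices, so enumeration is
  deterministic.

Defaults: ε = 0.03; T = 298.15 K (standard condition; the source protocol
leaves temperature unstated); R = 0.0019872 kcal/(mol·K).

Score combination uses the conservative corner of the brackets — complex
lower bound over unbound upper bounds — so disruption calls err toward
caution. How the reference implementation of K* combines its bounds
internally is not documented; this choice is ours. A complex whose lower
bound falls below log10 Z = −300 (the double-precision floor) is declared
COMPLETE_DISRUPTION ("X"): no finite ΔK* exists. The same condition on an
*unbound* partner is an error, since an unfolded partner is outside the
model. Log-space accumulation keeps every quantity finite for per-pair
energies anywhere in [−100, +1000] kcal/mol.

## Energy function

A pairwise-decomposable stand-in potential, not a calibrated force field:
Lennard-Jones 12-6 with Lorentz–Berthelot combining (tabulated rmin/2 and
well depth per element class) plus Coulomb with distance-dependent
dielectric ε(r) = 4r, heavy atoms only. Atom pairs closer than
0.6·(rmin_i/2 + rmin_j/2) contribute a flat +1000 kcal/mol, which keeps
Boltzmann weights well-defined (≈0) without infinities. Within a residue,
1-2 and 1-3 bonded pairs (including ring closures) are excluded;
inter-residue pairs always count. Partial charges and vdW parameters ship
as a plain-text per-residue table (`data/ff_params.tsv`) with separate
charge sets for the three histidine variants; the decomposition
E = template + Σ singles + Σ pairs is exact (tested to 1e-9 kcal/mol
against a direct all-atom sum). External energies can be injected through
a documented TSV energy-matrix format.

Side chains are rebuilt from idealised internal coordinates (canonical
bond lengths/angles, chi-driven dihedrals, approximate ring closure) on the
crystallographic backbone; the rotamer library is a small embedded
backbone-independent table (1 rotamer for Gly/Ala/Pro, 3 for everything
else). Wildtype side chains are rebuilt from the library too, so wildtype
and mutant are treated identically and wildtype self-ΔK* is exactly zero.

## Structure handling

PDB input is parsed with gemmi. Waters, hydrogens and chains outside the
two partner sets are dropped; alternate locations collapse to the highest
occupancy (ties by altloc letter); author numbering and insertion codes are
kept. The binding interface is defined as residues with any heavy atom
within 5.0 Å of the opposite partner (a common contact criterion; the
retention shell, not the contact cutoff, is what the source protocol
fixes), and the system is trimmed to residues within 12 Å of any interface
atom. Both distance boundaries are closed (≤) for determinism at exact
geometries.

## Mutation probabilities

Signatures are distributions over the 96 pyrimidine-centred trinucleotide
substitution classes; purine-centred contexts are folded onto the opposite
strand first. A cancer type's per-signature burden contributions are
renormalised to sum to 1 — only *relative* probabilities are meaningful.
One amino-acid mutation is scored by summing over every codon substitution
path of Hamming distance ≤ 2: single exchanges use the genomic flanking
context directly; double exchanges sum, over both substitution orders, the
product of the two step probabilities, the second step evaluated in the
context left by the first (so adjacent substitutions interact). This
order-symmetric product rule is our reconstruction of a formula the source
literature delegates to earlier work; it reduces to the single-step formula
when one step is certain. Context windows are computed on the raw coding
sequence (one flanking base per side), not per-codon, so codon-boundary
contexts are handled naturally. Mutations reachable only at Hamming
distance 3 are excluded outright (EXCLUDED_TRIPLE) and never carry a
number. A no-cancer-type mode skips the stage entirely and prioritisation
falls back to ΔK* order.

## Triage

"Change of Log10 K* scores > −3" is interpreted as a *decrease of more
than 3 log10 units*, i.e. disruptive iff ΔK* ≤ −3, boundary included —
consistent with every published validated value being ≤ −4.14. "X" is
always disruptive. Histidine mutations collapse to one verdict (all three
protonation states must disrupt, when the rule is enabled) but keep all
three values in outputs. Hotspots count *disruptive* calls per residue
position (the source text's "predicted individual mutations" is read as
post-filter), ranked descending with ties broken by ascending residue
number; prioritisation takes the disruptive mutations at the top-3
hotspots ordered by formation probability (or ΔK* without one). Lowering
the cutoff can only remove disruptive calls — a property the tests assert.

## Synthetic data

The toy dimer is two short facing chains whose closest heavy-atom
separation equals the recipe's `interface_gap` exactly, with side chains
(small residues only: Gly/Ala/Ser) pointing away from the interface, so
interface membership and trimming behaviour are known by construction and
unperturbed mutations barely move ΔK* (|ΔK*| ≲ 0.15 on the shipped
recipes). Engineered disruptive mutations are expressed as additive
complex-energy offsets injected at the energy-matrix stage (+8 kcal/mol
lowers Log10 K* by 8/(RT·ln10) ≈ 5.9 units at 298.15 K), making ground
truth exact rather than emergent from the toy physics. Default recipe:
3 residues per partner, 4 Å gap. What the fixtures deliberately do *not*
emulate: realistic protein geometry, packed interfaces, charged networks,
crystallographic artefacts — so passing tests demonstrate the protocol's
logic (bounds, rules, bookkeeping, determinism), not force-field accuracy
on real complexes. Toy genes are random stop-free coding sequences; toy
catalogs are uniform (1/96 everywhere, giving closed-form oracles) or
row-normalised random.

## Scan orchestration and determinism

Per mutation (histidine expanded to three variants): build the three
conformation spaces, compute energy matrices, bounded partition functions,
K*, ΔK* against the per-site wildtype from the same run, then triage; the
probability stage runs iff a cancer type is set. Per-mutation failures are
logged and skipped; a wildtype failure aborts. "Investigated alone or in
pairs" is implemented as single-site scans plus an optional pair mode in
which both listed sites are flexible in every evaluation while mutations
are still enumerated one at a time — batched flexibility rather than
double-mutant enumeration, which keeps the calls-table row count equal to
the allowed-mutation count. Outputs are CSV with fixed formatting and a
provenance header (config hash, seed, ε, temperature, cutoff); reruns at
the same seed are byte-identical.

Problem sizes used throughout the examples and checks — toy spaces up to
4 positions × 4 rotamers (256 conformations), dimers of 3 + 3 residues,
genes of ≤ 12 codons — were chosen so every oracle (exhaustive
enumeration, direct all-atom sums, hand-computed Boltzmann sums) stays
exact and instantaneous; the algorithms themselves carry no such limits
beyond the exhaustive estimator's explicit conformation cap.

## Known limitations

- The stand-in potential has no solvation, polarisation or minimisation;
  absolute K* values are physically meaningless — only differences and
  classifications are used, and only on synthetic systems are they tested.
- Rigid backbone and small rotamer library understate mutant relaxation,
  biasing toward disruption for large substitutions.
- Hotspot bookkeeping keys on residue number only; scans mixing mutable
  sites with identical numbers on *both* chains would pool them.
- No double-mutant enumeration; no >2-site designs; no DNA mutations.
- The probability stage assumes the supplied coding sequence matches the
  scanned chain's numbering (`gene_offset` shifts it by a constant).
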