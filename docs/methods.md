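# Methods

## Scope and model

The package implements the computational stages of a scaffold-selection
procedure: filtering structure candidates, scoring residues for evolutionary
conservation and energetic mutability, detecting spatially contiguous mutable
surface patches, designing NNK randomization libraries over a patch, and
verifying fold retention of evolved variants by Cα superposition. Wet-lab
stages (expression, biophysics, display rounds, crystallography) are out of
scope; their inputs and outputs appear here only as file formats.

## Candidate filter

A candidate passes when all computable rules hold: molecular weight within
[10, 25] kDa (inclusive; average residue masses, ExPASy table, plus one
water), X-ray resolution strictly below 3.0 Å, exactly one polymer chain
with ≥ 50 residues, and at most 2 cysteines (configurable). A structure with
no recorded resolution fails with the distinct label `resolution_unknown`
rather than passing silently. Non-computable curation rules (toxicity,
immunogenicity, literature solubility, fold novelty) are carried as free-text
notes in the criteria object — they require human judgment. Biological
assemblies are not expanded; the monomer rule looks at the coordinate file
as deposited, since oligomeric state curation is a manual step.

## Solvent accessibility

Shrake–Rupley numerical SASA: each atom's sphere of radius `vdW + probe`
(probe 1.4 Å) is sampled at `n_points` (default 960) positions from a
golden-spiral lattice; points outside every neighbour sphere are accessible.
The lattice is a fixed deterministic construction — no RNG — so SASA values
are bit-stable across runs and platforms. Van der Waals radii: C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20, P 1.80, Se 1.90 Å; unknown elements fall
back to 1.70 Å with a warning. Hydrogens are skipped by default (most X-ray
entries lack them); a flag includes them. Relative SASA divides the
per-residue sum by the theoretical maximum per residue type (Tien et al.
2013); a residue is *surface* at relative SASA ≥ 0.25. The 0.25 threshold
is this package's choice — "surface residue" has no universal quantitative
definition — and is exposed in the config; unknown residue types use the
table mean with a warning.

## Conservation

The statistic is identity-to-reference, not column entropy: the selection
gate is phrased as an identity percentage, so for each alignment column where
the reference (scaffold) sequence has a residue, conservation = 100 × (number
of records carrying the reference's residue) / (number of records). The
denominator includes the reference itself and gap-containing records; gaps
and 'X' count as mismatches ('X' matches nothing, including itself). Columns
where the reference is gapped produce no entry. Duplicate aligned sequences
are removed first (first occurrence kept; the reference always survives).
Homolog search and alignment construction are inputs, not package features.

Mapping onto a structure uses Needleman–Wunsch global alignment (BLOSUM62,
gap open −11, extend −1, via Biopython's PairwiseAligner); conservation flows
through aligned pairs, unaligned structure residues stay unscored, and an
alignment identity below 50 % aborts with a mapping error since it almost
certainly means the MSA belongs to a different protein.

## Mutability

A position's ΔΔG row holds the predicted folding free-energy change for all
20 substitutions, self included at exactly 0. The mutability score is the
percentage of the 20 values strictly below the tolerance threshold
(default 0.5 kcal/mol): stabilizing (< 0) and slightly destabilizing
(< 0.5) substitutions are a single criterion because the first is subsumed
by the second. Self counts in both numerator and denominator, so scores are
multiples of 5 in [0, 100]. A residue is *mutable* when conservation < 90 %
**and** mutability > 50 % (both strict) and it is on the surface.

"Positionscan" TSV files are the normal ΔΔG source
(`<wt><chain><num>\t<mutant>\t<ddG>` rows, or the two-column
`<wt><chain><num><mutant>\t<ddG>` variant); the reader demands all 20
mutants per position, resolves duplicates last-wins with a warning, and
warns when |self ΔΔG| > 0.01 kcal/mol. Files are expected pre-averaged
over any replicate runs. Re-implementing a force field is a non-goal; for
pipeline testing without external software a **surrogate** model is provided:
ΔΔG(i→a) = λ · (1 − min(rSASA_i, 1)) · Grantham(wt_i, a)/100. It has the
right qualitative shape (buried positions and chemically distant
substitutions are penalized; fully exposed residues tolerate everything) but
is *not* a stability predictor; its output carries `source="surrogate"` so
downstream reports can never confuse it with force-field results.

## Patches

Mutable residues become nodes of a contact graph with an edge when the
Euclidean distance between representative atoms (Cβ; Cα for glycine) is
≤ 8 Å. "Structurally close" has no published number in this procedure, so
8 Å — a conventional side-chain contact cutoff — is the default and a CLI
flag. Patches are the connected components, ranked by size, then mean
mutability, then smallest residue number; sequence span is reported and used
only in ranking, since sequential compactness was preferred but never
required. A patch below the 10-residue target is completed greedily: among
surface residues within the cutoff of any member, add the one with the
highest mutability (ties: lower conservation, then lower residue number),
re-evaluating candidates after each addition; if candidates run out the
patch is flagged `undersized`. Patches above 12 residues are flagged
`oversized` but never truncated — shrinking a patch is a user decision.
Pairwise patch independence reports both disjointness and the minimum
inter-patch distance, calling a pair independent when disjoint and separated
by more than the contact cutoff; both facts are reported because
"independent patches" could reasonably mean either.

## Library design

NNK expansion and diversity use exact integer arithmetic (`Fraction` for the
stop-free probability): DNA diversity is the product of expansion sizes,
protein diversity the product of per-position distinct amino-acid counts,
counting stop-free sequences only — a clone with an amber codon is not a
displayable library member. (With 10 NNK positions the bound is comfortably
met either way: 20¹⁰ ≈ 1.02 × 10¹³ stop-free vs 21¹⁰-style counts.)
Back-translation uses a most-frequent-codon table for E. coli class II
genes, overridable since synthesized constructs are vendor-optimized. The
cassette layout fixes the element order (T7 promoter, 5′ stem-loop, RBS,
ATG + Strep-tag II, scaffold ORF, c-Myc tag, TolA spacer, 3′ stem-loop) and
validates that the wild-type ORF translates without internal stops and that
the cassette ends without a stop codon, as ribosome display requires. The
shipped element sequences are representative public parts, not any
proprietary construct; real designs supply their own via `CassetteConfig`
(including raw-DNA overrides for the coding elements). Synthesis fidelity is
modelled only as an optional per-position error rate in `sample_variants`
(default 0).

## Superposition

Residues are paired by global sequence alignment by default — evolved
variants carry substitutions, and numbering-based matching can silently
misalign renumbered files; `by_number` is available when numbering is
trusted. The rigid transform is the Kabsch SVD construction with the
reflection correction (determinant sign fixed on the smallest singular
vector), so the rotation is always proper, including for mirror-image
inputs. No outlier trimming is applied by default: the reported RMSD is over
the full common Cα set, and `n_atoms` is reported so a discrepancy with a
published value computed on a different atom selection can be diagnosed.
Near-collinear point sets raise a degeneracy error rather than returning an
arbitrary rotation. In tests the implementation is checked against an
independent quaternion (Horn eigenvalue) formulation to 1 × 10⁻⁶ Å.

## Synthetic data

The generator plants known ground truth rather than imitating real proteins:

* **Structure** — an ideal helical Cα trace (rise 1.5 Å, radius 2.3 Å,
  100°/residue; consecutive Cα distance √(1.5² + 2·2.3²(1 − cos 100°)) ≈
  3.83 Å) with pseudo-Cβ 1.5 Å radially outward. Every residue of a bare
  helix is solvent-exposed, deliberately: surface logic runs, while
  mutability ground truth is planted elsewhere.
* **MSA** — each non-reference record mutates column *j* independently with
  probability *p_j* to a uniformly chosen different residue, so expected
  conservation is 100(1 − p·(n−1)/n) → 100(1 − p). Defaults: 50 records,
  p = 0.5 on planted columns and 0 elsewhere, cleanly splitting the
  < 90 % gate.
* **ΔΔG** — planted positions draw 14–20 of 20 values below 0.5 kcal/mol
  (score ≥ 70 %), background positions at most 8 (score ≤ 40 %), self
  always 0, enforced by construction so recovery is deterministic given the
  thresholds.

All randomness flows through one explicitly passed seeded generator; no
global RNG state. What passing recovery tests shows: the thresholds, graph
construction and greedy completion interlock correctly. What it does not
show: behaviour on real packing, partial burial, correlated MSA columns, or
force-field noise — those require real positionscan data and structures.

## Numerical and degenerate-input choices

* SASA at 960 points is within 1 % of the isolated-sphere closed form;
  point counts below 24 are rejected.
* Altloc resolution: highest occupancy, ties to file order. Waters/ligands
  are inventoried, never silently dropped.
* An empty mutable set yields an empty patch list (not an error); a single
  patch makes the independence report an error (nothing to compare).
* B-factor annotation clips scores to [0, 999.99] with a warning to keep
  the fixed-width PDB column valid.
* Pipeline outputs are pure functions of inputs + config; re-runs are
  byte-identical (the run log records paths and parameters, so it differs
  across output directories by construction).

## Problem sizes

Tests and the acceptance script run on 60-residue synthetic scaffolds,
50–500-record alignments, 20 recovery seeds, 200 random graphs (≤ 8 nodes),
1000 random ΔΔG vectors and 50-point clouds — sizes at which every oracle
(enumeration, closed form, exhaustive greedy trace) is exact and the whole
suite completes in seconds.

## Known limitations

* The surrogate ΔΔG model is for plumbing tests only; conclusions about a
  real scaffold require force-field positionscan input.
* Conservation is identity-to-reference with the reference in the
  denominator; other reasonable definitions (entropy, reference-excluded
  denominators) give different numbers. The choice is configurable and
  prominently documented because the gate value (90 %) interacts with it.
* No geodesic surface distances or patch-shape scoring; contact distance is
  Euclidean between representative atoms.
* No biological-assembly expansion, hydrogen placement or structure quality
  validation.
* The real-structure fold-retention check (PDB 4PSF vs 7AVC) needs the two
  entries downloaded; everything else is network-free.
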