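# Methods

This note documents the model behind `waterloan`, the parameters that
matter, the numerical choices, what the synthetic fixtures do and do not
emulate, and the known limitations.

## The transfer model and its assumptions

The central assumption is structural conservation of internal hydration:
if two homologous proteins superpose well locally, a buried water observed
in one is a good candidate position in the other. The method therefore
never scores water energetics; it only (i) curates which template waters
are trustworthy, (ii) decides which templates to trust more, and
(iii) checks geometric compatibility of each transferred water with the
query. This works best in families with many high-resolution structures
and breaks down for proteins whose nearest homolog is remote or whose
hydration sites are not conserved.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| B-factor cutoff | 45 (strictly greater discarded) | Å² | drop disordered template waters |
| CV radius | 10 | Å | neighbourhood for circular variance |
| CV threshold | 0.6 (internal ⇔ CV ≥ 0.6) | — | internal/external split |
| bit-score threshold | 0 (user-set; 300 ≈ close homologs) | bits | template admission |
| local-fit radius | 10 | Å | residues fitted around each water |
| local RMSD gate | 2.0 | Å | reject waters in distorted regions |
| clash cutoff | 2.4 (strict <) | Å | water vs protein/water/ion spacing |
| Na⁺ water exclusion | 2.1 | Å | sodium site must be water-free |
| Na⁺ protein exclusion | 1.8 | Å | sodium site must have clearance |
| recovery cutoff | 2.0 (strict <) | Å | benchmark match radius |

Alignment uses BLOSUM62 with BLAST-convention affine gaps (a length-k gap
costs 11 + k) and the gapped Karlin–Altschul constants λ = 0.267,
K = 0.041, so bit scores land on the blastp scale that users of sequence
search tools already calibrate thresholds against.

## Ordering and tie-breaking

Templates: state match first (when the query state is known and state
priority is on — the default; a flag demotes state to a tie-break), then
bit score descending, resolution ascending, and finally (entry id, chain)
lexicographically, which makes the ranking a total order and the whole
pipeline deterministic. Within a template, waters are assessed in
ascending source B-factor (most-ordered first); equal B-factors keep
source record order. The sodium ion, when requested, is placed *before*
any water, from the template with the highest percent identity (ties →
best resolution); waters placed afterwards must clear the ion at the
ordinary 2.4 Å cutoff.

## Geometry

Superposition is the closed-form Kabsch solution (SVD with determinant
correction, so the rotation is always proper even for near-reflective
point sets). The global fit runs on corresponded Cα atoms with iterative
outlier rejection: residuals above 2 σ are dropped and the fit repeated,
at most 5 cycles. The local fit uses backbone atoms (N, Cα, C, O) only —
side chains differ between homologs — of corresponded residues that have
any stored atom within 10 Å of the water oxygen in the template frame,
and requires at least three residue pairs. A kept water is mapped by the
**local** transform (the refinement is meant to correct the position, not
merely to gate it); falling back to the global transform when the local
fit is infeasible was deliberately rejected as unsafe, so such waters are
simply rejected.

Point sets whose second singular value is below 1e-8 of the first
(collinear) are refused; fits need ≥ 3 pairs. Distance comparisons at the
cutoffs are strict (`< cutoff` clashes, `= cutoff` does not; a recovered
water must be `< 2 Å` away). All coordinates are Å; author residue
numbering is preserved throughout.

## Design choices that were genuinely open

- **Circular-variance neighbour set**: protein heavy atoms only, no
  weighting. Burial is measured relative to the protein matrix; unit
  vectors keep the statistic scale-free. A water with no neighbours
  within the radius gets CV = 0 (maximally exposed) with a warning.
- **Sodium rule read as a conjunction**: the site must have *no water
  within 2.1 Å and no protein atom within 1.8 Å*. The disjunctive reading
  would almost never allow placement.
- **Water ownership after chain stripping**: a water (or monatomic ion)
  survives curation if its oxygen is nearer to a kept-chain atom than to
  any removed atom. Ions are kept through stripping because the curated
  sodium is part of what the method transfers.
- **Greedy recovery matching**: pairs are accepted in ascending distance,
  one-to-one. Tests compare it against a permutation-exhaustive optimum
  on small instances; no discrepancy has been observed at the benchmark
  sizes.
- **Leave-one-out granularity**: the *entire* test entry id (all chains)
  is removed from the database, which is stricter than removing only its
  waters and prevents self-template leakage through identical coordinates.
- **Alternate locations**: highest occupancy wins, ties go to altloc A.
  Hydrogens are ignored; waters are represented by their oxygen, since
  every distance in the method is measured to the water oxygen.

## The synthetic fixtures

`synth_fixtures` generates parallel ideal α-helical bundles (rise 1.5 Å,
100°/residue, backbone N/Cα/C/O at idealised helix offsets) arranged on a
circle around a central pore; waters are planted on the pore axis
(internal) and outside the bundle surface (external), and families are
derived from a common ancestor by substituting a fixed pool of sequence
positions (so members sit at the target identity both to the ancestor and
roughly pairwise), jittering backbones by a configurable σ (0.3 Å in the
benchmark family), and applying per-member random rigid motions. The
generator re-draws a water's jitter until the emitted structure keeps a
safety margin around the classifier thresholds (CV ≥ 0.7 for internal,
≤ 0.5 for external), so label/classifier agreement is a property of every
emitted fixture, not a statistical accident. Everything derives from one
integer seed and is byte-reproducible.

The benchmark family used by the tests and the acceptance script is six
members of a 7×36-residue bundle at 90 % identity with 0.3 Å jitter and
eight conserved pore waters — small enough that the full suite runs in
seconds on one CPU, large enough that alignment, ranking, both fits and
the clash filter all do real work.

What the fixtures do **not** emulate: side chains (fits are backbone-only
by design, but clash checking against a real query would also see side
chains), ligands, crystallographic noise models (B-factors are uniform
draws, uncorrelated with position), non-conserved hydration-site turnover,
membrane context, and sequence divergence beyond point substitutions
(no indels, so alignments on fixtures are gap-free). Passing tests
demonstrate the machinery is correct and self-consistent under controlled
conditions; they do not certify recovery rates on real crystallographic
families, where template availability and true structural divergence
dominate.

## Known limitations

- Correspondence comes from the sequence alignment; structurally
  equivalent but sequence-divergent regions can be missed (no
  sequence-independent structural alignment).
- One query chain is hydrated at a time; inter-chain interfaces are seen
  only as clash space.
- mmCIF input, hydrogen placement and energy scoring of placed waters are
  out of scope; external predictions are merged geometrically only.
- Bit scores use fixed Karlin–Altschul constants rather than per-search
  estimation; for very short or compositionally biased sequences the
  scale drifts from blastp's.
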