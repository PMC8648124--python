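# Methods

This note documents the models and procedures implemented in `sitematch`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic-fixture tests do and do not demonstrate.

## Data model and normalisation

Structures are parsed from PDB files (via gemmi) into a plain
atom/residue/chain model.  Normalisation rules, applied on input:

- hydrogens are dropped; every threshold in the package operates on heavy
  atoms only;
- alternate locations are resolved to the highest-occupancy conformer, so
  a site is a single rigid conformation;
- waters are never ligands; ligands are non-polymer, non-water HETATM
  groups;
- author residue numbering (gaps, insertion codes) is discarded and
  residues are renumbered 1…n per chain.  All primary-sequence distances
  use this sequential index, which is what makes "three consecutive
  residues have mean pairwise distance 4/3 ≈ 1.33" an identity.

Residues missing any of N, Cα, C are flagged non-matchable but do not
abort parsing.  Every residue exposes a Cβ: the real atom when present,
otherwise an ideal Cβ constructed from N, Cα, C at 1.52 Å from Cα with
L-amino-acid chirality (needed for glycine in both the cosine gate and
the burial cone).  The construction is SE(3)-equivariant and is verified
in tests against an independent internal-coordinate placement (bond
1.521 Å, angle C–Cα–Cβ 110.1°, improper N–C–Cα–Cβ −122.55°), which agrees
to ~0.001 Å.

## Interaction scoring

Site residues are selected by the sign of a pairwise residue–ligand
interaction score.  Full force-field two-body energies are outside this
package's scope, so the default scorer is a transparent proxy with three
favourable terms:

- **attraction** — a 6-12 Lennard-Jones well over heavy-atom pairs within
  6 Å (well depth 0.5 energy units; minimum at the sum of per-element
  radii), with each pair's energy capped at zero.  The positive overlap
  part is accumulated separately as **repulsion**, which is *not* part of
  the total; it feeds only the clash-quality filter (residues with
  repulsion above the quality cutoff are considered poorly modelled and
  excluded, mirroring the "total score too high" exclusion a force field
  would provide).
- **electrostatics** — Coulomb energy with distance-dependent dielectric
  ε(d) = 10·d over assigned formal charges (carboxylates −0.5 per oxygen,
  Lys +1, Arg/His fractional, common ions by element).
- **hydrogen bonds** — a distance-ramped bonus (−1.0 at 2.6–3.2 Å, zero
  outside 2.5–3.4 Å) between donor and acceptor heavy atoms, gated on the
  partner sitting on the exposed side of the residue atom (> 90° from its
  covalent neighbour).

All terms depend only on interatomic distances and internal angles, so
scores are exactly invariant under a joint rigid transform of residue and
ligand.  The scorer is pluggable (`sitematch.scoring.SCORERS`); a
force-field-backed scorer can be registered without touching extraction.
Because this scale is not Rosetta energy units, the inclusion threshold
(default −1.0) and quality cutoff (default 50) are configuration, not
constants; library membership on real PDB input will not numerically
reproduce counts obtained with a full force field, and no claim of that
kind is made.

## Site-library construction

Per structure, for each ligand: resolution must be better than the cutoff
(default 2 Å; structures without a resolution record are skipped with a
warning — synthetic fixtures carry a nominal 1.5 Å), ligand heavy-atom
count in [1, 100], mean ligand B-factor ≤ 60 Å².  Candidate residues are
those with ≥ 1 heavy atom within 5 Å of any ligand heavy atom; a residue
joins the site if its total score is below the inclusion threshold and it
passes completeness (no missing heavy atoms for its type) and quality
checks.  Sites with fewer than 2 residues are dropped.  One site per
distinct ligand per structure: duplicates arising from identical chains in
an asymmetric unit are collapsed by a (ligand name, residue-type multiset)
key — a deliberate composition key rather than sequence clustering, since
only within-structure copies are at issue.

Reduction to k-residue sites (`select_top_k`, default workflow k = 3)
keeps the k residues with lowest total score, ties broken by (score,
sequence index); sites with fewer than k residues are rejected, sites with
exactly k pass through unchanged.  Multi-chain sites are allowed in
matching but raise an explicit error in sequence-distance statistics,
where the quantity is undefined.

## The fast-match protocol

The site is one rigid unit.  For every (site residue, scaffold residue)
anchor pair: 3-point least-squares superposition of the anchor N, Cα, C
(interpreted as least-squares, not a triad frame, consistent with the
protocol's later explicit least-squares step); nearest scaffold residue
per site residue by Cα–Cα distance (ties to the lower sequence index;
implemented exhaustively — a spatial index would be an optimisation, not a
semantic change); then the gates in order: all Cα distances ≤ 2 Å and the
correspondence injective (two site residues may not be designed onto one
scaffold position); full-backbone superposition RMSD ≤ 1 Å, and the
refined placement is what later gates see; every Cα→Cβ cosine > 0.7;
clash-free at 0.6 × Lennard-Jones radius sums.

Clash geometry: the mobile set is the ligand plus site side-chain heavy
atoms (everything outside N, Cα, C, O — Cβ counts as side chain); the
static set is backbone N, Cα, C, O of scaffold residues *not* in the
correspondence.  Scaffold Cβ is excluded because scaffold side chains are
designable.  Default radii (Å): C 2.0, N 1.75, O 1.55, S 1.9, P 2.1,
halogens at standard van der Waals values, metals at ionic radii; the
table is configurable and an unknown element is a configuration error
naming the element.

All anchors are enumerated and accepted placements deduplicated by
correspondence (keeping lowest RMSD); an early-exit exists only at the
library level (`stop_at_first`), where scaffolds after a site's first
success are recorded as untested.  Scaffold iteration order is shuffled by
an explicit seed and recorded, since first-encounter numbers depend on the
order and the package makes that dependence reproducible rather than
hiding it.

Superposition is Kabsch via SVD of the cross-covariance with a reflection
guard (determinant correction), and the RMSD is computed from the actual
residuals rather than the trace identity, which loses ~7 digits to
cancellation for near-exact fits.  Collinear point sets raise a
degenerate-geometry error (the rotation about the line is undefined);
N/Cα/C triples are never collinear.

## Constraint-file writer

For consumption by an external matcher, each site residue yields one
constraint block over six anchor atoms: on the ligand side the heavy atom
closest to the residue plus the two ligand atoms closest to it; the mirror
rule on the residue side.  The distance between the two first atoms is
constrained at its observed value with no periodic sampling; the two
angles and three torsions are constrained at observed values with a 10°
tolerance and one periodic sample step, i.e. sampling at the ideal value
and ±10°.  Ligands with fewer than three heavy atoms cannot define the
frame and are rejected explicitly.  The output is byte-deterministic and
covered by a golden-file test.

## Burial layers, depth score, secondary structure

The weighted neighbour count of residue i sums, over all other residues j,

    w(d, θ) = 1 / (1 + exp(d − 9)) · ((cos θ + 0.5) / 1.5)²

with d the Cα(i)–Cα(j) distance in Å and θ the angle between Cα(i)→Cβ(i)
and Cα(i)→Cα(j); the angle factor is clamped to zero when cos θ ≤ −0.5.
w(9, 0) = 0.5 exactly.  Counts below 2 are surface, above 5.2 core,
otherwise boundary; the thresholds are configuration with those defaults.
The neighbour point is the neighbour's Cα (not Cβ), keeping the measure
side-chain independent.  Only the two printed factors are implemented; no
further cone-shape constants are assumed.

The depth score of a matched site is n_boundary + 2·n_core over the
layers of its *matched scaffold positions* (range 0–6 for 3-residue
sites); it is invariant to residue order and to rigid motions of the
scaffold.

Secondary structure is a deliberately simple dihedral-window 3-state
assigner (helix: φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]; strand:
φ ∈ [−180°, −80°], ψ ∈ [90°, 180°]; else loop; termini loop).  It is
*not* a hydrogen-bond-based assignment and will disagree with DSSP on
irregular real structures; it exists for descriptive summaries of
idealised backbones, where it is exact.

## Ligand clustering

Ligands are encoded as 1024-bit fingerprints and clustered by the Butina
leader algorithm at Tanimoto distance (1 − |a∧b|/|a∨b|; two empty
fingerprints are at distance 0 by convention) with cutoff 0.65.
Neighbour lists are computed once; candidates are ranked by neighbour
count descending with ties broken by ligand id (the published procedure
leaves ties open); leaders absorb their unassigned neighbours, so every
member lies within the cutoff of its centroid by construction.

The default fingerprint backend is an in-repo rotation-invariant 3D
shell-hashing scheme: for each atom and each shell radius (1.5–8 Å), the
sorted multiset of (element, 0.5 Å-binned distance) pairs within the
shell is hashed to one of the 1024 bits.  It is deterministic for a fixed
conformer and exactly rotation invariant.  It is not E3FP; the backend
registry accepts an E3FP-compatible implementation where one is
available, and everything downstream (distance, clustering, cutoff) is
fingerprint-agnostic.

## Match statistics

The `MatchMatrix` stores per-cell outcomes (matched / tested-no-match /
untested), the recorded test order, per-site first-encounter numbers, and
optionally post-confirmation outcomes, which may only turn matches off.
Derived statistics:

- **encounter curve** — sites with first-encounter number ≤ N; its
  endpoint equals the row-wise any() count.
- **power-law fit** — ordinary least squares on (log₁₀ N, log₁₀ count),
  chosen over MLE because the quantity of interest is the slope of the
  log–log plot; exact power-law inputs are recovered to 10⁻⁹ with r² = 1,
  and the fit is scale-equivariant (rescaling counts shifts the intercept
  only).  Extrapolation evaluates the fitted line.
- **overlap test** — expected co-matches under independence n_a·n_b/N and
  a 2×2 chi-squared with 1 df, no continuity correction (a goodness-of-fit
  variant would differ negligibly at any interesting N); degenerate
  margins return χ² = 0, p = 1 rather than failing.
- **subset resampling** — without replacement within a rep, independent
  reps, mandatory seed; requires a fully tested matrix and errors
  otherwise rather than silently treating untested cells as misses.
- **enrichment ratios** — site amino-acid frequencies over background,
  with zero background an error naming the amino acid.

## Synthetic fixtures

Generators build ideal poly-alanine backbones by NeRF chain extension
(bond lengths/angles at Engh–Huber values; helix φ/ψ = −57°/−47°, strand
−120°/120°; a two-helix bundle packs two helices antiparallel at 10 Å
with a chain break).  `plant_site` copies chosen residues and places a
pseudo-carbon ligand so every chosen residue has a ligand atom within
5 Å (extraction-compatible) at ≥ 3.3 Å clearance from site atoms and
≥ 3 Å from all other backbone atoms (clash-free by a safe margin); a
coverage-infeasible request — e.g. one atom spanning three distant
residues — raises a placement error rather than degrading.  `perturb`
adds seeded isotropic Gaussian noise; `make_match_matrix` draws Bernoulli
outcome tables with consistent encounter numbers.  All generators are
deterministic per seed; suite seeds are fixed in the tests.

What the fixtures do *not* emulate: real side chains beyond Cβ, rotamer
libraries, chemically realistic ligands, crystallographic artefacts, or
designability of the backbones.  Consequently the tests demonstrate the
correctness of the algorithms (gates at their exact thresholds, exact
self-match recovery, invariances) — not the biological match rates of
real fold families.

## The bundled analysis script

`scripts/acceptance.py` runs the whole pipeline at a fixed problem size
chosen to keep the run under a minute on one CPU while leaving every
statistic well determined: a 24-member two-topology family, a 30-site
planted library, 50 self-match fixtures, 100 resampling reps.  Family
members are generated with 0.45 Å per-coordinate jitter, which yields
pairwise local backbone RMSDs around 1 Å — the scale of variation real
fold-family members show — so sites match some but not all members and
the encounter-curve and overlap statistics are non-degenerate.  All
randomness derives from the single `--seed` argument.

## Known limitations

- The proxy scorer ranks contacts sensibly but its absolute scale is not
  a calibrated energy; thresholds carried over from force-field scales
  are defaults to be tuned per scorer.
- The secondary-structure assigner is not DSSP.
- Multi-model (NMR) PDB input uses the first model only; mmCIF and
  nucleic-acid scaffolds are unsupported.
- Matching uses the site's original side-chain conformation as a rigid
  body; placements reachable only through alternative rotamers are
  invisible to the screen, which is the price of its speed.
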