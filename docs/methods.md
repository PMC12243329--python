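# Methods

## Scope and model

residueflow estimates how much of a bio-based product could be made from a
national portfolio of biogenic residues.  The procedure is a deterministic
material-flow calculation, not a process simulation: no kinetics, titers,
reactor sizing, energy balances or costs are modelled, and pollutant or
inhibitor loads are out of scope.

The pipeline is: relevance cutoff → composition screening → mass pooling →
conversion cascade → market and land-use contextualisation.

**Cutoff.**  Residues below a technical-potential cutoff (default
250,000 Mg DM a⁻¹ for a from-scratch national inventory) are excluded as
irrelevant.  The bundled reference matrix is already cutoff-filtered, so
the packaged default configuration sets the cutoff to 0; one residue in it
(oil waste, 156,000 Mg DM a⁻¹) sits below the generic cutoff but is
retained by the underlying survey, and re-applying the generic cutoff to
that matrix would drop it.

**Screening.**  A process targets one of the seven composition fractions.
Residues enter the *favorable* tier when their mean fraction meets the
favorable threshold and the *possible* tier when they only meet the
relaxed threshold.  Defaults: lignin ≥ 0.23 favorable / ≥ 0.20 possible;
NFC ≥ 0.20 / ≥ 0.16; oil/glycerol > 0.90 with no possible tier (strict
comparison).  The split thresholds reproduce the published tier
memberships (eight lignin-favorable residues with green waste and leaves
as possible; cattle solid manure and roadside stalks as the NFC possible
tier); all thresholds and comparisons are configuration, not code.
Residues lacking a mean value for the target fraction are ineligible and
logged.  Because oil waste (0.91) and biodiesel glycerol (0.95) both store
their relevant content under fats/oils, the two TCA-intermediate chains
are configured as separate processes restricted to the respective residue
ids.

**Pooling.**  raw pool = Σ technical potential × usable share; fraction
pool additionally weights by the mean fraction.  The usable share defaults
to 1.0 and is 0.8 for residues from starch production (potato-pulp share).

**Conversion cascades.**  Each chain is an ordered list of steps with
dimensionless mass-per-mass factors.  The adipic-acid chain applies its
first factor (0.59, lignin recovery in decomposition) to the *lignin
fraction pool*, not to the raw residue mass — this basis reproduces the
published product potential (7.8 Mt × 0.59 × 0.35 × 0.68 × 0.61 ≈ 668 kt
against the published 665 kt, a 3-significant-figure rounding difference).
The idealized scenario replaces only the three factors with prospected
improvements (depolymerization 0.35→0.50, electrochemical 0.68→0.85,
microbial 0.61→0.99); other steps are unchanged.  Factors above 1 (citric
acid 1.32 and 1.03) record a negative ledger delta interpreted as
co-substrate uptake; the mass-conservation identity input = product +
side stream is asserted only for chains whose factors are all ≤ 1.  The
NFC fermentation factor 0.093 is the per-NFC basis extrapolated from a
silage feeding experiment (32 kg acids from 345 kg NFC, `nfc_yield_basis`).

**Market and land.**  National demand = global production × national GDP
share (default 0.03; configurable per product).  Coverage and
required-feedstock shares are reported unclamped — values above 1 mean the
demand outgrows the pool and are meaningful.  Land savings divide the
product mass by (chain factor × relevant-fraction content of the displaced
biomass × areal yield).  Packaged constants: woodland 10 Mg ha⁻¹ a⁻¹ with
average lignin content 0.25; corn silage 40 Mg ha⁻¹ a⁻¹ at 35% DM;
rapeseed 40 Mg ha⁻¹ a⁻¹ at 44.6% oil.  The rapeseed areal yield is used
verbatim from the source constants although it is far above agronomic
norms; treat the derived oil-crop areas as illustrative.

## Data-quality rubric

Five ordinal levels over three criteria: number of independent sources,
analytical grade (`detailed_with_series` > `detailed` > `method_stated` >
`unclear`) and age of the newest source relative to the reference year.
Default grid: level 1 = {≥3 sources, detailed with series, <5 y}; 2 = {≥2,
detailed, <10 y}; 3 = {≥2, method stated, <20 y}; 4 = {≥1, method stated,
<30 y}; 5 otherwise.  A residue receives the best level whose requirements
it fully meets, so e.g. >2 detailed-with-series sources from 15 years ago
score 3 — recency caps the level.  The exact grid is an interpretation of
the published tier boundaries and is therefore configurable; custom
rubrics are validated to weaken monotonically with the level, which
guarantees the score is monotone in each criterion.

## The bundled reference matrix

`reference_fixture()` loads 20 residues whose relevant-fraction means and
tier structure follow a published cross-sector composition survey of
German biogenic residues.  Per-residue technical potentials are **not**
published in that survey's main tables; the bundled potentials are
synthetic reconstructions chosen so the tier pool sums close exactly on
the published tonnages wherever those are internally consistent (lignin
favorable 31.2/7.8 Mt, with-possible 42.7/10.1 Mt, NFC favorable
6.9/2.7 Mt, oil waste 156/142 kt, glycerol 277/263 kt).  Two published
figures cannot be closed from per-residue data and are therefore carried
as constants in the fixture instead of being recomputed:

- the NFC possible-tier fraction pool: the raw-pool increment (9.7 Mt at
  NFC 0.16) implies 1.55 Mt of NFC, not the published 4.0 − 2.7 = 1.3 Mt;
- the published NFC product potentials (210 kt favorable / 368 kt
  possible): 2.7 Mt × 0.093 = 251 kt, so the favorable figure does not
  follow from the published pool and factor.

Quality metadata in the fixture (source counts, grades, years) is
synthetic/plausible; the published per-class quality tally depends on
supplementary per-residue data and is not reproduced.  The published
conversion of C6/C8 acids to lubricant ingredients implies an unstated
factor ≈ 1.25 and is not implemented.

## Synthetic-data generator

`generate_matrix` emulates the statistical structure of a national residue
inventory: sectors drawn from configurable weights (defaults 0.30
agriculture, 0.25 industry, 0.20 municipal, 0.15 forestry, 0.10 other),
potentials log-uniform over 2.5×10⁵–2×10⁷ Mg DM a⁻¹ (spanning the cutoff
to the largest single streams), compositions sampled on the simplex from
per-sector Dirichlet archetypes (woody sectors lignin-heavy ≈ 0.25,
food-industry sectors NFC-heavy ≈ 0.35) with concentration 60, and MIN/MAX
spreads of 5–30% around the mean, clipped to [0, 1].  Quality metadata is
sampled from simple categorical/Poisson defaults.  A single seeded PCG64
stream drives everything; the seed is recorded in the matrix provenance,
and identical configurations are bit-identical.

Planted-truth constraints are satisfied by exact post-hoc adjustment:
disjoint blocks of residues are pushed above the threshold, all other
residues are pushed below it for that fraction (rescaling the remaining
fractions to keep the simplex constraint), and member potentials are
rescaled to hit a requested fraction-pool mass exactly.  Constraint
satisfiability (disjoint fractions, counts within n) is validated before
any sampling.  The recorded ground truth (member ids, raw and fraction
pools summed in matrix order) is what the screening and pooling stages
must recover exactly.

What the generator does not emulate: real residue nomenclature, temporal
potential series, between-fraction correlations beyond the archetype
means, and measurement error structure.  Passing the recovery tests shows
the pipeline arithmetic is correct on matrices of realistic shape; it does
not validate the underlying survey data.

## Numerical choices

- Reporting rounds to 3 significant figures; all internal computation and
  the machine-readable report JSON are unrounded.
- Composition means may not close to 1 (heterogeneous assays): sums above
  1.05 warn, above 1.20 are hard errors.
- Tolerance for reproducing published tonnages is 1% relative, reflecting
  their 3-significant-figure rounding; published utilization ratios are
  printed at 2 significant figures and are compared against unrounded
  mass ratios.
- Tier assignment uses ≥ for lignin/NFC and strict > for oil, matching the
  stated threshold semantics; ties at a threshold are therefore
  deterministic.
- Pool sums run left-to-right in matrix order, so generator-recorded truth
  and pipeline pools agree bit-for-bit; cross-set additivity is asserted
  to 1e-12 relative.
- Written reports are deterministic (sorted JSON keys, fixed ordering, no
  timestamps) and byte-identical across re-runs.

## Problem sizes

Property tests exercise synthetic portfolios up to n = 1000 residues
(seconds on one CPU); the bundled assessment itself is a 20-residue
matrix and runs in milliseconds.

## Known limitations

- The assessment treats technical potentials as fully mobilisable;
  competition between processes for the same residue is not modelled
  (pools are computed per process independently).
- The GDP-share demand proxy is crude; one published demand figure
  (68 kt citric acid from a 2.0 Mt market) implies a share other than 3%
  and is not reproduced.
- The arable-land range for the carboxylic-acid and citric-acid products
  involves unstated intermediate assumptions and does not close from the
  packaged constants; only the woodland saving is asserted.
- Suitability shares of the full 77-residue national portfolio require the
  complete inventory; with the 20-residue bundled matrix the suitability
  summary covers only the encoded residues.
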