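# Methods

## Setting and unit of analysis

The package models a catchment-area referral system: the set of
organizations providing HIV care and/or family-planning (FP) services to
one sub-city's population, and the directed relation "organization *i*
refers clients to organization *j*". Ties are binary; a surveyed referral
frequency (never/rarely/sometimes/often) is carried through I/O untouched
but ignored by every statistic, because the study-level quantities the
pipeline reproduces are defined on binary arcs. Networks are simple: no
self-referrals, at most one arc per ordered pair. Referrals across
sub-city boundaries are out of scope by design — the survey instrument the
analysis mirrors never asked about them.

## Roster construction

The analyzable organization set comes from a snowball census: starting
from seed organizations known to the coordinating health office, each
named organization is asked to name others until no new names arise
(transitive closure over nominator → nominee links). An organization
enters the roster iff it was named by at least two *distinct* other
organizations, with one exception: private clinics, which sit largely
outside the free public/NGO referral circuit and are seldom named, are
admitted with a single nomination. Two choices were genuinely open and are
resolved as follows:

- **Seeds are always retained.** The census is anchored on them and they
  are interviewed regardless of how often they are later named.
- **Distinct-nominator counting.** "Named by two organizations" is read as
  two distinct namers; repeated nominations from the same namer count once.

## Descriptive statistics

Density, in/out-degree, the dyad census, reciprocity, Freeman
centralization and attribute mixing matrices are defined in the package
docstrings. Two conventions deserve a note:

- **Reciprocity** defaults to the dyadic convention that counts null dyads
  as symmetric, $(M+N)/(M+A+N)$. For the 25-organization network with 69
  arcs this is the only convention consistent with the reported 0.83 (arc
  reciprocity $2M/m$ would require $2M/69 = 0.83$, i.e. a non-integer
  mutual count). Arc reciprocity is available via `mode="arc"`.
- **Centralization** defaults to in-degree (received referrals), because
  the study's high-centralization network owes it to a hospital that
  *receives* ties from most of the network. Denominators: $(n-1)^2$ for in
  or out mode; $(n-1)(2n-4)$ for total mode, which normalizes the fully
  mutual star to exactly 1.

## ERGM homophily probing

All implemented terms — edges, nodematch, nodemix, absdiff, sender and
receiver covariates, edge covariates — are dyadic-independent, so the
likelihood factorizes over ordered dyads and maximum pseudolikelihood
(logistic regression of the arc indicator on the change statistics,
Newton iteration with step halving, score max-norm tolerance 1e-8) is the
exact MLE. This is why the package deliberately stops short of
dyadic-dependent terms (triangles, GWESP) and MCMC-MLE: the attribute
questions the analysis asks do not need them. Separation (a term that
perfectly predicts arcs, e.g. pure within-category referral) is detected
when estimates diverge past |θ| = 20 and reported as a non-converged fit;
a rank-deficient design (e.g. nodematch on a single-category attribute)
raises an error, which `homophily_report` converts into a "degenerate"
row. Association is judged by a two-sided Wald test at α = 0.05 with no
multiple-testing correction, matching how the source analysis reported
"associated / not associated".

Simulation uses a single-arc-toggle Metropolis chain with the per-dyad
linear predictor precomputed once (valid precisely because the terms are
dyadic-independent). Defaults: burn-in 20 sweeps, thinning 5 sweeps, one
proposal per dyad per sweep. For the edges-only model the stationary
arc-presence probability is logistic(θ), which the tests exploit as a
closed form.

## Service-gap audit

A gap is an organization that could have, but did not, refer clients for
services it does not provide. The service catalogue splits an HIV domain
(testing, ART, care and support, PMTCT) from a one-code FP domain so that
both scan modes are expressible: *domain* mode (provides nothing in the
domain and refers to no provider) and *partial* mode (provides a strict
subset of the HIV codes and refers to no *other* HIV provider). Any
out-arc to a qualifying provider clears the flag regardless of the
recorded frequency, since the study-level counts credit "at least one
client" referred. The audit is monotone: adding arcs can only remove
flags, removing services can only add domain-mode flags — both are
property-tested.

## The synthetic networks

`fixtures.make_paper_fixture` generates one network per sub-city that
reproduces the published marginals exactly:

| constraint | Kirkos | Kolfe Keranyo |
|---|---|---|
| n, m | 25, 69 | 26, 101 |
| type counts | 3 health centers, 14 NGO, 6 FBO, 2 private clinics | 1 hospital, 3 centers, 3 posts, 6 NGO, 1 FBO, 10 private clinics, 2 private hospitals |
| service mix | 18 HIV-only, 7 both | 5 HIV-only, 1 FP-only, 20 both |
| dyad census | (9, 51, 240) → reciprocity 0.83 | (15, 71, 239) → 0.78 |
| planted structure | 4-FBO clique, all 12 intra-arcs, one exit arc | hospital hub, in-degree 17 |
| FP gaps | exactly 2 HIV-only orgs, 16 with ≥1 FP referral | 0 |
| medians | clients 219, staff 10/2 | clients 1350 (hospital 150000), staff 7/5 |

The dyad censuses are the integer solutions implied by the printed arc
counts and reciprocities: for Kirkos, $(M+N)/300 = 0.83$ with $2M + A =
69$ has the unique solution $M = 9$; for Kolfe, $(15, 71, 239)$ is taken
among the integer solutions rounding to 0.78. Edge placement is
constraint-first — clique, exit arc, one FP-coverage arc per
organization that must not be a gap, hub in-arcs, the mutual-dyad quota —
followed by seeded random fill of asymmetric arcs under in-degree caps,
with deterministic seed escalation on the rare infeasible draw. Client
volume and staffing are hand-placed literal tables: the middle order
statistics pin the published medians exactly, and the medians of the
per-organization client:staff ratios land within ±15% of the published
29/19 (Kirkos) and 127/203 (Kolfe) — ratio medians over 25-odd
organizations cannot be pinned exactly without over-constraining the
other medians, so they are treated as soft targets.

Two published quantities are deliberately *not* hard targets. The
centralization values (0.192, 0.525) are not uniquely recomputable
without the raw data (the variant used is unstated); the generator's
in-degree caps place the synthetic values (0.184, 0.546) within ±0.05 of
them, asserted as a soft band. The ERGM coefficient table of the original
analysis was never published, so no coefficient-level reproduction is
claimed; instead the engine is validated by property-based checks
(below). One Results sentence says six Kolfe organizations provide no FP
while the attribute table implies five; the fixture follows the table.

What the fixtures do *not* emulate: real spatial structure (coordinates
are uniform on a 10 × 10 km box and "driving distance" is Euclidean),
any attribute–tie dependence beyond the planted structures, and
measurement error in self-reported attributes. A side effect worth
knowing: the Kolfe hub receives many ties *and* has an extreme
client:staff ratio, so an absdiff probe on that ratio can read as
associated in the synthetic network — a fixture artifact, not a study
finding. Passing tests therefore demonstrate the correctness of the
machinery on networks with the published margins, not substantive claims
about the real referral systems.

Nomination data are generated so the roster procedure recovers each
network exactly: one seed names everything (plus a non-private distractor
named once, which the rule must exclude), a second organization provides
the second distinct nomination for every non-private organization, and
private clinics stay named-once to exercise the exception path. A seeded
over-nomination fraction (default 0.2) adds realistic redundancy without
touching private clinics.

## Validation strategy and problem sizes

- Every descriptive metric is checked against independent explicit-loop
  oracles on the exhaustive set of all 4096 directed graphs on 4 nodes,
  and against networkx where it implements the same convention.
- Change statistics are checked against whole-graph statistic differences
  recomputed from first principles on random 5-node graphs.
- The MPLE is checked against the closed form logit(density) for the
  edges-only model, against statsmodels' logistic solver on the same
  design (1e-6), and against exhaustive-likelihood maximization (explicit
  partition-function sum over all 2^12 graphs) on 4-node graphs (1e-4).
- Parameter recovery: simulating at known (edges, homophily) coefficients
  with n = 25 and refitting recovers both within 2 SE in ≥ 90 of 100
  replicates.
- Calibration: with no distance effect in the generator, the distance
  edge covariate is declared not associated in ≥ 90% of 100 seeds,
  mirroring a null finding.
- The gap audit is compared to a set-logic oracle on random small
  networks and stress-tested for monotonicity over 1000 perturbations.

These sizes (n ≤ 25 simulations, 100 replicates, 4-node exhaustion) keep
the whole suite under a minute while leaving each check statistically
decisive.

## Known limitations

- Only dyadic-independent ERGM terms; no triangle/transitivity effects,
  no MCMC-MLE, no goodness-of-fit suite beyond recovery tests.
- One network at one time point; no longitudinal comparison.
- The gap audit is organization-level; it says nothing about client-level
  unmet need.
- Fixtures match printed marginals only and must not be mistaken for the
  true unpublished networks.
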