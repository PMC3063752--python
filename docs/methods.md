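# Methods

`replisim` models the evolution of a division of labor between templates
and catalysts in minimal replicator systems.  Two chemical forms of the
same information carrier exist: RNA-form molecules, which can act both as
template and as template-directed polymerase, and DNA-form molecules, which
can act only as template.  The question the models pose is purely
population-dynamical: under what conditions does a system of RNA-only
self-replicators evolve, and then retain, template-only (DNA-like)
molecules?

## Reaction scheme

Every molecule carries a role (RNA polymerase `Rp`, DNA polymerase `Dp`, or
parasite), a form (RNA/DNA), and two recognition rate constants in [0, 1]:
`rrec` for RNA templates and `drec` for DNA templates.  Replication is a
two-step reaction:

1. **Complex formation** between a free RNA-form catalyst and a free
   template, at rate `rrec` or `drec` of the catalyst according to the
   template's form, multiplied by `k_p >= 1` when the template is a
   parasite.
2. Either **dissociation**, at one minus the same recognition constant
   (the parasite factor does not apply), or **replication** at rate `k`
   into an available resource unit, producing a copy of the template whose
   form is the catalyst's product type (`Rp` makes RNA, `Dp` makes DNA) and
   freeing both partners.

Molecules decay to resource at a form-dependent rate (`d_rna = d_dna` in
the baseline); decay of one complex member frees the other.  At most one of
five mutually exclusive mutation channels fires per replication: a uniform
step of half-width `delta` on `rrec` or on `drec` (clamped, not reflected,
at [0, 1]), a polymerase-type flip `Rp -> Dp` (the reverse rate is zero by
default; it is not needed for DNA evolution and leaving it off keeps the
Rp pool from a spurious sink), or conversion into a parasite.  Parasites
breed true and their recognition fields are inert.

The two-step scheme is the load-bearing assumption: because a catalyst
engaged in replicating others cannot simultaneously be replicated, RNA-only
systems carry a *template–catalyst trade-off* that parasites (pure
templates) exploit.  Template-only DNA dissolves the trade-off, which is
the selective raison d'être of the transcription system.  The
instantaneous-replication control (`complex_formation_enabled = false`)
removes the explicit hand-off by firing replication as a single event at
the recognition-rate constant into a random empty neighbour, with complex
formation treated as rate-limiting.

## Lattice engines

The surface model is a 2-D cellular automaton, one molecule per square,
empty squares acting as the resource.  One pass makes `N_sites` attempts of
a random-sequential update: pick a site; if occupied, pick a random Moore
neighbour (configurable to von Neumann) and select at most one event —
decay, complex formation, dissociation, replication into an empty
neighbour of either complex member, or a diffusion swap — with probability
`rate * dt`.  `dt` must keep each attempt's event menu summing below one;
the default is the reciprocal of the largest per-molecule total rate.
Boundaries have no flux.  Complexes move as rigid units: swaps that would
separate partners are rejected.  The well-mixed variant samples interaction
partners uniformly from the whole lattice with diffusion disabled.

The update scheme is pinned by a calibration contract rather than by fiat:
the well-mixed engine's species-density trajectories must converge, for
large lattices, to the mass-action ODE with the same rate constants (the
acceptance suite checks 20 checkpoints against a 3-sigma Monte-Carlo band
on a 256x256 lattice; the residual discretisation bias is O(dt) and is held
well under the band by `dt = 0.005` there).  This convergence also fixes
the meaning of the simulation timescale.

The compartment model superimposes Cellular Potts (CPM) boundary dynamics:
compartments are sets of squares with a shared id, evolving by Metropolis
copy attempts under `H = lam * (volume - target)^2 + J * (unlike
contacts)`, with `target = beta * n_replicators`, so compartment size
tracks internal population.  Copy attempts onto molecule-occupied squares
are rejected — boundary impermeability is implemented as rejection, both
for replicator motion and for boundary retraction.  At `volume >= V_div`
the compartment divides along the second principal component of its site
coordinates (sites and their molecules partitioned by the sign of the
centred projection on the first principal axis; exact ties by fair coin).
A compartment emptied of replicators has target zero, shrinks, and is
removed at volume zero.  Reactions and diffusion never cross compartment
boundaries; intra-compartment diffusion is raised (`diff = 1.0`) so the
interior is relatively well-mixed.  A `cross_boundary_diffusion` toggle
(used with the instantaneous-replication variant) lets diffusion swaps
ignore compartment boundaries while reactions still respect them.

## Mass-action companions

`ode_models` renders the same reaction scheme as deterministic mass action
over species x form free pools plus one pool per complex type, with the
resource defined as capacity minus occupancy (complexes count two), exactly
mirroring the lattice's empty-square bookkeeping.  Mutation terms are
omitted: the ODEs isolate the deterministic population dynamics.
Extinction is declared when total catalyst concentration falls below 1e-6
of capacity (the integrator-noise floor).  Noteworthy structure found and
exploited by the analyses:

- the pure transcription system has a *line* of stable equilibria
  parameterised by the initial `Rp^DNA : Dp^DNA` ratio (structural
  instability), with collapse at extreme ratios;
- the two-step cycle has a strong Allee threshold — initial conditions
  must be inside the interior attractor's basin (the ratio-scan seeds RNA
  pools at 0.1 for this reason);
- adding reverse transcription introduces a self-amplifying asymmetry in
  the `Rp:Dp` ratio.  At recognition 0.01 the amplification is slow
  (e-folding on the order of 1e5 time units), so the outcome is classified
  by integrating to 2e7, which LSODA does in well under a second;
- the stoichiometric bookkeeping behind the template/catalyst asymmetry:
  producing the `Rp^RNA x Rp^RNA` and `Rp^RNA x Dp^RNA` complexes at equal
  rates consumes free molecules 3:1.

## Lineage labeling

The descent protocol labels every molecule by its current form; labels are
inherited strictly from the template side of each replication, regardless
of product form, and never enter any rate (a labeled and an unlabeled run
with the same seed are bit-identical).  The system runs until each tracked
species' surviving population carries a single label, the winning label and
the standing DNA-form fraction at labeling time are recorded, and the cycle
repeats.  The `Rp -> Dp` mutation channel is disabled for the duration.
Per-cycle step budgets default to 50x the completion time (slowest tracked
species) of a pilot cycle, bounded by a hard cap; cycles that exhaust the
budget are flagged incomplete and excluded from fixation denominators.
Because the desk-scale community has a finite lifetime (below), the canned
descent experiment runs the protocol in batches of five cycles over
independently seeded communities; the per-cycle statistic is unchanged,
only the substrate is refreshed.  A species whose DNA-origin fixation fraction
exceeds its standing DNA-form fraction receives its information through DNA
templates more often than label assignment alone predicts; the comparison
ships as an exact one-sided binomial test with the standing fraction as the
null.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 1.0 | replication rate of a formed complex (sets the timescale) |
| `d_rna`, `d_dna` | 0.05 | decay to resource, per time |
| `diff` | 0.01 | neighbour-swap diffusion rate |
| `k_p` | 2.0 | parasite complex-formation advantage |
| `mu_r`, `mu_d` | 0.01 (evolving presets) | per-replication mutation probability of each recognition constant |
| `delta` | 0.05 | half-width of the uniform mutation step |
| `mu_rp_to_dp` | 1e-4 when enabled | polymerase-type conversion |
| `mu_par` | 1e-5..1e-4 | catalyst-to-parasite conversion |
| `beta` | 2.0 | CPM target volume per internal replicator |
| `V_div` | 300 | CPM division threshold (squares) |
| `J`, `lam`, `temp` | 2.0, 1.0, 4.0 | CPM contact energy, volume stiffness, Metropolis temperature |

Recognition-parameter anchors used throughout: idealized self-replication
`(rrec, drec) = (0.4, 0)`; idealized transcription `(0, 1)` for both
polymerases; idealized transcription-like system `(1, 1)` for `Rp` with
`(0, 1)` for `Dp`; reverse-transcription probe `rrec = 0.01` on `Dp`;
invasion inoculum 0.001.

Two calibrated (decay, diffusion) pairs coexist in the presets.  At the
desk scales this package targets (128²–256² lattices), the
parasite-wave regime and the transcription-clump regime of this kernel do
not overlap: self-replicator/parasite experiments run at `d = 0.05, diff =
0.01` (waves persist; the well-mixed control still collapses), while
transcription, coexistence and lineage experiments run at `d = 0.02, diff
= 0.1` (DNA-rich clumps persist).  Full-scale runs (512²–1024², as in the
scenario presets' default sizes) give waves and clumps far more room and
are expected to close this gap; treating the two families separately at
desk scale is a documented scale limitation, not a property of the
modelled chemistry.  The CPM coefficients were calibrated once so that a
constant-target compartment tracks its target within a few percent RMS.

## What the experiments show (and what they do not)

The canned experiments in `replisim.experiments` reproduce, at desk scale,
the directional results the models exist for: parasite-driven collapse of
well-mixed self-replication and its rescue by spatial structure; survival
of the transcription and transcription-like cycles and their destruction by
reverse transcription; fast within-population deterioration of catalysts in
self-replicating systems versus near-neutral deterioration once DNA buffers
the catalyst population, with reverse transcription re-opening the ratchet;
higher fixed-boundary compartment fitness after loss of the DNA replicase;
and DNA-biased template descent for the DNA-dependent polymerases.  The
quantitative values (densities, fixation percentages, decline magnitudes)
are scale- and parameter-dependent; printed full-scale equilibria from
larger lattices and 200-cycle protocols are not recomputed at desk scale.

The synthetic initial conditions are idealized: populations start from the
anchor recognition values rather than from an evolved equilibrium, the
coexistence community is assembled as adjacent bands rather than grown from
a single ancestor, and no sequence-level structure, complementary-strand
chemistry, or template discrimination among same-type templates is
represented.  Passing tests therefore demonstrate the population-dynamical
mechanisms, not chemical realism.

## Numerical choices

- Random-sequential updates with one RNG stream per run (numba's internal
  generator, seeded once at run start; initialisation and division
  tie-breaks use separate seeded `numpy` generators).
- Mutation steps clamp at the [0, 1] boundary; clamping (versus
  reflection) slightly biases boundary-hugging traits inward, which is why
  the neutral reference for deterioration is simulated with the same clamp
  rather than assumed flat.
- Event-menu overflow (`dt` too large) aborts with a diagnostic rather
  than renormalising probabilities.
- CPM sweeps do not enforce compartment connectivity (standard for the
  method); rare fragment slivers are possible and are cleaned up by the
  volume constraint.
- ODE integration uses LSODA (rtol 1e-8), retrying once with Radau at
  tighter tolerance on failure; trajectories are clipped at zero before
  classification.

## Known limitations

- Throughput is ~1e7 update attempts/s; full-scale 1024² equilibration is
  hours, not minutes.  All shipped analyses are sized for minutes.
- The two-regime preset calibration above.
- The fixed-boundary fitness assay's absolute densities depend on `d/k`
  and compartment size; only the ordering (Rp-only > transcription-like,
  with the latter's nonzero death rate) is scale-robust.
- Division by principal component assumes reasonably convex compartments;
  ragged CPM shapes can yield uneven daughters (conservation is exact
  regardless).
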