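# Model and methods

`colonsim` simulates the dialogue between the gut microbiota and the colonic
epithelium inside one section of the transverse colon, and chains five such
sections to emulate the organ. This note records the model equations, the
numerical choices, the calibration status of every default, and what the
synthetic test fixtures do and do not establish about real data.

## 1. Compartmental section model

A section is a cylinder (radius `R = 2.5 cm`, length `Lsec = 1 cm`) split
radially into three well-mixed compartments: lumen `L`, outer mucus `O` and
inner mucus `I` (each mucus shell 0.04 cm thick). State variables are, per
compartment, the volume fractions `f_i` of thirteen solid mixture components
(eight microbial functional groups, mucus, polysaccharides, protein, residual
chyme, liquid) and the concentrations `c_j` (mM; oxygen in arbitrary units)
of eleven dissolved components. Volume fractions sum to one per compartment;
polysaccharides, protein and residual chyme are bulky and exist only in the
lumen; microbial groups never enter the inner mucus. Both exclusions are
structural: the excluded entries are not part of the ODE state vector.

The dynamics are

    df_i/dt = sum_h U_h[f_i] + F_i,      dc_j/dt = sum_h U_h[c_j] + C_j,

with five flow families `h`:

* **Transit** — prescribed inflow `v_in` (cm/h) over the lumen cross-section
  and a solved outflow `v_out`; the outflow removes the lumen mixture with
  bacteria under-represented according to a saturating retention factor
  (`retention_max * f_b / (K + f_b)`), so only bacteria resist washout.
* **Secretion** — epithelial sources in the inner mucus: mucus volume and
  AMPs at a basal per-cell rate plus a PRR-stimulated term, and the
  crypt-top oxygen flux. Capacities scale with per-crypt cell counts times
  crypts per section.
* **Absorption** — enterocyte-scaled uptake of lactate, the three SCFAs and
  H2S, routed `L -> I`, `O -> I` and `I -> epithelium` (the inner-mucus
  concentrations are exactly what the crypt model sees as its boundary
  conditions); liquid is absorbed compartment-wise. Rates intensify toward
  the wall (`I > O > L`).
* **Diffusion** — passive first-order exchange of monosaccharides, the four
  gases, oxygen and (weakly) AMPs across the two interfaces; conserves the
  total dissolved amount.
* **Motility** — active attraction of every group from the lumen into the
  outer mucus (saturating in the mucus present there); passive return rides
  the balancing flows.

**Volume balancing.** Compartment volumes are constant. At every
right-hand-side evaluation three unknowns — `v_out` and the two mucus
interface velocities — are solved in closed form, innermost compartment
first, so that `sum_i df_i/dt = 0` holds exactly (to round-off) in each
compartment. The interface fluxes are sign-aware: when secretion dominates,
the flux advects the local mixture outward (mucus liquefies on entering the
lumen, bacteria ride along); when absorption dominates, liquid is drawn
inward instead, and because only liquid moves inward, bacteria can never be
pushed into the inner mucus. The moving volume carries its dissolved
content; without this solute advection, locally produced SCFA accumulates
unphysically in the thin mucus shells and the expected transverse orderings
(SCFA and H2S decreasing toward the wall, AMPs and O2 increasing) cannot
form. The transit-slowdown constraint `0 < v_out < v_in` is monitored and
reported; it holds at every healthy steady state.

## 2. Microbial metabolism

Eight functional groups cover the degradation network: two monosaccharide
fermenter groups (`Bmon`), three lactate consumer groups (`Bla`, with an
oxidative pathway reserved to the oxygen-tolerant one), hydrogenotrophic
acetogens (`BH2a`), methanogenic archaea (`BH2m`, pH-gated), and an
H2S-producing group (`BH2s`) gathering sulfate reducers and cysteine
catabolizers, which grows on dietary protein (oxygen-requiring pathway),
on hydrogen, and — more poorly — on mucin glycoprotein.

Every transformation is one column of a Petersen matrix pair: `P_f` holds
the solid volume-fraction yields, `P_c` the dissolved yields, and source
terms are `F = P_f K`, `C = P_c K` with the kinetic rate vector `K`. Rates
follow multiplicative Monod saturation: `q_max * f_group * prod(c/(K+c))`,
times the pH gate (a Gaussian bell, methanogenesis only) and a
liquid-availability factor (growth is limited by free liquid space). The
liquid row of `P_f` is computed, never configured, as minus the sum of each
column, so metabolic volume conservation is exact by construction: growth
consumes liquid, lysis and degradation release it.

Death is basal + AMP-proportional + oxygen-proportional, the oxygen
coefficient keyed to the group's inflammation-sensitivity class (`phi` high,
`mu` moderate, `delta` zero); oxygen acts as the inflammation proxy. H2S
attacks mucus bonds above a 1 mM threshold through a C1-smooth ramp
(quadratic blend over 0.05 mM) — smooth enough for stiff integrators, exactly
zero below threshold. The four gases have first-order liquid-to-gas sinks
toward per-gas equilibrium concentrations; oxygen is a solute and is never
gas-transferred.

## 3. Epithelial crypt

The crypt is one-dimensional on a normalised axis `z in [0,1]` (base to
mouth). Four mobile cell densities (stem, progenitor, goblet, enterocyte)
obey advection–reaction–diffusion equations; deep crypt secretory cells are
a static base bump. Transport is crowding-driven: an upward velocity
proportional to the gradient of the pressure `(rho_tot/capacity)^2`
(one-way, upwinded), plus a small random-motility diffusion
(`1e-3` on the unit axis) that keeps the steady state grid-converged
(doubling the grid from 50 to 100 nodes moves cell counts by < 0.5%).
Cells are removed by a smooth shedding sink concentrated in the top 6% of
the axis — a better-posed stand-in for mouth extrusion than a boundary
outflow, whose one-sided velocity estimate did not converge under grid
refinement. Stem cells divide inside a niche weight `exp(-(z/0.1)^2)` and
compete for niche occupancy against the static dcs population (capacity
1600 cells per unit length) rather than against the whole column; without a
dedicated niche budget the stem population is outcompeted by progenitors
and collapses to an unintended stem-free steady state. Committed stem cells
become progenitors; progenitors divide under whole-column crowding and
differentiate above `z = 0.1` into goblet cells and enterocytes at a fixed
1:3 fate split. Stem and progenitor division share the PRR amplification
`1 + 0.6 * R`, with `R = f_B^O / (0.013 + f_B^O)` the Hill-1 activation by
the outer-mucus bacterial fraction.

Solutes: oxygen enters as a Neumann flux at the base (vessels beneath the
epithelium), diffuses upward, and leaves through a Robin exchange with the
inner mucus at the top — that outflux is the section model's oxygen source.
Lactate, acetate, propionate and butyrate enter at the top with Dirichlet
values equal to the inner-mucus concentrations and are absorbed on the way
down in proportion to the enterocyte density. Butyrate is additionally
consumed by beta-oxidation: the switch level
`sigma = M(but) / (1 + (H2S/1 mM)^4)` scales an oxygen-and-butyrate Monod
consumption by differentiated cells, with O2 used at a fixed stoichiometric
ratio (2 per butyrate). High H2S shuts the switch, stranding oxygen at the
crypt mouth — the mechanistic route from protein fermentation to epithelial
oxygen leakage.

## 4. Coupling and the five-section pipeline

Each section is solved as a joint fixed point: integrate the section ODEs to
stationarity under the current epithelial summary, refresh the crypt
boundary from the inner-mucus state, relax the crypt, recompute the summary
(counts, PRR activation, crypt-top O2 flux) and update it with damping 0.5,
until the largest relative change of any coupling quantity falls below
`3e-4` (about 4–10 outer iterations; tightening to `1e-4` changes the
reported quantities only in the fifth significant digit at ~30% more
runtime). Downstream sections start from the upstream solution, receive the
upstream steady lumen composition bit-for-bit, and match `v_in` to the
upstream `v_out`.

Breach scenarios perturb sections 2–4 only: scenario A multiplies the AMP
production rate (default 3x), scenario C adds an oxygen bloom at the crypt
base (default +0.26 units/h, tripling the basal supply), and scenario B
applies both; A and C compose exactly to B at the parameter level. The
magnitudes are calibrated defaults chosen so the qualitative scenario
responses are clear-cut.

## 5. Numerics

* Section ODEs: LSODA, `rtol 1e-7`, `atol` 1e-10 on fractions and 1e-8 on
  concentrations; structural zeros are excluded from the state vector, so
  the exclusions hold exactly, not approximately. Integration runs in
  100 h chunks up to `T_max = 400 h` per section, stopping early if
  `||dy/dt||_inf / (||y||_inf + eps) < 1e-8` (the healthy steady states
  typically reach ~1e-6/h by 400 h; the fixed horizon is the defining
  procedure, the early stop an optimisation).
* Negative undershoots are clipped to zero inside rate evaluations only,
  never in the state, so the conservation audits stay exact.
* Crypt: method of lines on 50 nodes (production default), upwind advection.
  Solutes are solved quasi-statically by default (diffusion is fast against
  cell turnover) via Picard-linearised tridiagonal solves; a fully dynamic
  mode co-integrates cells and solutes and agrees with the quasi-static
  steady state to < 1e-4 relative (verified in the test suite).
* Balancing flows: closed-form sequential elimination (I, then O, then L);
  the system is triangular, and exactness matters for the conservation
  audits.

## 6. Diets and the grid scan

Two named diets are fixed inputs: the reference diet
(fibre fraction 0.05, protein 0.0135, with its printed dissolved inputs)
and the high-protein/low-fibre diet (0.025/0.025). For scans, the fibre
range [0.02, 0.06] maps affinely onto each metabolite's input concentration
range (e.g. monosaccharides [1e-5, 4e-5] mM); the named diets are *not* on
that affine map and always take precedence — the map exists to make scans
reproducible, the named diets to preserve the exact published inputs.
Protein spans [0.01, 0.03]. `v_in = 0.416 cm/h` at the first section.

## 7. Calibration status and limitations

Every kinetic constant, yield and rate in the shipped defaults is a
**calibrated** value — none is a transcription of a measured or previously
published table — chosen once so that the reference
simulation lands in the physiological ranges that characterise the healthy
transverse colon: total luminal SCFA near 90–110 mM with an approximate
54:23:23 acetate:propionate:butyrate ratio, H2S well below the 1 mM toxicity
threshold, AMPs near 0.5 mM in the inner mucus, a bacterial volume fraction
of ~0.006 in the lumen rising along the colon and roughly double that in
the outer mucus, ~2300 cells per crypt of which ~27% are proliferative, a
goblet:enterocyte ratio of 1:3, and a 7–8-fold oxygen drop from crypt base
to mouth. The acceptance script recomputes these quantities from scratch.

Known limitations of the calibrated defaults:

* The longitudinal SCFA decline across sections is steeper than the gentle
  few-percent decline expected physiologically: with washout-dominated
  luminal kinetics, fibre is mostly fermented in the first section and the
  downstream sections dilute rather than replenish. The decline is
  monotone, which is the property the experiments rely on.
* Crypt composition varies only mildly along the five sections; behaviours
  that hinge on strong longitudinal crypt gradients (e.g. a pronounced
  downstream recovery of an immature crypt under the high-protein diet) are
  muted.
* The model is deterministic; there is no demographic noise in either the
  microbial or the cellular populations.

## 8. What the synthetic fixtures show — and what they do not

The test fixtures (a two-group fermenter, a diffusion-only section, a
20-node crypt, seeded random states) exercise conservation laws, oracle
equivalence against independent per-process evaluations and closed-form
solutions, structural exclusions, and the qualitative orderings of the
healthy state, the diet grid and the breach scenarios. Passing them shows
the implementation solves the stated equations correctly and that the
calibrated defaults produce the intended qualitative biology. It does not
validate the model against clinical or experimental measurements: absolute
concentrations and cell counts inherit the uncertainty of the calibrated
parameters, and conclusions about real diets or diseases require the same
caution as for any mechanistic model fitted to ranges rather than data.
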