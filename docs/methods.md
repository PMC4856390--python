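# Methods

This note records the science and the concrete numerical choices behind
`cabletaper`: the model and its assumptions, the conventions that resolve
genuinely open design points, what the synthetic-data generators do and do
not emulate, and the known limitations.  It states no empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Model and units

The package solves the passive cable equation for a neurite of radius
r(x) µm:

    τ ∂v/∂t = −v + [2 r_a g_l r √(1+r′²)]⁻¹ ∂/∂x [ r² ∂v/∂x ],

v being voltage above rest.  External units are µm, mV, nA, MΩ, ms;
r_a stays in Ω·cm and g_l in S/cm² as conventionally quoted.  Every µm→cm
conversion happens in `params.py` (`UM_PER_CM`); radii — never diameters —
are stored throughout (SWC column 6 is a radius; no factor 2 anywhere).
Named passive sets ship for the cell classes this method is typically
applied to (fly tangential HS/VS: 60 Ω·cm, 5·10⁻⁴ S/cm²; dentate granule:
210, 4·10⁻⁵; Purkinje and neocortical L5: 150, 5·10⁻⁵).

The local electrotonic length is λ(x) = √(r/2 r_a g_l); the cumulative
electrotonic distance Λ(x) = ∫₀ˣ ds/λ.  The taper-rate parameter

    ϵ(x) = λ(x) |r′(x)| / r(x)

(the ratio of the voltage decay length to the radius e-fold length) is the
package's *declared convention* for "how fast the cable tapers": no formula
for it is standard, but this one vanishes on cylinders, scales as 1/√(r_a g_l),
and orders the approximation error correctly in every comparison the suite
runs.  For noisy/periodic profiles `estimate_epsilon` optionally smooths the
radius with a moving average (≈ one oscillation period) before
differentiating, since the raw derivative of a jagged reconstruction
measures digitisation noise, not taper.

## 2. Finite-difference oracle (`numeric.py`)

The reference solver discretises the flux form d/dx[r² dv/dx] − 2 r_a g_l r
√(1+r′²) v = −(r_a/π) I δ(x−x′) on a uniform grid with face-centred fluxes
and half control volumes at the ends.  The matrix is symmetric positive
definite, which yields reciprocity (Green matrix symmetric to machine
precision), discrete current conservation (row sums telescope), and
second-order convergence — all asserted in the suite.  The √(1+r′²)
lateral-area factor is kept in the oracle although the asymptotics drop its
O(ϵ²) contribution; the difference is part of what the comparisons measure.
For piecewise-constant (staircase) cables the factor is disabled, since the
grid derivative at a step is meaningless.

Boundary conditions: `sealed` (zero flux, natural in flux form), `killed`
(v = 0, node eliminated), and `matched_infinite` — a Robin load v/R∞ with
R∞ the input resistance of a semi-infinite uniform cable continuing at the
boundary radius.  The last emulates "the cable continues toward the soma"
on a finite grid and is validated against an explicit 10λ collar.  Point
injection is lumped onto the nearest grid node (the snapped coordinate is
reported and used by both solvers in any comparison).  The default grid
keeps dx ≤ min λ/200.

Transients use Crank–Nicolson with a Rannacher start-up: the first two
steps are taken as four backward-Euler half-steps.  Without it, a current
step excites stiff modes that trapezoidal stepping damps only as
(1 − 4/z), leaving ~0.3% residual ringing at t = 20τ; with it the scheme
settles to the steady solution to ~10⁻¹² (the trapezoidal fixed point *is*
the steady-state system).  The Robin collar is treated quasi-statically
(stiffness only); the collar's own charging transient is neglected.

Trees are solved compartmentally: each parent–child edge is a frustum with
axial conductance π r₁ r₂/(r_a l) and slant lateral area split equally
between its end nodes; the sparse SPD system gives node voltages, and a
dense inverse gives the full tree Green matrix (fine for the few-thousand
node trees this package targets).  The root is a sealed terminal
compartment by default; a lumped somatic conductance is available.

## 3. Asymptotic solution (`asymptotic.py`)

The first-order two-scale solution is v(x) ≈ √λ(x)[A e^Λ + B e^−Λ].
Conventions that the derivation leaves open were fixed as follows:

- **√λ prefactor and normalisation.**  The prefactor is √λ(x) (it arises
  as ρ^{1/4}); all amplitudes are normalised by √λ(x′) so that the
  proximal-side coefficient B₁ with unit current *is* the input resistance
  at the injection site, in MΩ.  With this convention the cylinder case
  reproduces the classical closed form R = (R∞/2)(1+e^{−2(L−x′)/λ}) —
  identically, not approximately — which pins every constant.
- **Two-region coefficients.**  Proximal of the injection site the voltage
  decays toward the soma (pure e^{−(Λ(x′)−Λ(x))}); distal of it a sealed
  end at L imposes the reflection ratio k = (2−λ′(L))/(2+λ′(L)), giving
  A₂ = B₂ k e^{−2(Λ(L)−Λ(x′))} and B₁ = A₂ + B₂ (continuity built in).
  The current-conservation jump in the r²-weighted flux fixes B₂ =
  r_a λ(x′)/(2π r²(x′)) per unit current.  |λ′(L)| ≥ 2 makes the
  reflection ratio degenerate and raises `TaperDegeneracyError` — the
  first-order theory has nothing sensible to say about such violent distal
  flare.
- **Quadrature/differentiation.**  Λ by cumulative trapezoid, λ′ by central
  differences (second-order one-sided at the ends), on a uniform grid —
  consistent with the oracle's second-order accuracy, so comparison errors
  measure the asymptotics, not scheme mismatch.

The current-transfer ratio v(0,x′)/v(x′,x′) = √(λ(0)/λ(x′)) e^{−Λ(x′)}
at leading order; the reflection factor cancels in the ratio.

## 4. The transfer functional and the optimal taper (`optimal.py`)

"Current transfer to the proximal end" is taken literally: the quantity
aggregated is the *current* handed to a fixed proximal interface, not the
voltage developed across a shape-dependent load.  In WKB form the axial
current r² dv/dx launched at x′ reaches x = 0 attenuated by
(λ(0)/λ(x′))^{7/2} e^{−Λ(x′)} — the λ^{−7/2} e^{−Λ} integrand of the
variational treatment, with the constant λ(0)^{7/2} of the fixed interface
pulled out.  The functional is therefore

    J = ∫₀ᴸ t(x′) dx′  (µm),   t = delivered-current fraction,

computed two independent ways: closed-form quadrature of the WKB integrand
(optionally with the sealed-end reflection factor 1 + k e^{−2(Λ(L)−Λ)}),
and exactly, by grounding the proximal end of the oracle (killed BC — a
perfect somatic sink identical for every candidate shape) and reading the
delivered current for *all* injection sites from a single adjoint solve
(reciprocity).  On a cylinder the three forms are λ(1−e^{−L/λ}),
λ(1−e^{−2L/λ}) and λ·tanh(L/λ).

This reading matters.  Integrating the *voltage* at a matched-infinite
collar instead — superficially the same quantity — penalises thick
proximal ends through the collar's own conductance (R∞ ∝ r^{−3/2}) and
actually inverts the shape comparison: by that measure an equal-volume
cylinder beats the quadratic taper.  The variational derivation is only
self-consistent with the proximal factor held fixed, i.e. with the
current reading; the voltage-based functional is deliberately not offered.

The reduced Euler–Lagrange equation for J (distal reflection neglected) is
λ′(x) = −2/7 with x increasing distally: an optimal cable's electrotonic
length shrinks linearly at slope 2/7, equivalently r(x) = α(L−x)² + r_L
with the unconstrained α* = 8 r_a g_l/49.  `euler_lagrange_residual`
reports λ′ + 2/7 pointwise: ≡ +2/7 for a cylinder, ≈ 0 in the interior of
the optimal quadratic (exactly 0 only as r_L → 0; a finite distal radius
bends λ away from linearity within ≈ √(r_L/α) of the tip).  In practice α
is *fitted* — to the cable's volume (closed-form positive root of the
volume quadratic) or to its proximal radius ((r₀−r_L)/L²) — because real
cables arrive with a volume budget.

**Known limitation (measured, and left red in the acceptance suite).**
The fitted quadratic is *near*-optimal, not a strict constrained local
maximum: under exact volume-preserving perturbations that pin both end
radii, the exact functional retains a small first-order gradient (at 2%
perturbation amplitude, improvements of order 0.1% of J exist, spread
along the cable).  The stationarity argument lives entirely at the WKB
level, and at the optimum itself ϵ = |λ′| = 2/7 ≈ 0.29 — the optimal
taper sits at the edge of the slow-taper regime, so WKB stationarity
transfers to the exact functional only to O(ϵ).  The defensible content of
the optimality claim, and what the suite asserts green, is dominance:
at equal volume, length and distal radius the quadratic beats the cylinder
and the linear frustum under both evaluation routes, and the derivative-
free segment optimiser (which knows nothing of the analytics) lands on a
quadratic-shaped staircase.

`perturb_volume_preserving` generates the admissible variations: windowed
random Gaussian bumps (window [4x(L−x)/L²]², vanishing at both ends so the
terminal radii — boundary constraints of the variational problem — stay
fixed), with exact volume restoration via the closed-form root of the
volume quadratic in the correction amplitude.

## 5. Segment optimisation (`segments.py`)

Seven equal-length constant-radius segments; Nelder–Mead simplex search on
the logs of the n−1 proximal radii; the distal segment is pinned at r_L and
the volume constraint is enforced by uniform scaling of the free radii
(projection), so every candidate is feasible and no penalty constant is
needed.  The objective is the exact delivered-current integral with a
grounded proximal end (one adjoint oracle solve per evaluation, slant
factor off).  Ten log-uniform random restarts by default (the desk-scale
version of a larger published protocol; the suite's geometries span short,
medium and long electrotonic lengths).  The fit step regresses the distal
six segment radii at segment midpoints on a quadratic and, for contrast, a
line; the quadratic residual is consistently the smaller, and the
optimised staircase tracks the volume-matched analytic profile to within
15% RMS.

## 6. Tree mapping (`tree.py`)

Three steps. (i) *Apparent lengths* by one post-order sweep: terminals 0;
unbranched stretches add arclength; daughters combine as
(Σ l_d^{3/2})^{2/3} (the parent's own arclength is added after combining,
consistent with the traversal direction; trifurcations extend the sums).
(ii) *Radius distribution*: the root path carries r(x) = α(l₀−x)² + r_L
with α = (r_prox−r_L)/l₀²; at each branch the parent radius is split so
Σ r_d^{3/2} = r₀^{3/2} exactly, with the daughter ratio set by apparent
lengths — `literal` rule r₁:r₂ = l₁^{3/2}:l₂^{3/2} (the default) or
`linear` rule r₁:r₂ = l₁:l₂ (the unique rule under which the combination
formula is an exact conductance continuation); both satisfy the Rall
relation to machine precision, recorded per branch point in the
provenance (node radii are sampled *after* taper along each edge, so the
relation is checked on those records, not on SWC radii).  Radii are
floored at r_L, with floor events counted.  (iii) *Volume matching*:
bisection on the proximal radius (volume is monotone in it) with geometric
bracket expansion, terminating at a tenth of the requested relative volume
tolerance (default 10⁻³); a supplied proximal radius that already matches
is accepted immediately (fixed point in one evaluation).

`transfer_map` reports, per node, the ratio v_root/v_node under unit
current at that node (G[root,k]/G[k,k] from the dense tree Green matrix),
uniformly node-weighted means, distances and input resistances.
`equalisation_index` is the coefficient of variation of per-node *somatic
impact* G(root,k) — the dendritic-democracy quantity: the optimal taper
equalises it because the high input resistance of thin distal branches
offsets their attenuation.  The CV of the transfer *ratio* (available as
`quantity='ratio'`) strips out exactly that compensation and is **not**
reduced by taper; the suite asserts the impact reading.

A practical regime note, established empirically by the suite: the mean
transfer advantage of the optimal taper over an equal-volume constant
radius exists for electrotonically *extended* arbors.  On compact trees
(root-tip depth ≲ λ) attenuation is mild and the thin distal ends only
raise local input resistance, so the constant-radius tree wins the ratio
comparison.  The tree acceptance world therefore uses 16-tip random
binary trees with 150–300 µm branch lengths (depth a few λ at the distal
radii, like the reconstructed cell classes the method is aimed at),
r_L = 0.15 µm, fly passive parameters.

## 7. Synthetic worlds (`synthetic.py`) — what they do and don't emulate

- `make_periodic_cable`: radius oscillating about a mean with a
  raised-cosine bump per period (C¹), alternating above/below the mean,
  amplitude per period uniform in [0, range].  Amplitude *fractions* are
  drawn from a fixed 4096-slot pool so a seed defines one cable family:
  the smoothing ladder (period doubled, amplitude halved per rung) then
  smooths literally the same cable, which is what makes per-seed error
  monotonicity a physical statement rather than a draw-to-draw lottery.
  The ladder defaults (mean radius 0.5 µm, L = 1 mm, base period 125 µm,
  base amplitude 0.03 µm) are calibrated so the *smoothest* rung sits at
  the taper-rate scale where the asymptotics claim validity (raw median
  ϵ ≈ 0.01), putting the roughest rung at ϵ ≈ 0.1 where the first-order
  error is conspicuous.  What a green ladder test establishes: the error
  of the first-order solution decreases with ϵ on this family.  What it
  does not: accuracy on real reconstructions, whose radius noise is
  neither periodic nor C¹.
- `make_random_tree`: strictly binary topology by recursive quota
  splitting, branch lengths uniform in a range, random 3-D directions,
  ~10 µm node spacing, constant placeholder radii.  It emulates branching
  statistics only — no tortuosity, no systematic branch-order length
  trends, no measured-radius noise.
- Canonical profiles (cylinder, frustum, quadratic) are exact on their
  grids.

All generators are pure functions of their arguments including the seed.

## 8. Degenerate inputs, tolerances, tie-breaks

- Profiles require ≥ 2 strictly increasing sample points, positive radii.
- SWC: 7 whitespace columns, '#' comments; parse errors name the line;
  structure errors (duplicate ids, dangling parents, cycles, multiple
  roots, non-positive radii) name the node.  Type codes are preserved,
  never interpreted.  Floats are written with shortest round-trip repr, so
  read→write→read is the identity on the node table.
- Injection sites snap to the nearest grid node; both routes of any
  comparison use the snapped coordinate.
- Green matrices default to ≤ 2001 grid points (the dense RHS is m×m).
- `match_volume` refuses targets below the all-r_L floor volume;
  `optimize_segments` refuses volumes below the distal-segment floor;
  `fit_alpha_volume` refuses volumes below the cylinder floor.
- Equal daughter apparent lengths at a branch: weights tie, radii split
  equally (2^{−2/3} each for a symmetric bifurcation).

## 9. Out of scope

Second-order corrections in ϵ; closed-form transients and closed-form
branched-tree voltages (the numerical oracle covers those regimes); active
conductances and conductance-based synapses; morphology repair or soma
surface reconstruction; optimisation of functionals other than the
aggregate current transfer.
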