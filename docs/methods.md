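# Methods

`oxynet` computes the steady oxygen partial-pressure field in tissue
perfused by a vessel network, treating each vessel as a line source of
oxygen embedded freely in a uniform Cartesian mesh. This note documents the
model, the numerical scheme, the choices made where the design was open,
and what the built-in verification problems do and do not demonstrate.

## Model

Three coupled subproblems:

1. **Network hemodynamics.** Each vessel is a Poiseuille resistor,
   C = πR⁴/(8μL); node pressures solve the Kirchhoff system Σⱼ Q_ij = s_i
   with prescribed inflows/outflows at boundary nodes and zero sources at
   interior nodes (transmural fluid exchange is neglected). With pure-flow
   boundary conditions pressures are defined up to a constant (one boundary
   node is pinned to zero) and the flows are invariant to the absolute
   viscosity scale — μ only sets resistance ratios, so its awkward printed
   units never enter the results.

2. **Intravascular oxygen.** Blood carries dissolved plus
   hemoglobin-bound oxygen, f(P_b) = Q(α_b P_b + H_D C₀ S_a(P_b)) with the
   Hill saturation S_a = P_bⁿ/(P_bⁿ + P₅₀ⁿ) (n = 2). Conservation along a
   vessel, df/ds = −q(s), is integrated in the pressure variable,
   dP_b/ds = −q/f′(P_b), by classical RK4 on an arclength grid with three
   samples per mesh cell (h_k = h/3). The network is swept in flow order:
   bifurcations inherit the junction value; collecting junctions mix by
   conservation (invert f of the summed influx). RK4 midpoint fluxes are
   interpolated with a 4-point cubic (a chord average would cut the scheme
   to second order); intervals whose second differences exceed six times
   the local first difference (clamp kinks, depletion fronts) fall back to
   the chord average, which keeps the front dynamics stable.

3. **Tissue diffusion-consumption.** Dα ΔP_O = M(P_O) − S with
   Michaelis–Menten consumption M = M₀P/(P₀+P) and the spread line sources
   S. Discretization: central differences on a node-centered grid
   (x_i = ih, h = L/n, n a power of two), no-flux boundaries by ghost-point
   reflection. The steady state is reached by semi-implicit pseudo-time
   steps (P^{n+1}−P^n)/Δt = DαΔ_h P^{n+1} − M(P^{n+1}) + S^{n+1}, each
   solved by Newton linearization with geometric multigrid V-cycles
   (red-black Gauss–Seidel 2+2 smoothing, full-weighting restriction,
   bi/trilinear prolongation, dense solve at the n = 4 level). The Newton
   stopping rule is an RMS residual below 10⁻³ M₀ — full elliptic
   convergence per pseudo-step is deliberately not enforced.

### Source spreading

Wall-flux samples become point sources q(x_k)h_k on the centerline
(trapezoid closure: endpoint samples carry half weight) and are spread to
the 4^d neighboring nodes with the tensor-product 4-point Peskin kernel,
which conserves mass and first moment exactly. Near no-flux faces ghost
weights fold back across the boundary, and contributions landing exactly
on a face node are doubled: the even (mirror) extension shares the face
plane, whose nodes carry half a cell in the discrete divergence theorem.
Without that doubling a source on the boundary is underweighted and the
face-plane field fails to converge under refinement.

### Wall-flux evaluation

The blood pressure is imposed on the wall (P_O = P_b at distance r₀ from
the centerline) and the flux is read off local least-squares fits with a
fixed intercept: in 2D a linear fit of the four nearest outside-the-vessel
nodes on each side of the wall; in 3D a fit of
c₁log(r/r₀) + c₂Δz + c₃Δz·log(r/r₀) over the shell r₀ < r_⊥ ≤ r₀+h,
|Δz| ≤ h. Both fits subtract the zero-order-consumption particular
solution ((M/4D)(r²−r₀²) around a 3D vessel, (M/2D)(d−r₀)² beyond a 2D
wall, scaled by M(P_b)/M₀) before fitting: at tissue-typical consumption
the reaction term curves the field measurably across the fit shell and
otherwise biases the fitted gradient at first order in h (25 % at
h = 40 μm in the single-vessel problem). Fluxes are positive out of the
blood; negative fits are clamped to zero by default.

Three geometric safeguards matter on networks:

* mesh nodes inside *any* vessel lumen are never used as tissue samples;
* a sample whose wall point x ± r₀n lies inside a neighboring lumen has no
  wall there and is not fitted;
* samples within twice the node's largest vessel radius of a segment end
  are not fitted either: the constant-pressure edge of a line source is a
  genuine field singularity whose fitted flux grows under refinement and
  would dump the blood's oxygen budget into a vanishing neighborhood.

Samples excluded by these rules inherit the nearest resolvable flux on the
same segment — consistent with the physical observation that the flux dips
at cross-links where several vessels share the local supply. The exclusion
radius is purely geometric, so successive meshes regularize the same
physical neighborhood. Ends lying on a no-flux face are exempt (the mirror
symmetry continues the vessel there).

### Post-processing correction

Spreading smooths the near field within ~2 cells of each source. For a
unit point source the error patch δP_k = P_k − P̄_k is precomputed on an
8^d-node patch: P_k is the free-space Green's function of the solve
operator and P̄_k the discrete patch solution of the spread source with
Dirichlet data P_k. Because the converged coupled solution satisfies the
*steady* equation, patches are built for the steady operator (−DαΔ); the
2D log kernel's arbitrary constant cancels in δP_k. The corrected field
P̄ + Σ_k q_k h_k δP_k feeds the flux fits and is the reported solution;
the uncorrected field is what the pseudo-time iteration propagates.

Implementation notes:

* One dense LU factorization of the patch operator serves every source;
  patches are computed per source point (exact sub-cell offsets) once per
  network/mesh and reused across iterations. A tabulated-offset variant
  with multilinear interpolation is available but its interpolation error
  plateaus near 1 % — the patch varies log-sharply with the offset — so
  the solver uses exact per-point patches.
* P_k diverges at r → 0 while sources can coincide with mesh nodes; it is
  evaluated at max(r, r₀) with r₀ the owning vessel's radius. The line
  source model makes no claim inside the lumen, where the physical field
  is pinned near the wall value, and the cap is mesh independent so
  nested-mesh error metrics remain meaningful.
* Sources within the patch half-extent of a no-flux face get explicit
  mirror-image copies (method of images), matching the folded spreading.
* The consumption nonlinearity is neglected in the patches: near vessels
  P ≫ P₀ makes M′ tiny, away from them δP_k itself is negligible.

### Outer iteration

Per iteration: (1) fit q* from the corrected field; (2) under-relax,
q ← λq + (1−λ)q*, λ = ½; (3) sweep the blood network; (4) spread and take
one pseudo-time step. Stopping: normalized L2 change of both q and P_O
below 10⁻³. Initialization: P_O ≡ 0, q ≡ 0, P_b ≡ P_b0. The pseudo-step
defaults are Δt = 5000·(1024/n) in 2D and 5000·(64/n) in 3D — larger steps
converge faster but destabilize the negative flux-field feedback, and the
stable window shrinks with refinement.

Two stabilizers address the non-smoothness of the flux map: a per-sample
adaptive damping that shrinks the update of samples whose correction
direction alternates (the clamp and the depletion fronts of weak vessels
flip single samples on fine meshes), and a depletion rule in the blood
sweep — a vessel whose P_b reaches zero releases nothing further, and the
cumulative release of a segment never exceeds the oxygen flux entering it.
An optional Gauss–Seidel variant re-evaluates each segment's flux with
freshly updated upstream blood values.

## Parameters

Defaults (override via config): Dα = 6×10⁻¹⁰ cm³O₂/cm/s/mmHg,
M₀ = 1.7×10⁻⁴ cm³O₂/cm³/s (2×10⁻³ for the high-demand single-vessel
validation), P₀ = 1 mmHg, C₀ = 0.5 cm³O₂/cm³, α_b = 3.1×10⁻⁵
cm³O₂/cm³/mmHg, P₅₀ = 38 mmHg, n = 2, P_b0 = 100 mmHg. The discharge
hematocrit is not pinned by the retinal literature values above; the
standard systemic H_D = 0.45 is used. Internal units: cm, s, mmHg, cm³O₂.

## Verification geometries

* **3D single vessel**: a 640 μm cube with a 10 μm-radius axial vessel
  spanning the full edge through the center, 0.05 nl/s inflow. Used for
  the near-vessel error map (h = 40, 20, 10 μm against the 5 μm run) and
  the 3D convergence order.
* **2D cobweb**: twelve spokes and five concentric rings in a 5.12 mm
  square, six inlets and six outlets alternating on the innermost ring at
  0.6 nl/s each. The spokes are the main branches (radii tapering
  28 → 12 μm); ring arcs are thin cross-links (10 μm) and the innermost
  loop is thinnest of all (5 μm), so its large resistance keeps it from
  short-circuiting the alternating inlets and outlets — its blood flow is
  small and its oxygen pressure decays fast, while the bulk of the flow
  perfuses the spokes and outer web.
* **Random capillary webs** (2D/3D): jittered, pruned lattices with four
  inlets and four outlets near the center — synthetic stand-ins for
  measured capillary plexus geometries, used for robustness testing only.

### What the verification shows — and what it does not

At the stated parameters the cobweb is deeply supply-limited: the blood
can cover under two percent of the tissue's saturated demand, so vessels
deplete within a few hundred micrometers and the solution is organized
around depletion fronts and thin oxygenated sleeves (sub-micrometer log
layers at fresh walls). The single-vessel problem shows clean behavior:
near-vessel errors of a few percent at h = 4r₀ dropping below one percent
at h = r₀, and a fitted convergence order near 1.7 (between the
first-order behavior of the singular near field and the second-order bulk
scheme). The 2D network case converges in its integral quantities (total
supply stabilizes to about one percent across meshes) but its pointwise
nested-mesh differences remain dominated by the junction/front regions:
the model itself has singular structure there that no fixed local
regularization can make mesh-converge pointwise. Synthetic geometries also
idealize real microvasculature: straight or circular centerlines, uniform
radii per segment, no anastomotic irregularity, no flow-dependent
hematocrit or viscosity. Passing tests demonstrate the numerics (mass
conservation, flux-fit exactness, multigrid behavior, RK4 order,
correction localization), not physiological fidelity of any particular
network.

## Numerical choices and degenerate inputs

* Flow solve: one boundary node pinned; interior conservation checked to
  10⁻¹⁰ of the peak flow. Components without a boundary node are an error.
* Stagnant segments (|Q| ≈ 0) release nothing and equilibrate with the
  local tissue value; they are logged.
* Flux-directed cycles abort the blood sweep (pressure-driven flow cannot
  produce them).
* Newton divergence (three consecutive residual increases) and outer
  residual doubling raise errors advising a smaller Δt; an iteration cap
  can instead return the best state (`stall_action="accept"`) — useful on
  fine 2D meshes where clamp flicker at a handful of samples keeps the
  normalized q-residual just above threshold long after the field residual
  (typically ~10⁻⁴) has converged.
* Problem sizes used by the built-in studies: 3D up to 128³, 2D up to
  2048²; these resolve the single-vessel physics well (h = r₀/2) while a
  full study remains a desk-scale computation. The 3D convergence studies
  run the outer iteration at a tightened tolerance (2×10⁻⁴): iteration
  residue at the production tolerance is comparable to the finest-pair
  discretization error and would contaminate the measured order.

## Known limitations

* The line-source simplification overestimates the field inside and right
  at the lumen; the correction restores the point-source near field but
  the model is only meaningful beyond the wall.
* Edge singularities at interior vessel ends (fresh inlets especially) are
  regularized by the geometric junction-ball rule; the flux distribution
  inside those balls is extrapolated, not resolved.
* Corrections near domain boundaries use explicit images for the faces a
  patch touches; corner-adjacent sources are handled by repeated
  reflection, but patch truncation error grows slightly there.
* Pressure-prescribed network boundary conditions are not implemented
  (flows only); radius- or hematocrit-dependent effective viscosity is out
  of scope.
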