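# Methods

## The model

Nuclear chromatin is described at the mesoscale by three volume fractions —
heterochromatin `phi_h`, euchromatin `phi_e` and nucleoplasm `phi_n` — with
`phi_h + phi_e + phi_n = 1`. The independent state variables are `phi_n` and
the order parameter `phi_d = phi_h − phi_e`. The free energy density is

    f = (c/2) [phi_e^2 + phi_h^2 (phi_h0 − phi_h)^2]
        + (kappa/2) (|∇phi_n|^2 + |∇phi_d|^2)
        − (V(phi_h)/d0) exp(−d/d0)

with a double-well bulk term whose minima are the euchromatic state
`(phi_h, phi_e) = (0, 0)` (note: this well is water-rich — the printed bulk
term penalizes `phi_e^2`, so its minimum has no euchromatin either; we
implement the functional exactly as written and treat "euchromatin" in
readouts as everything below the binarization threshold), the
heterochromatic state `(phi_h0, 0)`, an interfacial penalty, and an
exponentially-decaying chromatin–lamina attraction (`d` = distance to the
nuclear envelope). Dynamics are conserved Cahn–Hilliard-type fluxes of the
chemical potentials `mu_n = δf/δphi_n`, `mu_d = δf/δphi_d`, plus first-order
epigenetic interconversion

    d(phi_d)/dt += 2 (Gamma_me phi_e − Gamma_ac phi_h),

which vanishes when `phi_h/phi_e = Gamma_me/Gamma_ac`; for a homogeneous
state the methylated share of chromatin relaxes to
`Gamma_me/(Gamma_me + Gamma_ac)`. The methylation rate composes
deacetylation and methyltransferase steps harmonically,
`1/Gamma_me = 1/Gamma_HDAC + 1/Gamma_HMT` (and acetylation likewise from
demethylase and acetyltransferase steps).

### Parameters (defaults, units: nm, s, pN)

| symbol | meaning | default | notes |
|---|---|---|---|
| `c` | chromatin–chromatin interaction strength / volume | 8e-3 pN/nm² | physiological range ~8–16e-3 |
| `kappa` | interfacial penalty | 0.8 pN (model core); 1.25 in simulation presets | see "numerical choices" |
| `phi_h0` | heterochromatin well composition | 0.8 | dense but hydrated |
| `d0` | lamina attraction decay length | 2.5 nm | anchoring-protein scale |
| `V_EC`, `V_HC` | lamina affinity of EC / HC | 0 / configurable | `V_LAD = V_HC − V_EC` |
| `M_n`, `M_d` | mobilities | 1.0 | set the time unit `kappa/(M c²)` |
| `Gamma_ac` | acetylation rate | 1e-7 /s in presets | see calibration |
| `D_h` | effective mark diffusivity (extraction) | 8.33 nm²/s | enters the size relation only |

`V(phi_h)` interpolates linearly between `V_EC` and `V_HC` over
`[0, phi_h0]` (pluggable; results depend only weakly on the shape).
The interface width is `l_int = sqrt(kappa/c)`.

## Numerical scheme

Finite differences on a square lattice restricted to the nucleus mask;
no-flux (mirror) conditions at the mask boundary. The discrete interfacial
energy is link-based (forward differences), which makes the masked 5-point
Laplacian its exact variational derivative — the discrete energy and the
discrete chemical potentials are a consistent pair, verified against
central-difference perturbation to <1e-4 relative error.

Time stepping is linearly implicit for the biharmonic term plus a convex
stabilization `a = 2c`, explicit for the bulk nonlinearity, lamina force
and reactions:

    (I − dt M a L + dt M kappa L²) phi^{k+1}
        = phi^k + dt M L (g(phi^k) − a phi^k) + dt R(phi^k).

Because `1ᵀL = 0`, the total of `phi_n` is conserved to solver precision;
`phi_d` changes only through the reaction term. For a general mask the
operator is LU-factorized once per (geometry, dt); when the mask is the
full rectangle (`make_geometry("square", ...)`) the same operator is
diagonal in the DCT-II basis and the step costs a few FFTs — the two paths
agree to 1e-14 and the spectral path is ~20x faster, so the heavy panels
(perturbations, response surfaces) use square nuclei.

Three regularizations keep the composition on the physical simplex without
biasing the mark budget (the printed free energy has no entropic barrier,
so excursions are possible):

* the lamina attraction is spread over `max(d0, h)` (preserving its
  integral) because `d0` is below the lattice spacing;
* the attraction is multiplied by a packing headroom factor that shuts it
  off smoothly as `phi_h` approaches `min(phi_h0, 1 − phi_n)` — without
  this, boundary cells are driven off the simplex and the projection acts
  as a systematic mark sink (strong affinity then *reduces* LAD size, a
  pure artifact);
* after each step `phi_d` is clipped to `[phi_n − 1, 1 − phi_n]` and the
  clipped excess is redistributed over cells with headroom, so the
  projection conserves marks; clip counts are recorded in the trace.

Initial condition: uniform composition at the reaction fixed point
(methylated share `Gamma_me/(Gamma_me+Gamma_ac)` of a configurable
chromatin fraction), plus seeded i.i.d. noise of amplitude 0.01 projected
onto the simplex. Heterogogeneous inputs are Gaussian random fields with
stated pointwise mean and CV, Gaussian spectrum with correlation length
`xi` (2D for `Gamma_me(x)`, periodic 1D along the boundary arc for
`V_LAD(s)`), truncated at zero; the seed reproduces them bit-identically.

Steady state is declared when the windowed relative change of (mean
interior domain radius, mean LAD thickness) stays below `tol` (default
0.02) for two consecutive checks. This is a quasi-steady plateau criterion:
slow residual evolution (Ostwald-like transfer between compartments)
continues below the tolerance, so condition comparisons always use the
same protocol and matched seeds (common random numbers).

## Morphometrics

Simulated fields are binarized at `phi_h0/2` (the well midpoint), labeled
with 8-connected components, and classified LAD iff any cell lies within
2.5% of the effective nuclear radius from the envelope (mirroring the
imaging rule). Interior size is the area-equivalent radius
`R_d = sqrt(area/pi)`.

LAD thickness uses 50 equal-arc boundary segments. Per segment, the
accumulated LAD area `A` is inverted through the convex inner-band
relation `A = s·t − (pi/n)·t²` (the total turning 2*pi of a convex
boundary spread over the n segments), which reduces to `t = A/s` for thin
bands and makes a uniform annulus of thickness `t` read back exactly `t`
— the literal area/length quotient underestimates thick bands on curved
boundaries by `t/2R`. Segment areas sum exactly to the total LAD area.

Contact angles of peripheral domains come from a circular-cap fit: contact
width `w` along the boundary and cap height `hh` give
`R = w²/(8hh) + hh/2`, `theta = arccos(1 − hh/R)`; a half-disk reads 90°,
spread lamellae read small angles.

## Localization pipeline

Voronoi tessellation assigns each localization a polygon; unbounded
(convex-hull) polygons are `edge` and excluded from area sums. Reduced
density is the nucleus mean non-edge polygon area over the own polygon
area. Density classes come from percentiles of the reduced densities
pooled over all nuclei passed in one call: sparse ≤ P30 < dense ≤ P70 <
ultradense; the clustering mask is dense ∪ ultradense (the literal
dense-only band is available as an option).

DBSCAN (min 3 localizations) runs on the mask with
`eps = 3 x median nearest-neighbor distance` per nucleus. The scale-free
3x factor is deliberate: for a Poisson field the median spacing is
~0.5/sqrt(lambda), so eps = 2x spacing gives a filling factor
`lambda pi eps² = pi`, *below* the 2D continuum-percolation threshold
(~4.5) — a uniform-density domain then shatters into fragments at any
density. 3x gives filling ~7, safely above threshold. Clusters whose point
sets approach within 2*eps are merged (single-linkage): density fringes
(e.g. the blurred inner edge of a LAD band) otherwise break off as
satellite fragments, while true neighboring domains are separated by much
more. Two domain-calling guards are default-on and switchable: clusters
without a single ultradense member are dropped (background density
fluctuations lack a heterochromatin core), and clusters covering more than
half the nuclear area are dropped as unsegmented background percolation.

The nuclear envelope is an alpha-shape (Delaunay triangles with
circumradius < alpha, default 5x the 90th-percentile nearest-neighbor
distance — a high percentile so dense clusters do not collapse the scale —
with automatic doubling if the hull disconnects). LAD classification and
thickness profiles then follow the same rules as for fields, with member
Voronoi polygon areas in place of cell areas.

Known behavior and limits of the percentile pipeline (characterized by the
synthetic tests): the classes are *count-composition sensitive*. When the
background contributes less than ~30% of pooled localizations, the 30th
percentile eats into the heterochromatin population and erodes its
lowest-density fringe (thickness underestimates); above ~70%, mask classes
fill with background fluctuations (spurious calls). Thin bands carry a
positive bias of order the localization jitter plus one accreted
background polygon layer (~25-30 nm). Cross-condition comparisons should
pool all nuclei in one classification call, as the imaging protocol does.

## Synthetic data

`SyntheticSpec` generates per-nucleus localization clouds: homogeneous
Poisson background inside a circle/ellipse, disk-uniform interior clusters
(rejection-placed with minimum separation 4x the mean radius), and a
peripheral band of constant, patchy (alternating covered/empty blocks) or
smoothly varying thickness, all at stated intensities, plus optional
Gaussian jitter (sigma = 10 nm, the STORM localization-precision scale).
Defaults (background 450 /um², HC multiplier 13) put the background at
~28% of pooled counts for the default spec — just below the 30th
percentile, so the background stays out of the clustering mask while
erosion of the heterochromatin classes stays ~2%. What the generator does
not emulate: fluorophore blinking/multiple localizations per molecule,
drift, anisotropic clusters, chromatin texture between the two density
levels. Passing recovery tests therefore validate the geometry and
bookkeeping of the pipeline, not its robustness to photophysics.

The thickness-linearity property holds across nuclei when the total
localization budget is fixed (chromatin conservation: thicker LADs mean
fewer euchromatin localizations); with intensities fixed instead, the
pool composition drifts across conditions and the percentile classes bias
band-heavy nuclei (see above).

## Inverse extraction

Interior radii invert the kinetic-balance relation
`R_d = sqrt(3 D_h phibar_h* / Gamma_ac)` with the rational closure
`phibar_h* = s0 · Gamma_me/(Gamma_me + Gamma_ac)`; `s0` is calibrated once
so the control condition's central radius maps to the nominal control
rate, and `D_h`, `Gamma_ac` are fixed constants per run. With this closure
the inverse is the closed form `Gamma_me = Gamma_ac x/(s0 − x)`,
`x = R_d² Gamma_ac/(3 D_h)`, with limiting radius
`R_d_max = sqrt(3 D_h s0/Gamma_ac)`. The inverse is convex and steep near
saturation, so distribution means are tail-dominated; the package reports
the median as the central extracted rate.

LAD thicknesses invert a simulation-built response surface
`T_LAD(Gamma_me, V_LAD)` (isotonic-regularized along the affinity axis;
failed cells interpolated with a warning; cacheable by config hash).
Thicknesses at the low plateau map to affinity 0, at the high plateau to
the saturated top-of-grid bin — which is exactly what renders the
extracted affinity distribution bimodal when the periphery alternates bare
and saturated stretches; "bimodal" is declared when both plateau masses
exceed 10%. The heterochromatin budget check compares
`phibar_h · A_nuc` at the central extracted rate with the summed measured
domain areas and flags relative residuals above 0.5.

## Desk-scale calibration and its limits

The perturbation panel runs on a 1.2 um square nucleus at h = 6.25 nm with
`l_int = 12.5 nm` (`kappa = 1.25` at the printed `c`; the printed
`kappa = 0.8` gives `l_int = 10 nm`, under-resolved at an affordable
lattice). Control kinetics (`Gamma_ac = 1e-7 /s`,
`Gamma_me = 1.857e-7 /s`, CV 0.5, `xi` = 80 nm; affinity mean 0.02 with
CV 0.5 over 600 nm arcs; chromatin fraction 0.5) are calibrated so the
control shows discrete interior domains coexisting with peripheral LADs.
Three desk-scale facts constrain what this control can be:

1. interior/LAD coexistence requires the total reaction rate to stay well
   below the spinodal growth rate `~(c phi_h0²/4)²M/kappa` while the
   composition stays below the 2D percolation threshold — this bounds the
   interior domain radius from below at several `l_int` (the calibrated
   control measures ~150 nm, not the ~50 nm of real nuclei);
2. a 200 nm mean LAD thickness would occupy ~60% of this nucleus — above
   percolation — so the control's LAD thickness is ~75 nm (~6% of the
   box, matching the thickness-to-radius proportion of real nuclei rather
   than the absolute value);
3. with single-digit interior-domain counts per nucleus, percent changes
   between conditions carry replicate noise of order 10 percentage points
   even with matched seeds.

Perturbation conditions scale the two parameter means proportionately
(affinity and methylation multipliers per condition are tabulated in
`ladkit.perturb.CONDITIONS`), holding CVs, correlation lengths, geometry,
seeds and integration protocol fixed. All reported condition effects are
percent changes against the control under this common protocol.

## Known limitations

* The desk-scale nucleus exaggerates the perimeter-to-area ratio ~6x, so
  peripheral reaction fluxes weigh more than in real nuclei; the
  simulated sensitivity of LAD thickness to the affinity is weak-to-flat
  where the realistic response rises, and the three-regime shape of the
  affinity response is only marginally detectable at this scale.
* The quasi-steady plateau is not a true fixed point; compartment
  exchange continues slowly below tolerance. Comparisons are protocol-
  matched, not asymptotic.
* The percentile density classes assume a pool composition with a
  meaningful sparse background share; compositions outside the ~30-70%
  window degrade domain calling (documented above, exercised by tests).
* No Flory–Huggins mixing entropy, no mechanical coupling, no 3D, no
  water exchange with the cytosol (strict no-flux).
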